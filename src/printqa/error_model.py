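"""Gaussian error propagation of the three partial errors to the total error.

Each processing stage contributes a partial error characterised by the mean
(Delta mean) and standard deviation (sigma) of its signed surface-deviation
distribution: SegE (ground truth vs. direct segmentation), DEE (direct
segmentation vs. print-STL) and PrE (print-STL vs. printed model). Assuming
independent stages, the total error has

    Delta mean_total = Delta mean_SegE + Delta mean_DEE + Delta mean_PrE
    sigma_total      = sqrt(sigma_SegE^2 + sigma_DEE^2 + sigma_PrE^2)

Means of opposite sign can cancel, but the spread only ever grows with each
processing step. The independence assumption is inherited from the study
design and documented, not tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

PARTIAL_LABELS = ("SegE", "DEE", "PrE")


@dataclass(frozen=True)
class PartialError:
    """Mean and sigma (mm) of one stage's surface-deviation distribution."""

    label: str
    d_mean: float
    sigma: float

    def __post_init__(self):
        if self.label not in PARTIAL_LABELS:
            raise ValueError(
                f"label must be one of {PARTIAL_LABELS}, got {self.label!r}"
            )
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class TotalError:
    """Propagated total error; ``six_sigma`` is always exactly 6 * sigma_total."""

    d_mean_total: float
    sigma_total: float
    six_sigma: float


def propagate_total(
    seg_e: PartialError, dee: PartialError, pr_e: PartialError
) -> TotalError:
    """Combine exactly one partial error per stage into the total error."""
    partials = (seg_e, dee, pr_e)
    labels = sorted(p.label for p in partials)
    if labels != sorted(PARTIAL_LABELS):
        raise ValueError(
            f"need exactly one record per label {PARTIAL_LABELS}, got {labels}"
        )
    d_mean = sum(p.d_mean for p in partials)
    # hypot: quadrature sum without under-/overflow of the squares
    sigma = math.hypot(*(p.sigma for p in partials))
    assert all(sigma >= p.sigma * (1.0 - 1e-12) for p in partials)
    return TotalError(d_mean_total=d_mean, sigma_total=sigma, six_sigma=6.0 * sigma)


def six_sigma_interval(mean: float, sigma: float) -> float:
    """Width of [mean - 3 sigma, mean + 3 sigma]; the mean cancels: 6 * sigma."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return 6.0 * sigma


def normal_coverage_3sigma() -> float:
    """Probability mass of a normal distribution within +-3 sigma (~0.9973)."""
    return math.erf(3.0 / math.sqrt(2.0))


def format_report(partials: dict, total: TotalError) -> dict:
    """JSON-ready report of one propagation, mm values at 4 decimals."""
    return {
        "partials": {
            label: {"d_mean_mm": round(p.d_mean, 4), "sigma_mm": round(p.sigma, 4)}
            for label, p in partials.items()
        },
        "total": {
            "d_mean_mm": round(total.d_mean_total, 4),
            "sigma_mm": round(total.sigma_total, 4),
            "six_sigma_mm": round(total.six_sigma, 4),
            # reported separately because rounding sigma first gives a
            # slightly different 6-sigma value than using full precision
            "six_sigma_from_rounded_sigma_mm": round(
                6.0 * round(total.sigma_total, 4), 4
            ),
        },
    }
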