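"""Gaussian error propagation: combine SegE, DEE and PrE into a total error.

Means add; standard deviations add in quadrature. Opposite-sign means can
cancel, but the spread only grows with each processing step.
"""

import json

from printqa import PartialError, format_report, propagate_total

seg_e = PartialError("SegE", d_mean=-0.0144, sigma=0.0401)
dee = PartialError("DEE", d_mean=-0.0046, sigma=0.0175)
pr_e = PartialError("PrE", d_mean=-0.0131, sigma=0.0291)

total = propagate_total(seg_e, dee, pr_e)
report = format_report({"SegE": seg_e, "DEE": dee, "PrE": pr_e}, total)
print(json.dumps(report, indent=2))
print(f"\ntotal: {total.d_mean_total:+.4f} mm +- {total.sigma_total:.4f} mm, "
      f"6-sigma interval {total.six_sigma:.4f} mm")
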