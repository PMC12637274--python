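"""Bland-Altman agreement between two measurement series.

Simulates paired lesion-area measurements from a reference and a slightly
biased, noisy second method, then reports the systematic bias, the 95%
limits of agreement, and the proportional-bias regression.
"""

import tempfile
from pathlib import Path

import numpy as np

from spatioseg.agreement import bland_altman, export_plot_data

rng = np.random.default_rng(42)
reference = rng.uniform(50, 400, 80)  # e.g. lesion areas in pixels
predicted = reference + 3.0 + rng.normal(0, 8.0, 80)  # small constant bias + noise

report = bland_altman(predicted, reference)
print(f"n = {report.n}")
print(f"bias (mean difference)      : {report.mean_diff:+.2f} px")
print(f"limits of agreement (1.96sd): ({report.loa_low:+.2f}, {report.loa_high:+.2f}) px")
print(f"proportional bias slope     : {report.prop_bias_slope:+.4f} "
      f"(p = {report.prop_bias_p:.3f})")
inside = np.mean((report.pairs[:, 1] >= report.loa_low)
                 & (report.pairs[:, 1] <= report.loa_high))
print(f"fraction of differences inside the limits: {inside:.3f} (~0.95 expected)")

with tempfile.TemporaryDirectory() as d:
    csv = Path(d) / "ba.csv"
    export_plot_data(report, csv, figure_path=Path(d) / "ba.png")
    print(f"exported {sum(1 for _ in open(csv)) - 1} CSV rows (pairs + 3 reference lines)")
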