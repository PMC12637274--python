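"""Bland-Altman method-agreement analysis.

Given two paired measurement series (for example predicted vs reference
lesion area, or per-image HD95 from two models), the analysis reports the
mean of the paired differences (systematic bias), the limits of agreement
``bias +/- 1.96 * SD`` within which about 95% of differences are expected to
lie, and a test for proportional bias obtained by regressing the differences
on the pair means.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AgreementReport", "bland_altman", "proportional_bias", "export_plot_data"]

LOA_MULTIPLIER = 1.96  # fixed z multiplier; about 95% coverage for Gaussian differences


@dataclass
class AgreementReport:
    n: int
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    prop_bias_slope: float
    prop_bias_p: float
    pairs: np.ndarray  # (n, 2) columns: mean, difference


def bland_altman(a, b) -> AgreementReport:
    """Agreement statistics for paired series; differences are ``a - b``.

    ``a`` is the method under evaluation (e.g. predicted), ``b`` the
    reference.  SD uses the n-1 denominator; limits of agreement are
    ``mean_diff +/- 1.96 * sd_diff``.  Zero-variance differences collapse the
    limits onto the bias.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"expected equal-length 1-D series, got {a.shape} and {b.shape}")
    if len(a) < 3:
        raise ValueError(f"need at least 3 pairs, got {len(a)}")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("series contain non-finite values")
    d = a - b
    m = (a + b) / 2.0
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    try:
        slope, p = proportional_bias(np.column_stack([m, d]))
    except ValueError:  # constant means: proportional bias undefined
        slope, p = float("nan"), float("nan")
    return AgreementReport(
        n=len(a),
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        loa_low=mean_diff - LOA_MULTIPLIER * sd_diff,
        loa_high=mean_diff + LOA_MULTIPLIER * sd_diff,
        prop_bias_slope=slope,
        prop_bias_p=p,
        pairs=np.column_stack([m, d]),
    )


def proportional_bias(pairs) -> tuple[float, float]:
    """OLS slope of difference on mean, with the two-sided p-value for slope = 0.

    A slope significantly different from zero indicates the disagreement
    between the methods grows (or shrinks) with the magnitude measured.
    """
    pairs = np.asarray(pairs, dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or len(pairs) < 3:
        raise ValueError("pairs must be an (n>=3, 2) array of (mean, difference)")
    m, d = pairs[:, 0], pairs[:, 1]
    if np.allclose(m, m[0]):
        raise ValueError("degenerate design: pair means are constant, slope undefined")
    res = stats.linregress(m, d)
    return float(res.slope), float(res.pvalue)


def export_plot_data(report: AgreementReport, csv_path, figure_path=None):
    """Write (mean, difference) pairs plus bias/LoA reference lines to CSV.

    The CSV has one row per pair (kind ``pair``) followed by three reference
    rows (``bias``, ``loa_low``, ``loa_high``).  Differences are predicted
    minus reference.  Optionally renders the scatter as a figure.
    """
    rows = [
        {"kind": "pair", "mean": m, "difference": d} for m, d in report.pairs
    ]
    rows.append({"kind": "bias", "mean": np.nan, "difference": report.mean_diff})
    rows.append({"kind": "loa_low", "mean": np.nan, "difference": report.loa_low})
    rows.append({"kind": "loa_high", "mean": np.nan, "difference": report.loa_high})
    df = pd.DataFrame(rows)
    df.to_csv(csv_path, index=False)
    if figure_path is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 4))
        ax.scatter(report.pairs[:, 0], report.pairs[:, 1], s=12, alpha=0.7)
        ax.axhline(report.mean_diff, color="red", ls="--", label=f"bias={report.mean_diff:.4g}")
        ax.axhline(report.loa_low, color="gray", ls=":", label=f"LoA=({report.loa_low:.4g}, {report.loa_high:.4g})")
        ax.axhline(report.loa_high, color="gray", ls=":")
        ax.set_xlabel("mean of methods")
        ax.set_ylabel("difference (predicted - reference)")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(figure_path, dpi=120)
        plt.close(fig)
    return df
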