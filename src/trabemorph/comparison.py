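"""Agreement analysis between morphometry algorithm variants.

Mirrors the standard method-comparison toolbox: per-sample percent
differences under an explicit normalization, Bland–Altman mean ± SD with
1.96·SD limits of agreement, and ordinary least-squares regression with R².

Normalization of the percent difference is a genuine source of ambiguity
between published comparisons, so it is an explicit enum rather than a
hidden default: ``ref_b`` (denominator = second series, the reference),
``ref_a``, or ``pair_mean``.  Under ``pair_mean`` the difference is exactly
antisymmetric in the pair.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, PreconditionError

__all__ = [
    "ComparisonReport", "percent_difference", "bland_altman",
    "linear_regression", "compare_variants", "plot_comparison", "format_report",
]

LOA_MULTIPLIER = 1.96


@dataclasses.dataclass
class ComparisonReport:
    """One row of a variant-pair agreement table."""

    parameter: str
    pair: tuple                # (label_a, label_b); label_b is the ref_b reference
    mean_diff_pct: float
    sd_diff_pct: float
    loa_low: float
    loa_high: float
    slope: float               # regression of the first label on the second
    intercept: float
    r_squared: float
    n: int
    normalization: str


def _denominator(a: np.ndarray, b: np.ndarray, normalization: str) -> np.ndarray:
    if normalization == "ref_b":
        return b
    if normalization == "ref_a":
        return a
    if normalization == "pair_mean":
        return (a + b) / 2.0
    raise PreconditionError(f"unknown normalization {normalization!r}")


def percent_difference(a, b, normalization: str = "ref_b") -> np.ndarray:
    """Per-sample 100·(a−b)/denominator; zero denominators yield NaN with a warning."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise PreconditionError("paired series must have equal length")
    denom = _denominator(a, b, normalization)
    out = np.full(a.shape, np.nan)
    ok = denom != 0
    if not ok.all():
        warnings.warn(f"{np.count_nonzero(~ok)} sample(s) excluded: zero denominator",
                      stacklevel=2)
    out[ok] = 100.0 * (a[ok] - b[ok]) / denom[ok]
    return out


def bland_altman(a, b, normalization: str = "ref_b") -> ComparisonReport:
    """Mean ± SD of percent differences and 1.96·SD limits of agreement.

    SD uses the n−1 denominator; at least three usable pairs are required.
    """
    d = percent_difference(a, b, normalization)
    d = d[np.isfinite(d)]
    n = len(d)
    if n < 3:
        raise InsufficientDataError(f"Bland–Altman needs n >= 3 pairs, have {n}")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return ComparisonReport(
        parameter="", pair=("a", "b"),
        mean_diff_pct=mean, sd_diff_pct=sd,
        loa_low=mean - LOA_MULTIPLIER * sd, loa_high=mean + LOA_MULTIPLIER * sd,
        slope=np.nan, intercept=np.nan, r_squared=np.nan,
        n=n, normalization=normalization,
    )


def linear_regression(a, b) -> tuple:
    """OLS of b on a; returns (slope, intercept, r_squared)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or len(a) < 3:
        raise InsufficientDataError("regression needs >= 3 paired samples")
    if np.var(a) == 0:
        raise PreconditionError("degenerate regressor: zero variance")
    res = stats.linregress(a, b)
    return float(res.slope), float(res.intercept), float(res.rvalue**2)


def compare_variants(results: pd.DataFrame, pairs, normalization: str = "ref_b",
                     parameters=None) -> pd.DataFrame:
    """Pairwise agreement table over a long-format results table.

    ``results`` needs columns ``sample, parameter, variant_label, value``;
    ``pairs`` is a list of ``(label_a, label_b)`` with the second label acting
    as the reference (x-axis; ref_b denominator).  One report row is produced
    per (parameter, pair); samples missing either value are dropped with a
    logged count.
    """
    required = {"sample", "parameter", "variant_label", "value"}
    if not required.issubset(results.columns):
        raise PreconditionError(f"results table needs columns {sorted(required)}")
    rows = []
    params = parameters or sorted(results["parameter"].unique())
    for parameter in params:
        sub = results[results["parameter"] == parameter]
        for (label_a, label_b) in pairs:
            wide = sub.pivot_table(index="sample", columns="variant_label",
                                   values="value", aggfunc="first")
            if label_a not in wide.columns or label_b not in wide.columns:
                continue
            paired = wide[[label_a, label_b]].dropna()
            dropped = len(wide) - len(paired)
            if dropped:
                warnings.warn(f"{parameter} {label_a} vs {label_b}: "
                              f"{dropped} sample(s) dropped (missing values)",
                              stacklevel=2)
            a = paired[label_a].to_numpy()
            b = paired[label_b].to_numpy()
            ba = bland_altman(a, b, normalization)
            # First label on the reference (second-label) axis, matching the
            # reference-based plots this table accompanies.
            slope, intercept, r2 = linear_regression(b, a)
            rows.append(ComparisonReport(
                parameter=parameter, pair=(label_a, label_b),
                mean_diff_pct=ba.mean_diff_pct, sd_diff_pct=ba.sd_diff_pct,
                loa_low=ba.loa_low, loa_high=ba.loa_high,
                slope=slope, intercept=intercept, r_squared=r2,
                n=ba.n, normalization=normalization,
            ))
    return pd.DataFrame([dataclasses.asdict(r) for r in rows])


def plot_comparison(results: pd.DataFrame, parameter: str, pair,
                    normalization: str = "ref_b", ax=None):
    """Regression (left) and Bland–Altman (right) panel for one variant pair.

    Solid line marks the mean difference, dashed lines the ±1.96·SD limits.
    Returns the matplotlib Figure.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    label_a, label_b = pair
    sub = results[results["parameter"] == parameter]
    wide = sub.pivot_table(index="sample", columns="variant_label",
                           values="value", aggfunc="first")
    paired = wide[[label_a, label_b]].dropna()
    a = paired[label_a].to_numpy()
    b = paired[label_b].to_numpy()
    slope, intercept, r2 = linear_regression(b, a)
    ba = bland_altman(a, b, normalization)
    d = percent_difference(a, b, normalization)

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.scatter(b, a, s=8)
    xs = np.linspace(b.min(), b.max(), 2)
    ax1.plot(xs, slope * xs + intercept,
             label=f"y = {slope:.3f}x + {intercept:.3g}\nR² = {r2:.2f}")
    ax1.set_xlabel(f"{label_b} (reference)")
    ax1.set_ylabel(label_a)
    ax1.legend(fontsize=8)
    mean_ab = (a + b) / 2.0
    ax2.scatter(mean_ab, d, s=8)
    ax2.axhline(ba.mean_diff_pct, color="k",
                label=f"mean {ba.mean_diff_pct:.2f}%")
    for y in (ba.loa_low, ba.loa_high):
        ax2.axhline(y, color="k", linestyle="--")
    ax2.set_xlabel("pair mean")
    ax2.set_ylabel(f"difference [%] ({normalization})")
    ax2.legend(fontsize=8)
    fig.suptitle(f"{parameter}: {label_a} vs {label_b}")
    fig.tight_layout()
    return fig


def format_report(report: pd.DataFrame) -> pd.DataFrame:
    """Percent columns rounded to two decimals, diff ± SD combined for display."""
    out = report.copy()
    out["diff_pm_sd"] = [f"{m:.2f} ± {s:.2f}"
                         for m, s in zip(out["mean_diff_pct"], out["sd_diff_pct"])]
    for col in ("mean_diff_pct", "sd_diff_pct", "loa_low", "loa_high", "r_squared"):
        out[col] = out[col].round(2)
    return out
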