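"""Treatment-group statistics and report generation.

Per-group spheroid populations are summarised as n, mean, SD (n−1
denominator) and SEM = SD/√n; pairs of arms are compared with the classical
unpaired two-sided Student's t test (pooled variance; Welch available behind
a flag) and a fold change of means. Reports follow the per-spheroid
scatter-with-mean±SEM-bar presentation standard in the spheroid cytotoxicity
literature, plus a machine-readable comparisons CSV. No multiple-testing
correction is applied; pairwise p values are reported raw and the report
footer says so.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .morphometry import SpheroidMeasurement, measurements_to_frame

__all__ = [
    "WellSummary",
    "GroupComparison",
    "summarize",
    "compare",
    "effect_fold",
    "significance_label",
    "render_report",
    "DEFAULT_P_CUTOFFS",
]

#: p cutoffs mapped to "*", "**", "***" (configurable per report/figure)
DEFAULT_P_CUTOFFS: tuple[float, float, float] = (0.01, 0.001, 0.0001)

VARIABLES = ("perimeter_um", "area_um2", "volume_um3", "cell_count")


@dataclass
class WellSummary:
    """Population summary of one group (a well or a pooled arm)."""

    group: str
    arm: str
    n_spheroids: int
    stats: dict[str, dict[str, float]] = field(default_factory=dict)
    # stats[variable] = {"mean": ..., "sd": ..., "sem": ...}; sd/sem are NaN
    # (undefined) for n < 2 rather than silently dropped


@dataclass
class GroupComparison:
    arm_a: str
    arm_b: str
    variable: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t_statistic: float
    p_two_sided: float
    fold_change: float  # mean_b / mean_a
    significance: str = "ns"
    degenerate: bool = False


def significance_label(
    p: float, cutoffs: tuple[float, float, float] = DEFAULT_P_CUTOFFS
) -> str:
    c1, c2, c3 = cutoffs
    if p < c3:
        return "***"
    if p < c2:
        return "**"
    if p < c1:
        return "*"
    return "ns"


def summarize(
    measurements: list[SpheroidMeasurement],
    group_by: str = "arm",
) -> list[WellSummary]:
    """Per-group n, mean, SD and SEM for each morphometric variable.

    ``group_by`` is ``"arm"`` or ``"well"``. Groups with n = 0 or n = 1 are
    kept, with undefined moments reported as NaN. Output is ordered by group
    label for determinism.
    """
    if group_by not in ("arm", "well"):
        raise ValueError("group_by must be 'arm' or 'well'")
    df = measurements_to_frame(measurements)
    key = "arm" if group_by == "arm" else "well_id"
    out: list[WellSummary] = []
    for label in sorted(df[key].astype(str).unique()):
        sub = df[df[key].astype(str) == label]
        n = len(sub)
        stats: dict[str, dict[str, float]] = {}
        for var in VARIABLES:
            vals = sub[var].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            m = len(vals)
            mean = float(np.mean(vals)) if m else float("nan")
            sd = float(np.std(vals, ddof=1)) if m >= 2 else float("nan")
            sem = sd / np.sqrt(m) if m >= 2 else float("nan")
            stats[var] = {"mean": mean, "sd": sd, "sem": sem}
        arm = str(sub["arm"].iloc[0]) if n else label
        out.append(WellSummary(group=label, arm=arm, n_spheroids=n, stats=stats))
    return out


def compare(
    values_a: np.ndarray,
    values_b: np.ndarray,
    arm_a: str = "a",
    arm_b: str = "b",
    variable: str = "",
    welch: bool = False,
    p_cutoffs: tuple[float, float, float] = DEFAULT_P_CUTOFFS,
) -> GroupComparison:
    """Unpaired two-sided Student's t test between two groups of values.

    The default is the classical pooled-variance statistic with
    n_a + n_b − 2 degrees of freedom; ``welch=True`` switches to the
    unequal-variance form. Zero pooled variance with equal means gives
    t = 0, p = 1; with unequal means the comparison is flagged degenerate
    and p is reported as the smallest positive float.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    n_a, n_b = len(a), len(b)
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 observations per group")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    var_a, var_b = float(a.var(ddof=1)), float(b.var(ddof=1))
    # variances indistinguishable from zero at floating precision count as zero
    scale = max(np.abs(a).max(), np.abs(b).max(), 1e-300)
    tiny = (1e-12 * scale) ** 2
    var_a = 0.0 if var_a < tiny else var_a
    var_b = 0.0 if var_b < tiny else var_b

    degenerate = False
    if welch:
        se2 = var_a / n_a + var_b / n_b
        if se2 == 0.0:
            t_stat, p, degenerate = _degenerate_tp(mean_a, mean_b)
        else:
            t_stat = (mean_a - mean_b) / np.sqrt(se2)
            df_w = se2**2 / (
                (var_a / n_a) ** 2 / (n_a - 1) + (var_b / n_b) ** 2 / (n_b - 1)
            )
            p = 2.0 * float(sps.t.sf(abs(t_stat), df_w))
    else:
        df = n_a + n_b - 2
        sp2 = ((n_a - 1) * var_a + (n_b - 1) * var_b) / df
        if sp2 == 0.0:
            t_stat, p, degenerate = _degenerate_tp(mean_a, mean_b)
        else:
            t_stat = (mean_a - mean_b) / np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
            p = 2.0 * float(sps.t.sf(abs(t_stat), df))
    p = min(p, 1.0)

    fold = mean_b / mean_a if mean_a != 0 else float("nan")
    return GroupComparison(
        arm_a=arm_a,
        arm_b=arm_b,
        variable=variable,
        n_a=n_a,
        n_b=n_b,
        mean_a=mean_a,
        mean_b=mean_b,
        t_statistic=float(t_stat),
        p_two_sided=float(p),
        fold_change=float(fold),
        significance=significance_label(p, p_cutoffs),
        degenerate=degenerate,
    )


def _degenerate_tp(mean_a: float, mean_b: float) -> tuple[float, float, bool]:
    if mean_a == mean_b:
        return 0.0, 1.0, False
    # zero within-group variance but different means: arbitrarily significant
    return float("inf") if mean_a > mean_b else float("-inf"), float(np.nextafter(0, 1)), True


def compare_measurements(
    measurements_a: list[SpheroidMeasurement],
    measurements_b: list[SpheroidMeasurement],
    variable: str = "volume_um3",
    arm_a: str | None = None,
    arm_b: str | None = None,
    **kwargs,
) -> GroupComparison:
    """Convenience wrapper of :func:`compare` over measurement lists."""
    va = np.array([getattr(m, variable) for m in measurements_a], dtype=float)
    vb = np.array([getattr(m, variable) for m in measurements_b], dtype=float)
    return compare(
        va, vb,
        arm_a=arm_a or (measurements_a[0].arm if measurements_a else "a"),
        arm_b=arm_b or (measurements_b[0].arm if measurements_b else "b"),
        variable=variable,
        **kwargs,
    )


def effect_fold(
    measurements_treated: list[SpheroidMeasurement],
    measurements_control: list[SpheroidMeasurement],
    variable: str = "volume_um3",
    use_median: bool = False,
) -> float:
    """Fold change of the treated group relative to control (ratio of means).

    The conventional effect size for spheroid-size readouts; a ratio of
    medians is available as an option for heavy-tailed populations.
    """
    if not measurements_treated or not measurements_control:
        raise ValueError("both groups must be non-empty")
    vt = np.array([getattr(m, variable) for m in measurements_treated], dtype=float)
    vc = np.array([getattr(m, variable) for m in measurements_control], dtype=float)
    agg = np.median if use_median else np.mean
    denom = float(agg(vc))
    if denom <= 0:
        raise ValueError("control aggregate must be positive")
    return float(agg(vt)) / denom


# ---------------------------------------------------------------------------
# report rendering

_COMPARISON_COLUMNS = [
    "arm_a", "arm_b", "variable", "n_a", "n_b", "mean_a", "mean_b",
    "t", "p", "fold_change", "label",
]


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "arm_a": c.arm_a, "arm_b": c.arm_b, "variable": c.variable,
                "n_a": c.n_a, "n_b": c.n_b, "mean_a": c.mean_a, "mean_b": c.mean_b,
                "t": c.t_statistic, "p": c.p_two_sided,
                "fold_change": c.fold_change, "label": c.significance,
            }
            for c in comparisons
        ],
        columns=_COMPARISON_COLUMNS,
    )


def render_report(
    measurements: list[SpheroidMeasurement],
    comparisons: list[GroupComparison],
    out_dir: str | Path,
    variable: str = "volume_um3",
) -> list[Path]:
    """Write the comparisons CSV and per-arm scatter plots with mean±SEM bars.

    File naming is deterministic: ``comparisons.csv`` plus one
    ``scatter_<variable>.png`` when measurements are present. Returns the
    written paths.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    csv_path = out / "comparisons.csv"
    comparisons_to_frame(comparisons).to_csv(csv_path, index=False, float_format="%.6g")
    with open(csv_path, "a") as fh:
        fh.write("# unpaired two-sided Student's t test; raw p values, "
                 "no multiple-testing correction\n")
    written.append(csv_path)

    if measurements:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        df = measurements_to_frame(measurements)
        arms = sorted(df["arm"].astype(str).unique())
        rng = np.random.default_rng(0)  # fixed: only cosmetic x-dither
        fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(arms), 4.0))
        for i, arm in enumerate(arms):
            vals = df.loc[df["arm"].astype(str) == arm, variable].to_numpy(float)
            vals = vals[np.isfinite(vals)]
            x = i + rng.uniform(-0.18, 0.18, size=len(vals))
            ax.plot(x, vals, "o", ms=3, alpha=0.55)
            if len(vals):
                m = vals.mean()
                sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
                ax.errorbar([i], [m], yerr=[sem], fmt="_", color="k",
                            ms=22, capsize=6, lw=1.6, zorder=3)
        for c in comparisons:
            if c.variable == variable and c.significance != "ns" \
                    and c.arm_a in arms and c.arm_b in arms:
                ia, ib = arms.index(c.arm_a), arms.index(c.arm_b)
                y = df[variable].max() * (1.04 + 0.06 * min(ia + ib, 6))
                ax.plot([ia, ib], [y, y], "k-", lw=0.8)
                ax.text((ia + ib) / 2, y, c.significance, ha="center", va="bottom")
        ax.set_xticks(range(len(arms)), arms)
        ax.set_ylabel(variable)
        ax.set_title("per-spheroid measurements (bar: mean ± SEM)")
        fig.tight_layout()
        png_path = out / f"scatter_{variable}.png"
        fig.savefig(png_path, dpi=120)
        plt.close(fig)
        written.append(png_path)
    return written
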