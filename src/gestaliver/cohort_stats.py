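"""Cohort statistics: paired visit comparisons, the change-vs-liver-change
correlation battery with exact p arithmetic, pattern subgroup comparisons,
and plain-text report generation.

All tests are two-sided and no multiple-testing adjustment is applied;
reports carry raw p values only. Percentages are rounded half-up to
integers; p values are reported to three decimals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .volumetrics import DEFAULT_TOLERANCE_PCT, classify_pattern

__all__ = [
    "CorrelationResult",
    "correlation_p_from_r",
    "correlation_battery",
    "paired_test",
    "pattern_labels",
    "subgroup_comparison",
    "proportion_report",
    "volume_summary",
    "make_report",
    "DEFAULT_METHOD_MAP",
]

#: variables whose published correlations use Spearman rather than Pearson
DEFAULT_METHOD_MAP = {"ihl": "spearman", "egp_umol_kg_min": "spearman"}


@dataclass(frozen=True)
class CorrelationResult:
    variable: str
    method: str
    n: int
    r: float
    p: float
    exact_r_flag: bool = False  # |r| = 1: p returned as the 0 limit

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("correlation requires n >= 3")
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")


def correlation_p_from_r(r: float, n: int, method: str = "pearson") -> float:
    """Two-sided p for a correlation coefficient via the t-transform.

    t = r sqrt(n-2) / sqrt(1-r^2) referred to a t distribution with n-2
    degrees of freedom; the same transform serves Pearson and (as the
    standard large-sample approximation) Spearman coefficients.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if abs(r) > 1:
        raise ValueError(f"|r| must be <= 1, got {r}")
    if abs(r) == 1:
        warnings.warn("|r| = 1: returning the limiting p of 0")
        return 0.0
    t = r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)
    return 2.0 * stats.t.sf(abs(t), df=n - 2)


def _per_participant_changes(cohort: pd.DataFrame, variables) -> pd.DataFrame:
    """Late-minus-early change per participant for each requested variable."""
    wide = cohort[cohort["stage"].isin(["early", "late"])].pivot_table(
        index="participant", columns="stage",
        values=["liver_volume_cm3", *variables], aggfunc="first",
    )
    out = pd.DataFrame(index=wide.index)
    out["liver_volume_cm3"] = wide[("liver_volume_cm3", "late")] - wide[("liver_volume_cm3", "early")]
    for v in variables:
        out[v] = wide[(v, "late")] - wide[(v, "early")]
    return out


def correlation_battery(
    cohort: pd.DataFrame,
    variables: list[str] | None = None,
    method_map: dict[str, str] | None = None,
) -> list[CorrelationResult]:
    """Correlate each variable's change with the liver-volume change.

    Complete-case per variable (the per-variable n may differ); constant
    variables are skipped with a warning. The method map selects Spearman
    for the variables published that way; all others use Pearson.
    """
    method_map = DEFAULT_METHOD_MAP if method_map is None else method_map
    if variables is None:
        skip = {
            "participant", "stage", "liver_volume_cm3", "pregnancy_class", "completer",
            "gain_loss", "hypertension",
        }
        variables = [
            c for c in cohort.columns
            if c not in skip and pd.api.types.is_numeric_dtype(cohort[c])
            and not c.startswith("newborn_")
        ]
    changes = _per_participant_changes(cohort, variables)
    results: list[CorrelationResult] = []
    for v in variables:
        pair = changes[["liver_volume_cm3", v]].dropna()
        n = len(pair)
        if n < 3:
            warnings.warn(f"{v}: fewer than 3 complete cases; skipped")
            continue
        x = pair["liver_volume_cm3"].to_numpy()
        y = pair[v].to_numpy()
        if np.ptp(y) == 0 or np.ptp(x) == 0:
            warnings.warn(f"{v}: zero variance; skipped")
            continue
        method = method_map.get(v, "pearson")
        if method == "spearman":
            r = float(stats.spearmanr(x, y).statistic)
        else:
            r = float(stats.pearsonr(x, y).statistic)
        exact = bool(abs(r) >= 1.0 - 1e-15)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = correlation_p_from_r(min(max(r, -1.0), 1.0), n, method)
        results.append(CorrelationResult(v, method, n, r, p, exact_r_flag=exact))
    return results


def paired_test(before, after) -> tuple[float, float, float, float]:
    """Classical two-sided paired t test on after-minus-before differences.

    Returns ``(mean_diff, sd_diff, t, p)``.
    """
    b = np.asarray(before, dtype=float)
    a = np.asarray(after, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1D and of equal length")
    d = a - b
    n = d.size
    if n < 2:
        raise ValueError("need at least two pairs")
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of differences; paired t is degenerate")
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(d.mean()), float(sd), float(t), float(p)


def pattern_labels(
    cohort: pd.DataFrame, tolerance_pct: float = DEFAULT_TOLERANCE_PCT
) -> pd.DataFrame:
    """Per-completer pattern classification from the three visit volumes."""
    vols = cohort.pivot_table(
        index="participant", columns="stage", values="liver_volume_cm3", aggfunc="first"
    )
    rows = []
    for pid, row in vols.iterrows():
        if not (np.isfinite(row.get("early", np.nan)) and np.isfinite(row.get("late", np.nan))):
            continue
        post = row.get("postwean", np.nan)
        pat = classify_pattern(
            row["early"], row["late"], None if not np.isfinite(post) else float(post),
            tolerance_pct,
        )
        rows.append(
            {
                "participant": pid,
                "pregnancy_change": pat.pregnancy_change,
                "postwean_change": pat.postwean_change,
                "pattern": pat.label,
                "subtype": pat.subtype,
            }
        )
    return pd.DataFrame(rows).set_index("participant")


@dataclass(frozen=True)
class SubgroupComparison:
    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    summary_a: float
    summary_b: float
    difference: float
    direction: str
    test: str
    p: float


def subgroup_comparison(
    cohort: pd.DataFrame,
    labels: pd.DataFrame,
    metric: str,
    stage: str = "late",
) -> SubgroupComparison:
    """Compare gain-loss vs not-gain-loss on a metric.

    Continuous metrics use a two-sided two-sample (Welch) t test on the
    stage values; the binary hypertension flag uses Fisher's exact count
    comparison.
    """
    defined = labels[labels["pattern"] != "undefined"]
    gl_ids = defined.index[defined["pattern"] == "gain-loss"]
    ngl_ids = defined.index[defined["pattern"] == "not gain-loss"]
    if len(gl_ids) == 0:
        raise ValueError("gain-loss group is empty")
    if len(ngl_ids) == 0:
        raise ValueError("not-gain-loss group is empty")

    if metric == "hypertension":
        per_p = cohort.groupby("participant")["hypertension"].first()
        a = per_p.loc[gl_ids].astype(bool)
        b = per_p.loc[ngl_ids].astype(bool)
        table = [[int(a.sum()), int((~a).sum())], [int(b.sum()), int((~b).sum())]]
        _, p = stats.fisher_exact(table)
        sa, sb = a.mean(), b.mean()
        test = "fisher-exact"
    else:
        vals = cohort[cohort["stage"] == stage].set_index("participant")[metric]
        a = vals.reindex(gl_ids).dropna()
        b = vals.reindex(ngl_ids).dropna()
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"not enough observations of {metric!r} per group")
        res = stats.ttest_ind(a, b, equal_var=False)
        p = float(res.pvalue)
        sa, sb = a.mean(), b.mean()
        test = "welch-t"
    diff = float(sa - sb)
    direction = "gain-loss higher" if diff > 0 else ("gain-loss lower" if diff < 0 else "equal")
    return SubgroupComparison(
        metric, "gain-loss", "not gain-loss", len(a), len(b),
        float(sa), float(sb), diff, direction, test, float(p),
    )


def proportion_report(count: int, total: int) -> int:
    """Percent of total, rounded half-up to an integer."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must be between 0 and total")
    return int(math.floor(100.0 * count / total + 0.5))


def volume_summary(cohort: pd.DataFrame) -> dict:
    """Stage means/SDs, paired change, and both percent-change headlines.

    The headline percent is the ratio-of-means convention, 100 x mean
    change / mean early volume; the mean of per-participant percent changes
    is also reported.
    """
    vols = cohort.pivot_table(
        index="participant", columns="stage", values="liver_volume_cm3", aggfunc="first"
    )
    paired = vols[["early", "late"]].dropna()
    diff = paired["late"] - paired["early"]
    mean_diff, sd_diff, t, p = paired_test(paired["early"], paired["late"])
    out = {
        "n": len(paired),
        "early_mean": float(paired["early"].mean()),
        "early_sd": float(paired["early"].std(ddof=1)),
        "late_mean": float(paired["late"].mean()),
        "late_sd": float(paired["late"].std(ddof=1)),
        "change_mean": float(mean_diff),
        "change_sd": float(sd_diff),
        "paired_t": float(t),
        "paired_p": float(p),
        "headline_percent": round(100.0 * diff.mean() / paired["early"].mean()),
        "mean_of_percent_changes": float((100.0 * diff / paired["early"]).mean()),
    }
    if "postwean" in vols.columns:
        pw = vols[["late", "postwean"]].dropna()
        if len(pw) >= 2:
            m, s, t2, p2 = paired_test(pw["late"], pw["postwean"])
            out.update(
                postwean_n=len(pw), postwean_change_mean=m, postwean_change_sd=s,
                postwean_paired_t=t2, postwean_paired_p=p2,
            )
    return out


def make_report(cohort: pd.DataFrame, out_dir: str | Path) -> Path:
    """Write the correlation table, subgroup summary, and a Markdown report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    battery = correlation_battery(cohort)
    corr_df = pd.DataFrame(
        [
            {"variable": c.variable, "method": c.method, "n": c.n,
             "r": round(c.r, 3), "p": round(c.p, 3)}
            for c in battery
        ]
    )
    corr_df.to_csv(out / "correlations.csv", index=False)

    summ = volume_summary(cohort)
    labels = pattern_labels(cohort)
    defined = labels[labels["pattern"] != "undefined"]

    lines = ["# Cohort report", "", "## Liver volume by stage", ""]
    lines.append(
        f"- early: {summ['early_mean']:.0f} ± {summ['early_sd']:.1f} cm³ (n = {summ['n']})"
    )
    lines.append(f"- late: {summ['late_mean']:.0f} ± {summ['late_sd']:.1f} cm³")
    lines.append(
        f"- change: {summ['change_mean']:.0f} ± {summ['change_sd']:.0f} cm³ "
        f"({summ['headline_percent']}%), paired t p = {summ['paired_p']:.2g}"
    )
    n_all = cohort["participant"].nunique()
    counts = (
        cohort.groupby("participant")["pregnancy_class"].first().value_counts()
        if "pregnancy_class" in cohort
        else labels["pregnancy_change"].value_counts()
    )
    lines += ["", "## Pregnancy change classes", ""]
    for cls in ("gain", "no-change", "loss"):
        c = int(counts.get(cls, 0))
        lines.append(f"- {cls}: {c}/{n_all} ({proportion_report(c, n_all)}%)")

    lines += ["", "## Correlation battery (change vs liver-volume change)", ""]
    lines.append("| variable | method | n | r | p |")
    lines.append("|---|---|---|---|---|")
    for c in battery:
        lines.append(f"| {c.variable} | {c.method} | {c.n} | {c.r:.3f} | {c.p:.3f} |")

    if len(defined):
        n_gl = int((defined["pattern"] == "gain-loss").sum())
        lines += ["", "## Postwean pattern subgroups", ""]
        lines.append(
            f"- gain-loss: {n_gl}/{len(defined)} "
            f"({proportion_report(n_gl, len(defined))}%) of completers"
        )
        sub_rows = []
        for metric in ("egp_umol_kg_min", "rd_mg_kg_min", "hypertension"):
            try:
                s = subgroup_comparison(cohort, labels, metric)
            except ValueError:
                continue
            sub_rows.append(s)
            lines.append(
                f"- {metric}: gain-loss {s.summary_a:.3g} vs not-gain-loss "
                f"{s.summary_b:.3g} ({s.direction}), {s.test} p = {s.p:.3f}"
            )
        if sub_rows:
            pd.DataFrame([s.__dict__ for s in sub_rows]).to_csv(
                out / "subgroups.csv", index=False
            )

    report = out / "report.md"
    report.write_text("\n".join(lines) + "\n")
    return report
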