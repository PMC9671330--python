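"""Biomarker-change characterization and nonparametric testing.

Per-pair changes Delta_u = u_counterfactual - u_factual for each
controllable biomarker are summarised by patient group (female/male x
hypertensive/non-hypertensive) as median (P25; P75), then tested:
Lilliefors for normality of each change distribution, Wilcoxon
signed-rank for factual-vs-counterfactual shifts within a group,
Wilcoxon rank-sum for between-group differences, with Bonferroni
correction over the biomarker family at alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors as _sm_lilliefors

from .schema import CohortSchema, GROUP_LABELS
from .search import CounterfactualPair

ALPHA_DEFAULT = 0.05


@dataclass(frozen=True)
class TestReport:
    test: str
    groups: tuple[str, ...]
    biomarker: str
    statistic: float
    p_value: float
    reject: bool | None = None  # set after family-level adjustment


def compute_deltas(
    pairs: list[CounterfactualPair], schema: CohortSchema
) -> pd.DataFrame:
    """One row per available pair: group plus per-biomarker change (native
    units)."""
    ctrl = schema.controllable
    idx = schema.indices_of(ctrl)
    rows = []
    for p in pairs:
        if not p.available:
            continue
        row = {"factual_id": p.factual_id, "group": p.group}
        for name, j in zip(ctrl, idx):
            row[name] = p.delta[j]
        rows.append(row)
    return pd.DataFrame(rows, columns=["factual_id", "group", *ctrl])


def summarize_groups(deltas: pd.DataFrame) -> pd.DataFrame:
    """Median (P25; P75) of each biomarker change per group.

    Linear-interpolation percentiles; groups absent from the data are
    omitted rather than reported as zero change.
    """
    biomarkers = [c for c in deltas.columns if c not in ("factual_id", "group")]
    rows = []
    for grp in GROUP_LABELS:
        sub = deltas[deltas["group"] == grp]
        if sub.empty:
            continue
        for b in biomarkers:
            v = sub[b].to_numpy(dtype=float)
            p25, med, p75 = np.percentile(v, [25, 50, 75])
            rows.append(
                {"group": grp, "biomarker": b, "n": len(v),
                 "median": med, "p25": p25, "p75": p75}
            )
    return pd.DataFrame(rows)


def format_summary_table(summary: pd.DataFrame) -> pd.DataFrame:
    """Pivot to the group x biomarker layout with 'median (P25; P75)' cells."""
    cells = summary.assign(
        cell=[
            f"{m:.2f} ({lo:.2f}; {hi:.2f})"
            for m, lo, hi in zip(summary["median"], summary["p25"], summary["p75"])
        ]
    )
    return cells.pivot(index="group", columns="biomarker", values="cell")


def lilliefors_normality(sample: np.ndarray, biomarker: str = "", group: str = "") -> TestReport:
    """Kolmogorov-Smirnov test against a normal with estimated moments,
    Lilliefors-corrected p-value."""
    sample = np.asarray(sample, dtype=float)
    if sample.size < 4:
        raise ValueError("Lilliefors test needs at least 4 observations")
    if np.ptp(sample) == 0:
        raise ValueError("degenerate constant sample")
    stat, p = _sm_lilliefors(sample, dist="norm")
    return TestReport("lilliefors", (group,), biomarker, float(stat), float(p))


def paired_signed_rank(
    factual_values: np.ndarray,
    counterfactual_values: np.ndarray,
    biomarker: str = "",
    group: str = "",
) -> TestReport:
    """Two-sided Wilcoxon signed-rank on paired differences.

    Zero differences are dropped; the exact null distribution is used for
    small samples without ties, the tie-corrected normal approximation
    otherwise (scipy's auto rule).
    """
    x = np.asarray(factual_values, dtype=float)
    y = np.asarray(counterfactual_values, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = y - x
    nz = d[d != 0]
    if nz.size == 0:
        raise ValueError("all paired differences are zero")
    if nz.size < 5:
        raise ValueError("need at least 5 non-zero differences")
    stat, p = stats.wilcoxon(nz, zero_method="wilcox", alternative="two-sided",
                             method="auto")
    return TestReport(
        "wilcoxon_signed_rank", (group,), biomarker, float(stat), float(p)
    )


def rank_sum_between_groups(
    deltas_a: np.ndarray,
    deltas_b: np.ndarray,
    biomarker: str = "",
    groups: tuple[str, str] = ("A", "B"),
) -> TestReport:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) between two delta samples."""
    a = np.asarray(deltas_a, dtype=float)
    b = np.asarray(deltas_b, dtype=float)
    if a.size < 4 or b.size < 4:
        raise ValueError("both groups need at least 4 observations")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return TestReport("wilcoxon_rank_sum", groups, biomarker, float(stat), float(p))


def bonferroni(p_values, alpha: float = ALPHA_DEFAULT) -> list[bool]:
    """Reject H0_i iff p_i <= alpha / m for a family of m tests."""
    p = list(p_values)
    if not p:
        raise ValueError("empty p-value family")
    thr = alpha / len(p)
    return [pi <= thr for pi in p]


def characterize(
    pairs: list[CounterfactualPair],
    schema: CohortSchema,
    alpha: float = ALPHA_DEFAULT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full pipeline: delta summary table plus the test table.

    Within each group the signed-rank tests over the biomarker family are
    Bonferroni-corrected together; between-group (HTN vs noHTN, within each
    sex) rank-sum tests are corrected per sex.  Normality screening with
    Lilliefors is reported for every group x biomarker with n >= 4.
    """
    deltas = compute_deltas(pairs, schema)
    summary = summarize_groups(deltas)
    biomarkers = [c for c in deltas.columns if c not in ("factual_id", "group")]

    reports: list[dict] = []

    for grp in GROUP_LABELS:
        sub = deltas[deltas["group"] == grp]
        if sub.empty:
            continue
        # normality screen
        for b in biomarkers:
            v = sub[b].to_numpy(dtype=float)
            if v.size >= 4 and np.ptp(v) > 0:
                r = lilliefors_normality(v, b, grp)
                reports.append({**r.__dict__, "family": f"lilliefors:{grp}",
                                "reject": bool(r.p_value <= alpha)})
        # paired shift per biomarker, corrected within the group
        fam = []
        for b in biomarkers:
            v = sub[b].to_numpy(dtype=float)
            try:
                r = paired_signed_rank(np.zeros_like(v), v, b, grp)
            except ValueError:
                continue
            fam.append(r)
        if fam:
            rej = bonferroni([r.p_value for r in fam], alpha)
            for r, dec in zip(fam, rej):
                reports.append({**r.__dict__, "family": f"signed_rank:{grp}",
                                "reject": bool(dec)})

    for sex, (g1, g2) in (("F", ("F_HTN", "F_noHTN")), ("M", ("M_HTN", "M_noHTN"))):
        a = deltas[deltas["group"] == g1]
        b_ = deltas[deltas["group"] == g2]
        if len(a) < 4 or len(b_) < 4:
            continue
        fam = []
        for b in biomarkers:
            fam.append(
                rank_sum_between_groups(
                    a[b].to_numpy(float), b_[b].to_numpy(float), b, (g1, g2)
                )
            )
        rej = bonferroni([r.p_value for r in fam], alpha)
        for r, dec in zip(fam, rej):
            reports.append({**r.__dict__, "family": f"rank_sum:{sex}",
                            "reject": bool(dec)})

    tests = pd.DataFrame(reports)
    if not tests.empty:
        tests["groups"] = tests["groups"].map(lambda g: "|".join(g))
    return summary, tests
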