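"""Cohort comparison statistics.

Implements the group-comparison toolbox used across the quantification
panels: normality pre-tests (Shapiro–Wilk plus Lilliefors-corrected
Kolmogorov–Smirnov), Kruskal–Wallis with Dunn's post hoc comparisons,
one-/two-way ANOVA with Tukey HSD, per-condition Welch t-tests with the
Benjamini–Krieger–Yekutieli two-stage step-up FDR correction, two-sided
Mann–Whitney (exact enumeration at small n, tie-corrected normal
approximation otherwise), hair-cell counts per region, and the onset
analysis that locates the first age at which two genotypes separate.

Conventions: α = 0.05 and q = 0.05 by default, configurable per call; NA
values are excluded listwise per test; Dunn's pairwise p-values are
Bonferroni-adjusted over all pairs; two-way ANOVA uses type-II sums of
squares so mildly unbalanced designs remain interpretable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "normality_check",
    "kruskal_dunn",
    "anova_tukey",
    "multiple_t_bky",
    "mann_whitney",
    "count_cells_per_region",
    "onset_analysis",
    "group_summaries",
]

#: largest number of group-label assignments enumerated for the exact
#: Mann-Whitney path; above this the tie-corrected normal approximation is used
_EXACT_MW_MAX_COMBINATIONS = 200_000

#: per-arm size up to which the exact Mann-Whitney enumeration is preferred
_EXACT_MW_MAX_N = 8


@dataclass
class TestResult:
    """Outcome of one statistical test with provenance.

    ``comparisons`` holds per-pair (or per-condition) rows with raw and
    adjusted p-values; ``summaries`` holds per-group n / mean / SD.
    """

    name: str
    statistic: float
    pvalue: float
    comparisons: pd.DataFrame | None = None
    summaries: pd.DataFrame | None = None
    details: dict = field(default_factory=dict)


def _clean(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    return arr[np.isfinite(arr)]


def group_summaries(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    rows = []
    for name, values in groups.items():
        v = _clean(values)
        rows.append(
            {
                "group": name,
                "n": len(v),
                "mean": v.mean() if len(v) else math.nan,
                "sd": v.std(ddof=1) if len(v) > 1 else math.nan,
            }
        )
    return pd.DataFrame(rows, columns=["group", "n", "mean", "sd"])


# ---------------------------------------------------------------------------
# normality pre-tests

def normality_check(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> pd.DataFrame:
    """Shapiro–Wilk and Kolmogorov–Smirnov (Lilliefors) normality tests.

    A group "passes" when both tests give p > ``alpha``.  Groups with n < 3
    or degenerate (constant) values are reported as NA / failed with a
    reason rather than raising.
    """
    rows = []
    for name, values in groups.items():
        v = _clean(values)
        row = {
            "group": name, "n": len(v),
            "shapiro_p": math.nan, "ks_p": math.nan,
            "passed": False, "reason": "",
        }
        if len(v) < 3:
            row["reason"] = "n < 3: normality tests undefined"
            row["passed"] = None
        elif np.ptp(v) == 0:
            row["reason"] = "degenerate: all values identical"
        else:
            row["shapiro_p"] = sps.shapiro(v).pvalue
            # KS against a normal with estimated parameters requires the
            # Lilliefors correction; the plain KS test would be anticonservative
            _, row["ks_p"] = lilliefors(v, dist="norm")
            row["passed"] = bool(row["shapiro_p"] > alpha and row["ks_p"] > alpha)
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["group", "n", "shapiro_p", "ks_p", "passed", "reason"]
    )


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn

def _dunn_posthoc(
    groups: Mapping[str, np.ndarray], adjust: str = "bonferroni"
) -> pd.DataFrame:
    """Dunn's rank-based pairwise z-tests after Kruskal–Wallis.

    Uses mean ranks of the pooled sample with the standard tie correction
    Σ(t³ − t) / (12 (N − 1)) in the variance, and Bonferroni adjustment over
    all pairs (the convention of common interactive analysis software).
    """
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes, start = {}, {}, 0
    for g in names:
        n_g = len(groups[g])
        mean_ranks[g] = ranks[start:start + n_g].mean()
        sizes[g] = n_g
        start += n_g

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12.0 - tie_term

    m = len(names) * (len(names) - 1) // 2
    rows = []
    for g1, g2 in combinations(names, 2):
        se = math.sqrt(base_var * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
        z = (mean_ranks[g1] - mean_ranks[g2]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        rows.append(
            {
                "group_a": g1, "group_b": g2, "z": z,
                "p_raw": p_raw, "p_adjusted": min(1.0, p_raw * m),
                "method": f"dunn-{adjust}",
            }
        )
    return pd.DataFrame(rows)


def kruskal_dunn(groups: Mapping[str, Sequence[float]]) -> TestResult:
    """Kruskal–Wallis H test with Dunn's pairwise post hoc comparisons.

    Requires at least three groups of which at least two are nonempty.
    When every observation is identical the H statistic degenerates (zero
    tie-corrected variance); this is reported as H = 0, p = 1 with a
    ``degenerate`` flag instead of an error.
    """
    cleaned = {name: _clean(v) for name, v in groups.items()}
    if len(cleaned) < 3:
        raise ValueError("kruskal_dunn expects >= 3 groups (use mann_whitney for 2)")
    nonempty = {name: v for name, v in cleaned.items() if len(v) > 0}
    if len(nonempty) < 2:
        raise ValueError("need at least 2 nonempty groups")

    pooled = np.concatenate(list(nonempty.values()))
    if np.ptp(pooled) == 0:
        return TestResult(
            name="kruskal-wallis+dunn", statistic=0.0, pvalue=1.0,
            summaries=group_summaries(nonempty),
            details={"degenerate": True, "reason": "all observations identical"},
        )

    h, p = sps.kruskal(*nonempty.values())
    return TestResult(
        name="kruskal-wallis+dunn", statistic=float(h), pvalue=float(p),
        comparisons=_dunn_posthoc(nonempty),
        summaries=group_summaries(nonempty),
        details={"degenerate": False, "tie_corrected": True},
    )


# ---------------------------------------------------------------------------
# ANOVA + Tukey

def anova_tukey(
    table: pd.DataFrame,
    value: str,
    factors: Sequence[str],
    alpha: float = 0.05,
) -> TestResult:
    """One- or two-way ANOVA with Tukey HSD pairwise comparisons.

    Two-way designs are fitted with interaction and type-II sums of squares
    (equivalent to the classical decomposition when balanced, well-defined
    under mild attrition).  Tukey HSD is run over the levels of each factor;
    for a one-way design that is the usual post hoc family.
    """
    if not 1 <= len(factors) <= 2:
        raise ValueError("factors must name 1 or 2 columns")
    df = table.dropna(subset=[value, *factors]).copy()
    for f in factors:
        if df[f].nunique() < 2:
            raise ValueError(f"factor {f!r} needs >= 2 levels")

    terms = [f"C(Q('{f}'))" for f in factors]
    formula = f"Q('{value}') ~ " + " + ".join(terms)
    if len(factors) == 2:
        formula += f" + {terms[0]}:{terms[1]}"
    try:
        fit = ols(formula, data=df).fit()
        anova = anova_lm(fit, typ=2)
    except Exception as exc:  # singular design matrices, empty cells
        raise ValueError(f"ANOVA design could not be fitted: {exc}") from exc
    if not np.isfinite(anova["F"].iloc[0]):
        raise ValueError("singular ANOVA design (no residual degrees of freedom?)")

    effects = {}
    for term, row in anova.iterrows():
        if term == "Residual":
            continue
        label = (
            term.replace("C(Q('", "").replace("'))", "").replace(":", " x ")
        )
        effects[label] = {"F": float(row["F"]), "p": float(row["PR(>F)"])}

    comp_frames = []
    for f in factors:
        hsd = pairwise_tukeyhsd(df[value].to_numpy(), df[f].astype(str).to_numpy(),
                                alpha=alpha)
        res = pd.DataFrame(
            hsd.summary().data[1:], columns=hsd.summary().data[0]
        )
        comp_frames.append(
            pd.DataFrame(
                {
                    "factor": f,
                    "group_a": res["group1"],
                    "group_b": res["group2"],
                    "meandiff": res["meandiff"].astype(float),
                    "p_adjusted": res["p-adj"].astype(float),
                    "method": "tukey-hsd",
                }
            )
        )

    first = factors[0].replace(":", " x ")
    groups = {name: sub[value].to_numpy() for name, sub in df.groupby(factors[0])}
    return TestResult(
        name=f"{len(factors)}-way anova+tukey",
        statistic=effects[first]["F"],
        pvalue=effects[first]["p"],
        comparisons=pd.concat(comp_frames, ignore_index=True),
        summaries=group_summaries(groups),
        details={"effects": effects, "sum_sq_type": "II"},
    )


# ---------------------------------------------------------------------------
# Welch t per condition + BKY two-stage step-up FDR

def multiple_t_bky(
    table: pd.DataFrame,
    value: str,
    condition: str,
    group: str,
    q: float = 0.05,
) -> pd.DataFrame:
    """Per-condition Welch t-tests with two-stage step-up FDR correction.

    Each condition level (e.g. an age) contributes one two-sided Welch
    (unequal-variance) t-test between the two groups.  Raw p-values are then
    corrected across conditions with the Benjamini–Krieger–Yekutieli
    two-stage linear step-up procedure at FDR level ``q``; ``discovery``
    flags the conditions surviving it.  Conditions with fewer than two
    values in either group are reported as NA and excluded from the family.
    """
    levels = list(dict.fromkeys(table[condition]))
    group_names = sorted(set(table[group].dropna()))
    if len(group_names) != 2:
        raise ValueError(f"need exactly two groups, got {group_names}")

    rows = []
    for level in levels:
        sub = table[table[condition] == level]
        a = _clean(sub.loc[sub[group] == group_names[0], value])
        b = _clean(sub.loc[sub[group] == group_names[1], value])
        row = {
            "condition": level,
            "n_a": len(a), "n_b": len(b),
            "mean_a": a.mean() if len(a) else math.nan,
            "mean_b": b.mean() if len(b) else math.nan,
            "t": math.nan, "p_raw": math.nan,
        }
        if len(a) >= 2 and len(b) >= 2:
            t, p = sps.ttest_ind(a, b, equal_var=False)
            row["t"], row["p_raw"] = float(t), float(p)
        rows.append(row)
    out = pd.DataFrame(rows)

    valid = out["p_raw"].notna()
    out["q_value"] = math.nan
    out["discovery"] = pd.array([None] * len(out), dtype="boolean")
    if valid.any():
        reject, q_adj, _, _ = multipletests(
            out.loc[valid, "p_raw"], alpha=q, method="fdr_tsbh"
        )
        out.loc[valid, "q_value"] = np.minimum(q_adj, 1.0)
        out.loc[valid, "discovery"] = reject
    out.attrs["method"] = "welch-t + two-stage step-up (BKY)"
    out.attrs["q"] = q
    out.attrs["groups"] = group_names
    return out


# ---------------------------------------------------------------------------
# Mann-Whitney

def _mw_u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for sample a: #(a_i > b_j) + 0.5 #(a_i == b_j), via pooled ranks."""
    n1 = len(a)
    ranks = sps.rankdata(np.concatenate([a, b]))
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)


def _mw_exact_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided p by full enumeration of group-label assignments.

    Handles ties correctly because U is recomputed from pooled ranks for
    every assignment; the permutation distribution of U is symmetric about
    n₁n₂/2 under exchangeability.
    """
    pooled = np.concatenate([a, b])
    n1, n = len(a), len(a) + len(b)
    ranks = sps.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2.0
    n1n2 = n1 * (n - n1)
    lo = min(u_obs, n1n2 - u_obs)
    hi = max(u_obs, n1n2 - u_obs)
    count = 0
    total = 0
    eps = 1e-9
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - offset
        if u <= lo + eps or u >= hi - eps:
            count += 1
        total += 1
    return min(1.0, count / total)


def mann_whitney(a, b, *, exact: bool | None = None) -> TestResult:
    """Two-sided Mann–Whitney U test.

    By default the exact null distribution is enumerated when both arms have
    ≤ 8 observations (the enumeration recomputes U from pooled ranks per
    assignment, so ties are handled exactly); larger samples use the
    tie-corrected normal approximation with continuity correction.
    ``exact`` forces one path.
    """
    a = _clean(a)
    b = _clean(b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both arms must be nonempty")

    u = _mw_u_statistic(a, b)
    n_comb = math.comb(len(a) + len(b), len(a))
    if exact is None:
        exact = (
            min(len(a), len(b)) <= _EXACT_MW_MAX_N
            and n_comb <= _EXACT_MW_MAX_COMBINATIONS
        )
    if exact and n_comb > _EXACT_MW_MAX_COMBINATIONS:
        raise ValueError("sample too large for exact enumeration")

    if exact:
        p = _mw_exact_p(a, b, u)
        method = "exact-enumeration"
    else:
        _, p = sps.mannwhitneyu(a, b, alternative="two-sided",
                                method="asymptotic", use_continuity=True)
        p = float(p)
        method = "normal-approximation-tie-corrected"
    return TestResult(
        name="mann-whitney", statistic=u, pvalue=p,
        summaries=group_summaries({"a": a, "b": b}),
        details={"method": method, "n_a": len(a), "n_b": len(b)},
    )


# ---------------------------------------------------------------------------
# region counts

def count_cells_per_region(
    positions: Mapping[str, Sequence[float]] | Sequence[float],
    region_center: float,
    region_span: float = 200.0,
) -> dict[str, int]:
    """Count cells per type whose axial position lies in a tiling region.

    The region is the half-open interval
    ``[center − span/2, center + span/2)`` so that a cell sitting exactly on
    a boundary is counted once when regions tile the cochlear axis.
    ``positions`` is either a mapping of cell type (e.g. OHC / IHC) to
    positions in μm, or a bare position sequence (counted under type "all").
    """
    if region_span <= 0:
        raise ValueError("region_span must be positive")
    if not isinstance(positions, Mapping):
        positions = {"all": positions}
    lo = region_center - region_span / 2.0
    hi = region_center + region_span / 2.0
    return {
        ctype: int(np.sum((np.asarray(pos, dtype=float) >= lo)
                          & (np.asarray(pos, dtype=float) < hi)))
        for ctype, pos in positions.items()
    }


# ---------------------------------------------------------------------------
# onset analysis

def onset_analysis(
    table: pd.DataFrame,
    value: str,
    age: str = "age",
    group: str = "group",
    q: float = 0.05,
) -> tuple[pd.DataFrame, object]:
    """Locate the first age at which two genotypes separate.

    Runs per-age Welch t-tests with the two-stage step-up FDR correction
    (:func:`multiple_t_bky`) across ages and reports the earliest age, in
    table order, flagged as a discovery (None if no age separates).
    """
    result = multiple_t_bky(table, value=value, condition=age, group=group, q=q)
    discovered = result.loc[result["discovery"].fillna(False).astype(bool),
                            "condition"]
    onset = discovered.iloc[0] if len(discovered) else None
    result.attrs["onset_age"] = onset
    return result, onset
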