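"""Nonparametric group statistics for staged cohort features.

The comparison machinery mirrors a lifespan study design: subjects are
binned into five Erikson stages by age, per-stage normality is screened
with Shapiro-Wilk (any rejection routes the analysis to rank-based tests),
stagewise comparisons use the tie-corrected Kruskal-Wallis H with Dunn's
post hoc z-tests under Benjamini-Hochberg FDR correction, and sex contrasts
use the Mann-Whitney U.  The frustration / negative-density relation is
modelled with nested polynomial OLS fits compared by partial F tests, plus
a stage x density interaction (ANCOVA-style) partial F test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "STAGES",
    "STAGE_BOUNDS",
    "TestResult",
    "NormalityGateResult",
    "PolyModelSelection",
    "assign_stage",
    "bh_adjust",
    "normality_gate",
    "kruskal_wallis",
    "dunn_posthoc",
    "mann_whitney",
    "fit_poly_select",
    "fit_poly_and_select",
    "interaction_test",
]

STAGES: tuple[str, ...] = (
    "child",
    "adolescent",
    "early_adult",
    "middle_adult",
    "late_adult",
)

# Half-open age bins; a shared boundary age belongs to the older stage.
STAGE_BOUNDS: tuple[float, ...] = (6.0, 12.0, 18.0, 40.0, 65.0)


def assign_stage(age: float) -> str:
    """Map an age in years to its Erikson lifespan stage.

    Bins are [6,12), [12,18), [18,40), [40,65), [65, inf); ages below 6 are
    outside the study design and raise.
    """
    if age < STAGE_BOUNDS[0]:
        raise ValueError(f"age {age} below the study's minimum of {STAGE_BOUNDS[0]}")
    idx = int(np.searchsorted(STAGE_BOUNDS, age, side="right")) - 1
    return STAGES[idx]


@dataclass(frozen=True)
class TestResult:
    """A single hypothesis-test outcome (H, U, F, W ... statistics)."""

    name: str
    statistic: float
    pvalue: float
    df: float | tuple[float, float] | None = None
    group_sizes: tuple[int, ...] = ()
    extra: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"p-value {self.pvalue} outside [0, 1]")


@dataclass(frozen=True)
class NormalityGateResult:
    """Per-group Shapiro-Wilk p-values and the parametric/nonparametric call."""

    p_by_group: Mapping[str, float]
    nonparametric: bool
    degenerate_groups: tuple[str, ...] = ()


def _as_groups(values_by_group: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_group.items()}
    for name, v in groups.items():
        if v.size == 0:
            raise ValueError(f"group {name!r} is empty")
    return groups


def normality_gate(
    values_by_group: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> NormalityGateResult:
    """Shapiro-Wilk per group; any rejection sends the analysis nonparametric."""
    groups = _as_groups(values_by_group)
    p_by_group: dict[str, float] = {}
    degenerate: list[str] = []
    for name, v in groups.items():
        if v.size < 3:
            raise ValueError(f"group {name!r} has n={v.size} < 3")
        if np.ptp(v) == 0.0:
            # constant sample: W is undefined; treat as a (degenerate) rejection
            degenerate.append(name)
            p_by_group[name] = 0.0
            continue
        p_by_group[name] = float(sps.shapiro(v).pvalue)
    nonparametric = any(p <= alpha for p in p_by_group.values())
    return NormalityGateResult(p_by_group, nonparametric, tuple(degenerate))


def kruskal_wallis(values_by_group: Mapping[str, Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with chi-square p, df = k - 1."""
    groups = _as_groups(values_by_group)
    if len(groups) < 2:
        raise ValueError("Kruskal-Wallis needs at least 2 groups")
    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0.0:
        # every observation tied: no rank information, H = 0 by convention
        return TestResult(
            name="kruskal_wallis",
            statistic=0.0,
            pvalue=1.0,
            df=float(len(groups) - 1),
            group_sizes=tuple(v.size for v in groups.values()),
            extra={"degenerate": 1.0},
        )
    h, p = sps.kruskal(*groups.values())
    return TestResult(
        name="kruskal_wallis",
        statistic=float(h),
        pvalue=float(p),
        df=float(len(groups) - 1),
        group_sizes=tuple(v.size for v in groups.values()),
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (FDR control)."""
    _, p_adj, _, _ = multipletests(np.asarray(p_values, dtype=float), method="fdr_bh")
    return p_adj


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts**3 - counts))


def dunn_posthoc(
    values_by_group: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Dunn's pairwise z-tests after Kruskal-Wallis, BH-adjusted.

    Uses the pooled tie-corrected rank variance
    ``(N(N+1)/12 - T/(12(N-1))) * (1/n_i + 1/n_j)`` with
    ``T = sum(t^3 - t)`` over tie groups.  P-values are two-sided and
    adjusted across all unordered pairs by Benjamini-Hochberg step-up.
    """
    groups = _as_groups(values_by_group)
    if len(groups) < 3:
        raise ValueError("Dunn's test needs >= 3 groups; use mann_whitney for 2")
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)
    mean_ranks: dict[str, float] = {}
    start = 0
    for g in names:
        n_g = groups[g].size
        mean_ranks[g] = float(ranks[start : start + n_g].mean())
        start += n_g
    var_base = n_total * (n_total + 1) / 12.0 - _tie_term(pooled) / (12.0 * (n_total - 1))
    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / groups[a].size + 1.0 / groups[b].size))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "z": float(z),
                "p_raw": float(2.0 * sps.norm.sf(abs(z))),
            }
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p_raw"])
    table["significant"] = table["p_adj"] <= alpha
    return table


def mann_whitney(
    values_a: Sequence[float], values_b: Sequence[float]
) -> TestResult:
    """Two-sided Mann-Whitney U test between two samples.

    Both orientations of the statistic are reported (``u_a`` for the first
    sample, ``u_b = n_a * n_b - u_a``); the headline ``statistic`` is
    ``u_a``.  The p-value is exact for small tie-free samples and uses the
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (max(a.size, b.size) <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    u_a = float(res.statistic)
    return TestResult(
        name="mann_whitney",
        statistic=u_a,
        pvalue=float(res.pvalue),
        group_sizes=(a.size, b.size),
        extra={"u_a": u_a, "u_b": float(a.size * b.size - u_a)},
    )


@dataclass(frozen=True)
class PolyModelSelection:
    """Nested polynomial OLS fits of y on x with partial-F model selection.

    ``coefficients[d]`` holds the degree-d fit in ascending power order
    (intercept first); ``f_tests[(d_small, d_big)]`` holds the partial F
    statistic and p-value of adding the higher-order terms.
    """

    coefficients: Mapping[int, np.ndarray]
    coefficient_se: Mapping[int, np.ndarray]
    rss: Mapping[int, float]
    df_resid: Mapping[int, float]
    f_tests: Mapping[tuple[int, int], tuple[float, float]]
    selected_degree: int
    n_obs: int


def fit_poly_select(
    x: Sequence[float],
    y: Sequence[float],
    max_degree: int = 3,
    alpha: float = 0.05,
) -> PolyModelSelection:
    """Fit polynomial degrees 1..max_degree by OLS and select by partial F.

    Selection steps up from the linear fit: the quadratic is kept only if it
    improves significantly on the linear, and the cubic only if it improves
    on the quadratic (equivalent to a likelihood-ratio test under Gaussian
    errors).
    """
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < max_degree + 7:
        raise ValueError(f"need at least {max_degree + 7} observations")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant; polynomial fit is rank deficient")
    coefficients, ses, rss, df_resid = {}, {}, {}, {}
    fits = {}
    for d in range(1, max_degree + 1):
        design = sm.add_constant(np.vander(x, d + 1, increasing=True)[:, 1:])
        fit = sm.OLS(y, design).fit()
        fits[d] = fit
        coefficients[d] = np.asarray(fit.params)
        ses[d] = np.asarray(fit.bse)
        rss[d] = float(fit.ssr)
        df_resid[d] = float(fit.df_resid)
    # a lower-degree fit whose residual is at rounding level is already
    # saturated: higher-order terms only chase floating-point noise
    tss = float(((y - y.mean()) ** 2).sum())
    rss_floor = 1e-12 * max(tss, 1.0)
    f_tests: dict[tuple[int, int], tuple[float, float]] = {}
    for d in range(1, max_degree):
        delta_df = 1.0
        if rss[d] <= rss_floor:
            f_tests[(d, d + 1)] = (0.0, 1.0)
            continue
        denom = rss[d + 1] / df_resid[d + 1] if rss[d + 1] > rss_floor else 0.0
        if denom == 0.0:
            f_stat, p = float("inf"), 0.0
        else:
            f_stat = (rss[d] - rss[d + 1]) / delta_df / denom
            f_stat = max(f_stat, 0.0)
            p = float(sps.f.sf(f_stat, delta_df, df_resid[d + 1]))
        f_tests[(d, d + 1)] = (float(f_stat), p)
    selected = 1
    for d in range(1, max_degree):
        if f_tests[(d, d + 1)][1] <= alpha:
            selected = d + 1
        else:
            break
    return PolyModelSelection(
        coefficients=coefficients,
        coefficient_se=ses,
        rss=rss,
        df_resid=df_resid,
        f_tests=f_tests,
        selected_degree=selected,
        n_obs=int(x.size),
    )


def fit_poly_and_select(
    table: pd.DataFrame,
    by_stage: bool = False,
    x_col: str = "neg_density",
    y_col: str = "frustration",
    max_degree: int = 3,
    alpha: float = 0.05,
) -> PolyModelSelection | dict[str, PolyModelSelection]:
    """Model frustration on negative-link density, pooled or per stage."""
    if by_stage:
        return {
            stage: fit_poly_select(
                sub[x_col], sub[y_col], max_degree=max_degree, alpha=alpha
            )
            for stage, sub in table.groupby("stage", observed=True)
        }
    return fit_poly_select(table[x_col], table[y_col], max_degree=max_degree, alpha=alpha)


def interaction_test(
    table: pd.DataFrame,
    degree: int = 2,
    x_col: str = "neg_density",
    y_col: str = "frustration",
) -> TestResult:
    """Stage x density interaction via a partial F test on nested OLS models.

    Compares ``y ~ poly(x, degree) + stage`` against the same model with
    stage-specific polynomial terms; a significant F means the stagewise
    regression curves differ.
    """
    import statsmodels.api as sm

    stages = table["stage"].unique()
    if len(stages) < 2:
        raise ValueError("interaction test needs at least 2 stages")
    counts = table["stage"].value_counts()
    if (counts < degree + 2).any():
        small = counts[counts < degree + 2].index.tolist()
        raise ValueError(f"stages {small} have fewer than degree+2 subjects")
    x = np.asarray(table[x_col], dtype=float)
    y = np.asarray(table[y_col], dtype=float)
    poly = np.vander(x, degree + 1, increasing=True)[:, 1:]
    dummies = pd.get_dummies(table["stage"], drop_first=True).to_numpy(dtype=float)
    base = np.column_stack([poly, dummies])
    inter = np.column_stack(
        [poly[:, k : k + 1] * dummies for k in range(degree)]
    )
    reduced = sm.OLS(y, sm.add_constant(base)).fit()
    full = sm.OLS(y, sm.add_constant(np.column_stack([base, inter]))).fit()
    df_num = reduced.df_resid - full.df_resid
    if full.ssr <= 0:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (reduced.ssr - full.ssr) / df_num / (full.ssr / full.df_resid)
        f_stat = max(float(f_stat), 0.0)
        p = float(sps.f.sf(f_stat, df_num, full.df_resid))
    return TestResult(
        name="stage_density_interaction",
        statistic=float(f_stat),
        pvalue=p,
        df=(float(df_num), float(full.df_resid)),
        group_sizes=tuple(int(c) for c in counts.loc[sorted(counts.index)]),
    )
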