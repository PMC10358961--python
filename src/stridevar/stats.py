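"""Statistical comparison harness for estimation strategies.

Accuracy is summarised as RMSE against the reference strategy; group
comparisons follow a normality-gated design: Shapiro-Wilk per group,
then either Welch's one-way ANOVA with omega-squared and Games-Howell
post-hoc tests, or Kruskal-Wallis with epsilon-squared and Dunn
post-hoc tests, both with Holm's correction. The two-factor analysis
(condition x strategy) runs a classical two-way ANOVA on the
parametric branch and an aligned-rank-transform two-way analysis on
the nonparametric branch, always reporting the parametric table
alongside.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

ALPHA = 0.05
BOOTSTRAP_RESAMPLES = 2000

__all__ = [
    "rmse",
    "holm_adjust",
    "normality_gate",
    "welch_anova_f",
    "one_way_compare",
    "two_way_compare",
    "evaluate_strategies",
    "OneWayResult",
    "TwoWayResult",
    "ComparisonTable",
]


def rmse(estimates: np.ndarray, reference: np.ndarray) -> float:
    """Root-mean-square difference of two paired sequences."""
    a = np.asarray(estimates, dtype=float).ravel()
    b = np.asarray(reference, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def holm_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Holm's step-down adjustment (monotone, never below the raw p)."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def normality_gate(groups: Sequence[np.ndarray], alpha: float = ALPHA) -> str:
    """Majority-rule Shapiro-Wilk gate: 'parametric' or 'nonparametric'."""
    n_normal = 0
    n_groups = 0
    for g in groups:
        g = np.asarray(g, dtype=float)
        if len(g) < 3:
            raise ValueError("normality testing needs n >= 3 per group")
        n_groups += 1
        if np.ptp(g) == 0 or sps.shapiro(g).pvalue > alpha:
            n_normal += 1
    return "parametric" if n_normal * 2 >= n_groups else "nonparametric"


# ---------------------------------------------------------------------------
# one-way comparison


def welch_anova_f(groups: Sequence[np.ndarray]) -> Tuple[float, float, float, float]:
    """Welch's heteroscedastic one-way F test: (F, df1, df2, p)."""
    k = len(groups)
    ns = np.array([len(g) for g in groups], dtype=float)
    means = np.array([np.mean(g) for g in groups])
    vars_ = np.array([np.var(g, ddof=1) for g in groups])
    if np.any(vars_ == 0):
        vars_ = np.where(vars_ == 0, 1e-30, vars_)
    w = ns / vars_
    wsum = w.sum()
    mw = np.sum(w * means) / wsum
    a = np.sum(w * (means - mw) ** 2) / (k - 1)
    b = 1.0 + (2.0 * (k - 2) / (k**2 - 1)) * np.sum((1 - w / wsum) ** 2 / (ns - 1))
    f = a / b
    df1 = k - 1
    df2 = (k**2 - 1) / (3.0 * np.sum((1 - w / wsum) ** 2 / (ns - 1)))
    p = float(sps.f.sf(f, df1, df2))
    return float(f), float(df1), float(df2), p


def _omega_squared(groups: Sequence[np.ndarray], f: float) -> float:
    """Omega-squared from the Welch F via the F-to-omega approximation."""
    n = sum(len(g) for g in groups)
    df1 = len(groups) - 1
    w2 = df1 * (f - 1.0) / (df1 * (f - 1.0) + n)
    return float(max(w2, 0.0))


def _epsilon_squared(groups: Sequence[np.ndarray], h: float) -> float:
    """Rank epsilon-squared for the Kruskal-Wallis statistic."""
    n = sum(len(g) for g in groups)
    return float(h * (n + 1) / (n**2 - 1))


def _bootstrap_ci(
    groups: Sequence[np.ndarray],
    statistic,
    rng: np.random.Generator,
    n_boot: int = BOOTSTRAP_RESAMPLES,
    level: float = 0.95,
) -> Tuple[float, float]:
    vals = []
    for _ in range(n_boot):
        resampled = [g[rng.integers(0, len(g), len(g))] for g in groups]
        try:
            vals.append(statistic(resampled))
        except Exception:
            continue
    lo, hi = np.percentile(vals, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo), float(hi)


def _games_howell(groups, labels) -> pd.DataFrame:
    """Games-Howell pairwise tests (studentized-range reference)."""
    rows = []
    k = len(groups)
    for i in range(k):
        for j in range(i + 1, k):
            a, b = np.asarray(groups[i], float), np.asarray(groups[j], float)
            na, nb = len(a), len(b)
            va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
            se = np.sqrt(va + vb)
            t = (a.mean() - b.mean()) / se
            df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
            p = float(sps.studentized_range.sf(np.abs(t) * np.sqrt(2.0), k, df))
            rows.append(
                {"group_a": labels[i], "group_b": labels[j], "statistic": float(t),
                 "df": float(df), "p_raw": p}
            )
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    return out


def _dunn(groups, labels) -> pd.DataFrame:
    """Dunn's rank-based pairwise tests with tie correction."""
    all_vals = np.concatenate([np.asarray(g, float) for g in groups])
    n = len(all_vals)
    ranks = sps.rankdata(all_vals)
    splits = np.cumsum([len(g) for g in groups])[:-1]
    group_ranks = np.split(ranks, splits)
    _, tie_counts = np.unique(all_vals, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n - 1))
    rows = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            ni, nj = len(groups[i]), len(groups[j])
            diff = group_ranks[i].mean() - group_ranks[j].mean()
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / ni + 1.0 / nj))
            z = diff / se
            p = float(2.0 * sps.norm.sf(np.abs(z)))
            rows.append(
                {"group_a": labels[i], "group_b": labels[j], "statistic": float(z),
                 "p_raw": p}
            )
    out = pd.DataFrame(rows)
    out["p_holm"] = holm_adjust(out["p_raw"].to_numpy())
    return out


@dataclass
class OneWayResult:
    branch: str
    test_name: str
    statistic: float
    df1: float
    df2: Optional[float]
    p_value: float
    effect_name: str
    effect_size: float
    effect_ci: Tuple[float, float]
    posthoc: Optional[pd.DataFrame]
    degenerate: bool = False


def one_way_compare(
    groups: Sequence[np.ndarray],
    labels: Optional[Sequence[str]] = None,
    alpha: float = ALPHA,
    posthoc: str = "auto",
    effect_ci: bool = True,
    seed: int = 0,
    branch: str = "auto",
) -> OneWayResult:
    """Normality-gated one-way comparison across the groups.

    Parametric branch: Welch's F, p, omega-squared with bootstrap CI,
    Games-Howell post-hoc with Holm correction. Nonparametric branch:
    Kruskal-Wallis chi-squared, p, epsilon-squared with bootstrap CI,
    Dunn post-hoc with Holm correction. ``posthoc`` is "auto" (only
    when the omnibus test is significant), "always" or "never".
    ``branch`` overrides the Shapiro-Wilk gate when set to
    "parametric" or "nonparametric".
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    labels = list(labels) if labels is not None else [f"g{i}" for i in range(len(groups))]
    if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
        # all groups a single identical constant: nothing to test
        return OneWayResult(
            branch="degenerate", test_name="none", statistic=np.nan, df1=np.nan,
            df2=None, p_value=1.0, effect_name="none", effect_size=0.0,
            effect_ci=(0.0, 0.0), posthoc=None, degenerate=True,
        )

    if branch == "auto":
        branch = normality_gate(groups, alpha=alpha)
    elif branch not in ("parametric", "nonparametric"):
        raise ValueError("branch must be 'auto', 'parametric' or 'nonparametric'")
    rng = np.random.default_rng(seed)
    if branch == "parametric":
        f, df1, df2, p = welch_anova_f(groups)
        eff = _omega_squared(groups, f)
        ci = (
            _bootstrap_ci(groups, lambda gs: _omega_squared(gs, welch_anova_f(gs)[0]), rng)
            if effect_ci
            else (np.nan, np.nan)
        )
        ph = None
        if posthoc == "always" or (posthoc == "auto" and p < alpha):
            ph = _games_howell(groups, labels)
        return OneWayResult(
            branch=branch, test_name="welch_anova", statistic=f, df1=df1, df2=df2,
            p_value=p, effect_name="omega2", effect_size=eff, effect_ci=ci, posthoc=ph,
        )
    h, p = sps.kruskal(*groups)
    eff = _epsilon_squared(groups, h)
    ci = (
        _bootstrap_ci(groups, lambda gs: _epsilon_squared(gs, sps.kruskal(*gs)[0]), rng)
        if effect_ci
        else (np.nan, np.nan)
    )
    ph = None
    if posthoc == "always" or (posthoc == "auto" and p < alpha):
        ph = _dunn(groups, labels)
    return OneWayResult(
        branch=branch, test_name="kruskal_wallis", statistic=float(h),
        df1=float(len(groups) - 1), df2=None, p_value=float(p),
        effect_name="epsilon2", effect_size=eff, effect_ci=ci, posthoc=ph,
    )


# ---------------------------------------------------------------------------
# two-way comparison


@dataclass
class TwoWayResult:
    branch: str
    parametric: pd.DataFrame  # classical two-way ANOVA table (always reported)
    nonparametric: Optional[pd.DataFrame]  # aligned-rank-transform table
    warnings: List[str] = field(default_factory=list)

    @property
    def primary(self) -> pd.DataFrame:
        if self.branch == "nonparametric" and self.nonparametric is not None:
            return self.nonparametric
        return self.parametric


def _two_way_anova(frame: pd.DataFrame) -> pd.DataFrame:
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    model = ols("value ~ C(factor_a) * C(factor_b)", data=frame).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(
        index={
            "C(factor_a)": "factor_a",
            "C(factor_b)": "factor_b",
            "C(factor_a):C(factor_b)": "interaction",
        }
    )
    return table


def _aligned_rank_anova(frame: pd.DataFrame) -> pd.DataFrame:
    """Aligned-rank-transform two-factor analysis.

    For each effect, the response is aligned by removing the estimated
    contributions of the other effects (cell-mean decomposition),
    ranked, and a classical factorial ANOVA is run on the ranks; only
    the row of the aligned-for effect is retained.
    """
    work = frame.copy()
    gm = work["value"].mean()
    ma = work.groupby("factor_a")["value"].transform("mean")
    mb = work.groupby("factor_b")["value"].transform("mean")
    mab = work.groupby(["factor_a", "factor_b"])["value"].transform("mean")
    resid = work["value"] - mab
    effects = {
        "factor_a": resid + ma - gm,
        "factor_b": resid + mb - gm,
        "interaction": resid + mab - ma - mb + gm,
    }
    rows = []
    for name, aligned in effects.items():
        sub = work.copy()
        sub["value"] = sps.rankdata(aligned)
        table = _two_way_anova(sub)
        rows.append(table.loc[[name]])
    return pd.concat(rows)


def two_way_compare(
    frame: pd.DataFrame,
    value: str = "value",
    factor_a: str = "condition",
    factor_b: str = "strategy",
    alpha: float = ALPHA,
) -> TwoWayResult:
    """Condition x strategy two-factor comparison, normality-gated.

    The branch is chosen by the Shapiro-Wilk majority rule over the
    factorial cells; the parametric two-way ANOVA is always reported,
    the aligned-rank-transform analysis is the nonparametric stand-in.
    Cells with fewer than 2 observations trigger a warning and are
    excluded.
    """
    work = frame.rename(
        columns={value: "value", factor_a: "factor_a", factor_b: "factor_b"}
    )[["value", "factor_a", "factor_b"]].dropna()
    warnings: List[str] = []
    counts = work.groupby(["factor_a", "factor_b"], observed=True).size()
    thin = counts[counts < 2]
    if len(thin):
        warnings.append(f"{len(thin)} cells with <2 observations were excluded")
        ok = counts[counts >= 2].index
        work = work.set_index(["factor_a", "factor_b"]).loc[ok].reset_index()

    cells = [g["value"].to_numpy() for _, g in work.groupby(["factor_a", "factor_b"], observed=True)]
    testable = [c for c in cells if len(c) >= 3]
    branch = normality_gate(testable, alpha=alpha) if testable else "parametric"
    parametric = _two_way_anova(work)
    nonparametric = _aligned_rank_anova(work)
    return TwoWayResult(
        branch=branch, parametric=parametric, nonparametric=nonparametric,
        warnings=warnings,
    )


# ---------------------------------------------------------------------------
# strategy evaluation


@dataclass
class ComparisonTable:
    """RMSE rows plus the one-way and two-way comparison results."""

    rmse_rows: pd.DataFrame  # condition, variable, strategy, rmse, n_pairs
    group_summaries: pd.DataFrame  # condition, variable, strategy, mean, sd, shapiro_p
    one_way: Dict[str, OneWayResult]
    two_way: Dict[str, TwoWayResult]

    def to_csv(self, path_prefix: str) -> None:
        self.rmse_rows.to_csv(f"{path_prefix}_rmse.csv", index=False)
        self.group_summaries.to_csv(f"{path_prefix}_groups.csv", index=False)


def evaluate_strategies(
    table: pd.DataFrame,
    reference: str = "reference",
    test_runners: Optional[Sequence[str]] = None,
    effect_ci: bool = False,
    seed: int = 0,
) -> ComparisonTable:
    """The paper-style evaluation harness on a tidy results table.

    ``table`` columns: runner, condition, variable, strategy, value,
    and optionally ``unit`` (an alignment key such as the window index;
    defaults to one value per runner). Per condition and variable, the
    RMSE of every non-reference strategy against the reference is
    computed on pairs aligned by (runner [, unit]); the one-way
    comparison runs across conditions on the reference values of all
    runners, and the two-way comparison (condition x strategy) on the
    test-split runners only.
    """
    required = {"runner", "condition", "variable", "strategy", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    keys = ["runner", "condition", "variable"] + (["unit"] if "unit" in table.columns else [])
    strategies = [s for s in table["strategy"].unique() if s != reference]
    ref_tab = table[table["strategy"] == reference]

    rows = []
    for strat in strategies:
        est_tab = table[table["strategy"] == strat]
        merged = est_tab.merge(ref_tab, on=keys, suffixes=("_est", "_ref"))
        for (cond, var), grp in merged.groupby(["condition", "variable"], observed=True):
            if len(grp) == 0:
                continue
            rows.append(
                {
                    "condition": cond, "variable": var, "strategy": strat,
                    "rmse": rmse(grp["value_est"], grp["value_ref"]),
                    "n_pairs": len(grp),
                }
            )
    rmse_rows = pd.DataFrame(rows)

    summaries = (
        table.groupby(["condition", "variable", "strategy"], observed=True)["value"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    shapiro_p = []
    for _, r in summaries.iterrows():
        vals = table[
            (table["condition"] == r["condition"])
            & (table["variable"] == r["variable"])
            & (table["strategy"] == r["strategy"])
        ]["value"].to_numpy()
        if len(vals) >= 3 and np.ptp(vals) > 0:
            if len(vals) > 5000:  # Shapiro-Wilk p-values degrade above n=5000
                vals = np.random.default_rng(seed).choice(vals, 5000, replace=False)
            shapiro_p.append(sps.shapiro(vals).pvalue)
        else:
            shapiro_p.append(np.nan)
    summaries["shapiro_p"] = shapiro_p

    one_way: Dict[str, OneWayResult] = {}
    for var, grp in ref_tab.groupby("variable", observed=True):
        per_runner = grp.groupby(["condition", "runner"], observed=True)["value"].mean().reset_index()
        conds = per_runner["condition"].unique()
        groups = [per_runner[per_runner["condition"] == c]["value"].to_numpy() for c in conds]
        if all(len(g) >= 3 for g in groups) and len(groups) >= 2:
            one_way[var] = one_way_compare(
                groups, labels=[str(c) for c in conds], effect_ci=effect_ci, seed=seed
            )

    two_way: Dict[str, TwoWayResult] = {}
    sub = table if test_runners is None else table[table["runner"].isin(test_runners)]
    for var, grp in sub.groupby("variable", observed=True):
        per_runner = (
            grp.groupby(["condition", "strategy", "runner"], observed=True)["value"].mean().reset_index()
        )
        if per_runner["strategy"].nunique() >= 2 and per_runner["condition"].nunique() >= 2:
            two_way[var] = two_way_compare(per_runner, factor_a="condition", factor_b="strategy")

    return ComparisonTable(
        rmse_rows=rmse_rows, group_summaries=summaries, one_way=one_way, two_way=two_way
    )
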