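"""From-scratch ANOVA, coefficient-of-variation, Tukey HSD, compact letter
display and Pearson correlation engines.

These are the statistical workhorses behind the variance partitioning and
trait-plasticity comparisons. Sums of squares are computed directly from
group means (one-way) or from least-squares model comparisons (two-way,
Type II for unbalanced tree counts); only the reference distributions
(F, t, studentized range) come from :mod:`scipy.stats`.

Conventions: sample (n-1) standard deviations throughout; p-values floored
at 1e-300 to keep logs finite.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import TraitTable

P_FLOOR = 1e-300


def _floor_p(p: float) -> float:
    return float(max(p, P_FLOOR))


# -- descriptive -----------------------------------------------------------

def coefficient_of_variation(values) -> float:
    """CV in percent: 100 * sample SD / mean. Requires n >= 2 and mean != 0."""
    x = np.asarray(values, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        raise ValueError("coefficient of variation needs n >= 2")
    mean = x.mean()
    if mean == 0:
        raise ValueError("coefficient of variation undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / mean)


# -- one-way ANOVA ---------------------------------------------------------

def oneway_anova(values, groups, factor: str = "group") -> pd.DataFrame:
    """Fixed-effects one-way ANOVA from the between/within decomposition.

    Returns a table with rows ``factor`` and ``Residual`` and columns
    ``sum_sq, df, mean_sq, F, p``; total SS in ``df.attrs["total_ss"]``.
    """
    y = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    keep = ~np.isnan(y)
    y, g = y[keep], g[keep]
    labels, idx = np.unique(g, return_inverse=True)
    k, n = labels.size, y.size
    if k < 2:
        raise ValueError("one-way ANOVA needs at least two groups")
    if n - k < 1:
        raise ValueError("no residual degrees of freedom")
    grand = y.mean()
    ni = np.bincount(idx)
    means = np.bincount(idx, weights=y) / ni
    ssb = float(np.sum(ni * (means - grand) ** 2))
    ssw = float(np.sum((y - means[idx]) ** 2))
    dfb, dfw = k - 1, n - k
    msb, msw = ssb / dfb, ssw / dfw
    if msw > 0:
        f_stat = msb / msw
        p = _floor_p(sps.f.sf(f_stat, dfb, dfw))
    else:
        f_stat, p = np.inf if ssb > 0 else 0.0, P_FLOOR if ssb > 0 else 1.0
    out = pd.DataFrame(
        {
            "sum_sq": [ssb, ssw],
            "df": [dfb, dfw],
            "mean_sq": [msb, msw],
            "F": [f_stat, np.nan],
            "p": [p, np.nan],
        },
        index=[factor, "Residual"],
    )
    out.attrs["total_ss"] = ssb + ssw
    out.attrs["group_means"] = dict(zip(labels.tolist(), means.tolist()))
    out.attrs["group_n"] = dict(zip(labels.tolist(), ni.tolist()))
    return out


# -- two-way ANOVA (Type II) ----------------------------------------------

def _dummies(codes: np.ndarray, levels: int) -> np.ndarray:
    """Treatment-coded dummy block (drop first level)."""
    return np.eye(levels)[codes][:, 1:]


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid)


def twoway_anova_site_variety(table: TraitTable, trait: str) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA (site, variety, site x variety) on tree-level
    values of the common varieties, with Type II sums of squares.

    Type II tests each main effect adjusted for the other main effect, and
    the interaction adjusted for both; with balanced tree counts it reduces
    to the sequential decomposition.
    """
    df = table.trait_vector(trait)
    sites = np.unique(df["site"])
    if sites.size != 2:
        raise ValueError("two-way site x variety ANOVA needs exactly two sites")
    occupancy = df.groupby("variety")["site"].nunique()
    missing = occupancy[occupancy < 2]
    if len(missing):
        raise ValueError(
            f"varieties missing at one site: {sorted(missing.index)}"
        )
    y = df["value"].to_numpy(dtype=float)
    s_codes, s_levels = pd.factorize(df["site"], sort=True)
    v_codes, v_levels = pd.factorize(df["variety"], sort=True)
    n = y.size
    S = _dummies(s_codes, len(s_levels))
    V = _dummies(v_codes, len(v_levels))
    # interaction dummies: elementwise products of the main-effect columns
    I = np.einsum("ij,ik->ijk", S, V).reshape(n, -1)
    ones = np.ones((n, 1))
    rss_full = _rss(np.hstack([ones, S, V, I]), y)
    rss_add = _rss(np.hstack([ones, S, V]), y)
    rss_site_only = _rss(np.hstack([ones, S]), y)
    rss_var_only = _rss(np.hstack([ones, V]), y)
    ss_site = rss_var_only - rss_add
    ss_variety = rss_site_only - rss_add
    ss_inter = rss_add - rss_full
    df_site = len(s_levels) - 1
    df_var = len(v_levels) - 1
    df_int = df_site * df_var
    df_resid = n - len(s_levels) * len(v_levels)
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    ms_resid = rss_full / df_resid
    rows = []
    for name, ss, d in [
        ("site", ss_site, df_site),
        ("variety", ss_variety, df_var),
        ("site:variety", ss_inter, df_int),
    ]:
        ss = max(ss, 0.0)  # guard tiny negative round-off
        ms = ss / d
        if ms_resid > 0:
            f_stat = ms / ms_resid
            p = _floor_p(sps.f.sf(f_stat, d, df_resid))
        else:
            f_stat, p = np.inf if ss > 0 else 0.0, P_FLOOR if ss > 0 else 1.0
        rows.append((name, ss, d, ms, f_stat, p))
    rows.append(("Residual", rss_full, df_resid, ms_resid, np.nan, np.nan))
    out = pd.DataFrame(rows, columns=["factor", "sum_sq", "df", "mean_sq", "F", "p"])
    out = out.set_index("factor")
    out.attrs["total_ss"] = float(np.sum((y - y.mean()) ** 2))
    return out


# -- variance partitioning -------------------------------------------------

@dataclass
class VariancePartition:
    """Percentage variance contributions for one trait.

    Each percentage carries its own parent one-way ANOVA and denominator:
    genetic and residual come from the variety-factor ANOVA across both
    sites (all varieties, tree level); plasticity from the site-factor
    ANOVA on the common varieties. Because the parents differ, the three
    percentages are deliberately NOT forced to sum to 100.
    """

    trait: str
    genetic_pct: float
    plasticity_pct: float
    residual_pct: float
    anova_variety: pd.DataFrame = field(repr=False)
    anova_site_common: pd.DataFrame = field(repr=False)


def variance_components(all_table: TraitTable, common_table: TraitTable,
                        trait: str) -> VariancePartition:
    """Partition tree-level trait variance into genetic, plastic and residual shares.

    genetic % = SS(variety)/SS_total from a one-way ANOVA with variety as
    the factor across both sites; residual % = the within-variety share of
    the same ANOVA; plasticity % = SS(site)/SS_total from a one-way ANOVA
    on the common varieties with site as the factor.
    """
    dv = all_table.trait_vector(trait)
    anova_v = oneway_anova(dv["value"], dv["variety"], factor="variety")
    tot_v = anova_v.attrs["total_ss"]
    ds = common_table.subset("common").trait_vector(trait)
    anova_s = oneway_anova(ds["value"], ds["site"], factor="site")
    tot_s = anova_s.attrs["total_ss"]
    return VariancePartition(
        trait=trait,
        genetic_pct=100.0 * anova_v.loc["variety", "sum_sq"] / tot_v,
        plasticity_pct=100.0 * anova_s.loc["site", "sum_sq"] / tot_s,
        residual_pct=100.0 * anova_v.loc["Residual", "sum_sq"] / tot_v,
        anova_variety=anova_v,
        anova_site_common=anova_s,
    )


# -- Tukey HSD -------------------------------------------------------------

def tukey_hsd(values, groups, alpha: float = 0.05) -> pd.DataFrame:
    """All-pairs comparison via the studentized-range distribution.

    Unequal group sizes use the Tukey–Kramer standard error
    ``sqrt(MSE/2 * (1/ni + 1/nj))``. Returns one row per unordered pair
    with columns ``group1, group2, mean_diff, p_adj, significant``.
    """
    anova = oneway_anova(values, groups)
    means = anova.attrs["group_means"]
    ns = anova.attrs["group_n"]
    mse = anova.loc["Residual", "mean_sq"]
    df_resid = anova.loc["Residual", "df"]
    if mse <= 0:
        raise ValueError("zero residual variance: Tukey HSD undefined")
    k = len(means)
    rows = []
    for g1, g2 in itertools.combinations(sorted(means), 2):
        diff = means[g2] - means[g1]
        se = np.sqrt(mse / 2.0 * (1.0 / ns[g1] + 1.0 / ns[g2]))
        q = abs(diff) / se
        p = _floor_p(sps.studentized_range.sf(q, k, df_resid))
        p = min(p, 1.0)
        rows.append((g1, g2, diff, p, p < alpha))
    out = pd.DataFrame(rows, columns=["group1", "group2", "mean_diff", "p_adj",
                                      "significant"])
    out.attrs["group_means"] = means
    out.attrs["alpha"] = alpha
    return out


def compact_letter_display(comparisons: pd.DataFrame) -> dict[str, str]:
    """Insert-and-absorb letter assignment from an all-pairs comparison table.

    Groups sharing at least one letter are not significantly different;
    significantly different groups share none. Letters are assigned in
    descending order of group mean.
    """
    means = comparisons.attrs.get("group_means")
    groups = sorted(set(comparisons["group1"]) | set(comparisons["group2"]))
    if means is None:
        means = {g: 0.0 for g in groups}
    sig_pairs = {
        frozenset((r.group1, r.group2))
        for r in comparisons.itertuples() if r.significant
    }
    expected = {frozenset(p) for p in itertools.combinations(groups, 2)}
    seen = {frozenset((r.group1, r.group2)) for r in comparisons.itertuples()}
    if seen != expected:
        raise ValueError("comparison table must cover all group pairs exactly once")
    order = sorted(groups, key=lambda g: (-means[g], g))
    columns: list[set[str]] = [set(order)]
    for pair in sorted(sig_pairs, key=lambda p: sorted(p)):
        a, b = sorted(pair)
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.extend([col - {a}, col - {b}])
        # absorb: drop columns contained in another
        columns = [
            c for i, c in enumerate(columns)
            if c and not any(c < d or (c == d and i > j)
                             for j, d in enumerate(columns) if j != i)
        ]
    # letter columns ordered by the best (highest-mean) group they contain
    columns.sort(key=lambda c: min(order.index(g) for g in c))
    letters = {g: "" for g in groups}
    alphabet = string.ascii_lowercase
    for i, col in enumerate(columns):
        ch = alphabet[i % 26] * (1 + i // 26)
        for g in col:
            letters[g] += ch
    return {g: "".join(sorted(letters[g])) for g in groups}


# -- correlation -----------------------------------------------------------

def pearson_correlation(x, y) -> tuple[float, float]:
    """Product-moment r with a two-sided p from the t transform (n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise ValueError("Pearson correlation needs n >= 3")
    xc, yc = x - x.mean(), y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0 or sy == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    r = float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))
    if abs(r) == 1.0:
        return r, P_FLOOR
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = _floor_p(2.0 * sps.t.sf(abs(t), n - 2))
    return r, min(p, 1.0)


def fisher_ci(r: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Confidence interval for a correlation via the Fisher z transform."""
    if n < 4:
        return (np.nan, np.nan)
    r = float(np.clip(r, -0.9999999, 0.9999999))
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    crit = sps.norm.ppf(0.5 + conf / 2.0)
    return float(np.tanh(z - crit * se)), float(np.tanh(z + crit * se))


# -- summaries -------------------------------------------------------------

def site_summary(table: TraitTable, trait: str, level: str = "tree") -> pd.DataFrame:
    """Per-site mean, SD and n for one trait, at tree or variety-mean level."""
    if level == "tree":
        df = table.trait_vector(trait)
    elif level == "variety_mean":
        vm = table.variety_means()
        df = vm[vm["trait"] == trait].rename(columns={"mean": "value"})
        df = df.dropna(subset=["value"])
    else:
        raise ValueError("level must be 'tree' or 'variety_mean'")
    rows = []
    for site, grp in df.groupby("site", sort=True):
        v = grp["value"].to_numpy(dtype=float)
        sd = float(np.std(v, ddof=1)) if v.size > 1 else np.nan
        rows.append((site, float(v.mean()), sd, int(v.size)))
    return pd.DataFrame(rows, columns=["site", "mean", "sd", "n"])
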