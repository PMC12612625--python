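"""Phenotypic dissimilarity (PhD) and multivariate plasticity (MVPi) indices.

Both indices quantify how much the trees of one clonal variety shift their
phenotype between two contrasting gardens.

PhD (per variety x trait, in [0, 1]) is an average pairwise cross-site
dissimilarity of standardized trait values, discounted by the within-site
tree-to-tree variability:

    B = mean over cross-site tree pairs (i in A, j in B) of |z_i - z_j|
    W = mean over all within-site pairs, pooled across the two sites
    PhD = max(0, (B - W) / B),  PhD = 0 when B = 0

so PhD -> 0 when sites are indistinguishable relative to within-site spread
and PhD -> 1 when the sites separate completely with no within-site spread.
Two alternative formulations are available by name: ``"overlap"``
(one minus the normal distribution-overlap coefficient of the two sites)
and ``"rdpi"`` (relative-distance plasticity: mean |x_i - x_j|/(x_i + x_j)
over cross-site pairs, intended for raw positive trait values).

MVPi (per variety, >= 0) is the mean Euclidean distance between the
projections of a variety's trees at the two sites on the first three
principal components of one PCA fitted on the pooled standardized trees of
both sites.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import KEY_COLUMNS, TraitTable
from .stats import compact_letter_display, oneway_anova, tukey_hsd

PHD_VARIANTS = ("default", "overlap", "rdpi")


# -- standardization -------------------------------------------------------

def standardize_traits(table: TraitTable) -> tuple[TraitTable, pd.DataFrame]:
    """Z-score each trait over all trees of the common varieties, both sites pooled.

    Returns the standardized table and a provenance frame with the per-trait
    ``mean`` and ``sd`` used (sample SD, n-1), so the transform can be
    reproduced or inverted exactly.
    """
    common = table.subset("common")
    df = common.data.copy()
    params = []
    for t in common.trait_names:
        x = df[t].to_numpy(dtype=float)
        m = float(np.nanmean(x))
        sd = float(np.nanstd(x, ddof=1))
        if not sd > 0:
            raise ValueError(f"trait {t!r} has zero standard deviation")
        df[t] = (x - m) / sd
        params.append({"trait": t, "mean": m, "sd": sd})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out = TraitTable(df, common.trait_names, require_positive=False)
    return out, pd.DataFrame(params).set_index("trait")


# -- PhD -------------------------------------------------------------------

def phd_index(za, zb, variant: str = "default") -> float:
    """Phenotypic dissimilarity between one variety's trees at sites A and B.

    ``za`` and ``zb`` are the (standardized) trait values of the trees at
    each site; both must be non-empty.
    """
    a = np.asarray(za, dtype=float)
    b = np.asarray(zb, dtype=float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if a.size == 0 or b.size == 0:
        raise ValueError("PhD needs at least one tree per site")
    if variant == "default":
        between = np.abs(a[:, None] - b[None, :]).mean()
        within_diffs = [abs(x - y) for arr in (a, b)
                        for x, y in itertools.combinations(arr, 2)]
        within = float(np.mean(within_diffs)) if within_diffs else 0.0
        if between == 0:
            return 0.0
        return float(max(0.0, (between - within) / between))
    if variant == "overlap":
        sds = [arr.std(ddof=1) for arr in (a, b) if arr.size > 1]
        pooled = float(np.sqrt(np.mean(np.square(sds)))) if sds else 0.0
        delta = abs(a.mean() - b.mean())
        if pooled == 0:
            return 0.0 if delta == 0 else 1.0
        ovl = 2.0 * sps.norm.cdf(-delta / (2.0 * pooled))
        return float(1.0 - ovl)
    if variant == "rdpi":
        # relative distance; intended for raw positive values, guarded for
        # arbitrary input by absolute-value denominators (0/0 -> 0)
        num = np.abs(a[:, None] - b[None, :])
        den = np.abs(a)[:, None] + np.abs(b)[None, :]
        with np.errstate(invalid="ignore"):
            ratio = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        return float(ratio.mean())
    raise ValueError(f"unknown PhD variant {variant!r}; pick from {PHD_VARIANTS}")


def phd_matrix(std_table: TraitTable, variant: str = "default") -> pd.DataFrame:
    """Variety x trait PhD matrix over the common varieties.

    Expects the standardized common-variety table (see
    :func:`standardize_traits`). Entries are NaN where a variety lacks trees
    with a value at one of the sites.
    """
    design = std_table.design
    if len(design.sites) != 2:
        raise ValueError("PhD matrix needs exactly two sites")
    site_a, site_b = design.sites
    varieties = sorted(design.common)
    out = pd.DataFrame(np.nan, index=varieties, columns=std_table.trait_names)
    df = std_table.data
    for v in varieties:
        sub = df[df["variety"] == v]
        for t in std_table.trait_names:
            za = sub.loc[sub["site"] == site_a, t].dropna().to_numpy()
            zb = sub.loc[sub["site"] == site_b, t].dropna().to_numpy()
            if za.size and zb.size:
                out.loc[v, t] = phd_index(za, zb, variant=variant)
    out.attrs["variant"] = variant
    out.attrs["sites"] = (site_a, site_b)
    out.index.name = "variety"
    return out


def rank_traits_by_phd(matrix: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Mean PhD per trait with a trait-factor ANOVA and Tukey letter groups.

    Observations are the per-variety PhD values; the returned frame is
    sorted by descending mean PhD and carries the ANOVA table in
    ``attrs["anova"]`` and the all-pairs comparisons in ``attrs["tukey"]``.
    """
    long = matrix.reset_index().melt(
        id_vars="variety", var_name="trait", value_name="phd").dropna()
    if long["trait"].nunique() < 2 or long["variety"].nunique() < 2:
        raise ValueError("trait ranking needs >= 2 traits and >= 2 varieties")
    anova = oneway_anova(long["phd"], long["trait"], factor="trait")
    resid_ms = anova.loc["Residual", "mean_sq"]
    means = long.groupby("trait")["phd"].mean()
    if resid_ms > 0:
        comparisons = tukey_hsd(long["phd"], long["trait"], alpha=alpha)
        letters = compact_letter_display(comparisons)
    else:  # all traits internally constant: identical -> one group
        comparisons = None
        letters = {t: "a" for t in means.index}
    out = pd.DataFrame({
        "mean_phd": means,
        "letters": pd.Series(letters),
        "n_varieties": long.groupby("trait")["phd"].size(),
    }).sort_values("mean_phd", ascending=False)
    out.index.name = "trait"
    out.attrs["anova"] = anova
    out.attrs["tukey"] = comparisons
    out.attrs["alpha"] = alpha
    return out


# -- MVPi ------------------------------------------------------------------

@dataclass
class MVPiResult:
    """Per-variety MVPi plus the provenance of the projection space."""

    values: pd.Series
    n_components: int
    components: np.ndarray  # (n_traits, n_components) orthonormal axes
    explained_pct: np.ndarray
    dropped_trees: int


def mvpi(std_table: TraitTable, n_components: int = 3) -> MVPiResult:
    """Multivariate plasticity index per common variety.

    One PCA is fitted on the pooled standardized tree x trait matrix of
    both sites; each tree is projected on the first ``n_components`` axes
    (raw principal scores, no eigenvalue scaling) and MVPi(v) is the mean
    Euclidean distance over all cross-site tree pairs of variety ``v``.
    Trees with any missing trait are dropped (complete-case, with warning).
    """
    traits = std_table.trait_names
    if n_components > len(traits):
        raise ValueError("n_components cannot exceed the number of traits")
    design = std_table.design
    if len(design.sites) != 2:
        raise ValueError("MVPi needs exactly two sites")
    site_a, site_b = design.sites
    df = std_table.data
    complete = df.dropna(subset=traits)
    dropped = len(df) - len(complete)
    if dropped:
        warnings.warn(f"MVPi: dropped {dropped} trees with missing traits",
                      stacklevel=2)
    X = complete[traits].to_numpy(dtype=float)
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    # deterministic sign: largest-|weight| trait positive per axis
    for j in range(vt.shape[0]):
        lead = np.argmax(np.abs(vt[j]))
        if vt[j, lead] < 0:
            vt[j] = -vt[j]
    V = vt[:n_components].T
    proj = Xc @ V
    eig = np.var(Xc @ vt.T, axis=0, ddof=1)
    explained = 100.0 * eig[:n_components] / eig.sum()

    values = {}
    for v in sorted(design.common):
        mask = complete["variety"] == v
        pa = proj[(mask & (complete["site"] == site_a)).to_numpy()]
        pb = proj[(mask & (complete["site"] == site_b)).to_numpy()]
        if pa.shape[0] == 0 or pb.shape[0] == 0:
            values[v] = np.nan
            continue
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=2)
        values[v] = float(d.mean())
    series = pd.Series(values, name="mvpi")
    series.index.name = "variety"
    return MVPiResult(values=series, n_components=n_components,
                      components=V, explained_pct=explained,
                      dropped_trees=dropped)
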