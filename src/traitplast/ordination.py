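"""Per-site correlation-matrix PCA, varimax rotation, and fast-slow scoring.

The phenotypic space of each garden is explored with a PCA of the per-site
standardized tree x trait matrix. Loadings are correlation-scaled
(eigenvector times sqrt(eigenvalue)), i.e. the correlation between each
trait and each component, so row sums of squares (communalities) are
preserved by orthogonal rotation. Tree scores are unit-variance
standardized scores; rotated scores are those scores multiplied by the
rotation matrix.

The "fast-slow" (acquisitive-conservative) axis is the rotated component
with the largest combined absolute loadings of LMA and LDMC, oriented so
that LMA loads positive: higher score = more conservative (slow) phenotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .core import KEY_COLUMNS, TraitTable
from .stats import fisher_ci, pearson_correlation


@dataclass
class OrdinationResult:
    site: str | None
    trait_names: list[str]
    eigenvalues: np.ndarray
    explained_pct: np.ndarray
    loadings: pd.DataFrame            # trait x PC, correlation-scaled, unrotated
    scores: pd.DataFrame              # site/variety/tree + PC columns (unit variance)
    rotated_loadings: pd.DataFrame | None = None
    rotated_scores: pd.DataFrame | None = None
    rotation: np.ndarray | None = None
    rotated_explained_pct: np.ndarray | None = None

    @property
    def is_rotated(self) -> bool:
        return self.rotated_loadings is not None

    def communalities(self, k: int | None = None) -> pd.Series:
        L = self.rotated_loadings if self.is_rotated else self.loadings
        if k is not None and not self.is_rotated:
            L = L.iloc[:, :k]
        return (L ** 2).sum(axis=1)


def pca(table: TraitTable, site: str | None = None) -> OrdinationResult:
    """Correlation-matrix PCA of the (optionally per-site) tree x trait matrix.

    Complete-case trees only; components are ordered by descending
    eigenvalue with a deterministic sign (the largest-|loading| trait loads
    positive on each component).
    """
    sub = table if site is None else table.subset("all", site=site)
    traits = sub.trait_names
    df = sub.data.dropna(subset=traits)
    n = len(df)
    if n <= len(traits):
        raise ValueError(
            f"PCA needs more than {len(traits)} complete-case trees, got {n}")
    X = df[traits].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = [t for t, s in zip(traits, sd) if s == 0]
        raise ValueError(f"constant traits make the correlation matrix singular: {bad}")
    Z = (X - X.mean(axis=0)) / sd
    u, s, vt = np.linalg.svd(Z / np.sqrt(n - 1), full_matrices=False)
    eig = s ** 2
    loadings = vt.T * np.sqrt(eig)  # trait-component correlations
    for j in range(loadings.shape[1]):
        lead = np.argmax(np.abs(loadings[:, j]))
        if loadings[lead, j] < 0:
            loadings[:, j] = -loadings[:, j]
            vt[j] = -vt[j]
    pcs = [f"PC{j + 1}" for j in range(len(eig))]
    with np.errstate(divide="ignore", invalid="ignore"):
        std_scores = Z @ vt.T / np.where(np.sqrt(eig) > 0, np.sqrt(eig), np.inf)
    scores = df[KEY_COLUMNS].reset_index(drop=True).join(
        pd.DataFrame(std_scores, columns=pcs))
    return OrdinationResult(
        site=site,
        trait_names=list(traits),
        eigenvalues=eig,
        explained_pct=100.0 * eig / eig.sum(),
        loadings=pd.DataFrame(loadings, index=traits, columns=pcs),
        scores=scores,
    )


# -- varimax ---------------------------------------------------------------

def varimax_criterion(L: np.ndarray) -> float:
    """Raw varimax criterion: summed column variances of squared loadings."""
    sq = L ** 2
    return float(np.sum(sq.var(axis=0)))


def _varimax(L: np.ndarray, kaiser: bool = True, tol: float = 1e-8,
             max_sweeps: int = 1000) -> tuple[np.ndarray, np.ndarray]:
    """Iterative pairwise (planar) varimax rotation with Kaiser normalization.

    Returns the rotated loadings and the accumulated rotation matrix R such
    that ``L_rot = L @ R``. Raises on non-convergence.
    """
    p, k = L.shape
    h = np.sqrt((L ** 2).sum(axis=1))
    norm = np.where(h > 0, h, 1.0) if kaiser else np.ones(p)
    A = L / norm[:, None]
    R = np.eye(k)
    last = varimax_criterion(A)
    for _ in range(max_sweeps):
        for i in range(k - 1):
            for j in range(i + 1, k):
                x, y = A[:, i], A[:, j]
                u = x ** 2 - y ** 2
                v = 2.0 * x * y
                num = 2.0 * (p * (u @ v) - u.sum() * v.sum())
                den = p * (u @ u - v @ v) - (u.sum() ** 2 - v.sum() ** 2)
                phi = 0.25 * np.arctan2(num, den)
                if abs(phi) < 1e-15:
                    continue
                c, s_ = np.cos(phi), np.sin(phi)
                G = np.array([[c, -s_], [s_, c]])
                A[:, [i, j]] = A[:, [i, j]] @ G
                R[:, [i, j]] = R[:, [i, j]] @ G
        crit = varimax_criterion(A)
        if crit - last < tol:
            return A * norm[:, None], R
        last = crit
    raise RuntimeError("varimax did not converge within the sweep limit")


def varimax_rotate(result: OrdinationResult, k: int = 3) -> OrdinationResult:
    """Orthogonal varimax of the first ``k`` loading columns.

    Rotated components are reported in descending order of explained
    variance (column sums of squared rotated loadings over the number of
    traits); scores are re-derived by applying the same rotation to the
    unit-variance standardized scores.
    """
    if k > result.loadings.shape[1]:
        raise ValueError("k exceeds the number of components")
    L = result.loadings.iloc[:, :k].to_numpy().copy()
    L_rot, R = _varimax(L)
    # order rotated axes by explained variance; deterministic sign
    ss = (L_rot ** 2).sum(axis=0)
    order = np.argsort(-ss)
    L_rot, R, ss = L_rot[:, order], R[:, order], ss[order]
    for j in range(k):
        lead = np.argmax(np.abs(L_rot[:, j]))
        if L_rot[lead, j] < 0:
            L_rot[:, j] = -L_rot[:, j]
            R[:, j] = -R[:, j]
    rcs = [f"RC{j + 1}" for j in range(k)]
    rotated_loadings = pd.DataFrame(L_rot, index=result.trait_names, columns=rcs)
    pcs = [f"PC{j + 1}" for j in range(k)]
    rot_scores = result.scores[pcs].to_numpy() @ R
    rotated_scores = result.scores[KEY_COLUMNS].join(
        pd.DataFrame(rot_scores, columns=rcs))
    return dc_replace(
        result,
        rotated_loadings=rotated_loadings,
        rotated_scores=rotated_scores,
        rotation=R,
        rotated_explained_pct=100.0 * ss / len(result.trait_names),
    )


# -- fast-slow axis --------------------------------------------------------

def identify_fast_slow_axis(result: OrdinationResult) -> tuple[int, int]:
    """(component index, orientation sign) of the fast-slow axis.

    Among the first three rotated components, picks the one maximizing
    |loading(LMA)| + |loading(LDMC)|; the sign makes LMA load positive
    (positive score = conservative/slow). Ties keep the first index and are
    reported with a warning.
    """
    if not result.is_rotated:
        raise ValueError("identify_fast_slow_axis requires a rotated result")
    L = result.rotated_loadings
    for t in ("LMA", "LDMC"):
        if t not in L.index:
            raise ValueError(f"trait {t!r} absent: fast-slow axis undefined")
    k = min(3, L.shape[1])
    crit = (L.loc["LMA"].abs() + L.loc["LDMC"].abs()).to_numpy()[:k]
    best = int(np.argmax(crit))
    ties = np.flatnonzero(np.isclose(crit, crit[best]))
    if ties.size > 1:
        warnings.warn(f"fast-slow axis criterion tied among components {ties + 1}; "
                      "keeping the first", stacklevel=2)
    sign = 1 if L.iloc[:, best].loc["LMA"] >= 0 else -1
    return best, sign


def fast_slow_scores(result: OrdinationResult) -> pd.Series:
    """Mean oriented fast-slow score per variety (tree scores averaged)."""
    axis, sign = identify_fast_slow_axis(result)
    col = result.rotated_scores.columns[len(KEY_COLUMNS) + axis]
    s = sign * result.rotated_scores.groupby("variety")[col].mean()
    s.name = "fast_slow_score"
    return s.sort_index()


# -- plasticity vs strategy ------------------------------------------------

def plasticity_strategy_correlations(
    scores_by_site: dict[str, pd.Series],
    phd: pd.DataFrame,
    mvpi_values: pd.Series,
    alpha: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Pearson correlations of per-site fast-slow variety scores against
    each trait's PhD and against MVPi (11 tests per site).

    No multiplicity correction by default; ``holm=True`` applies a Holm
    step-down adjustment within each site.
    """
    rows = []
    for site, scores in scores_by_site.items():
        targets = {t: phd[t] for t in phd.columns}
        targets["MVPi"] = mvpi_values
        for name, col in targets.items():
            joined = pd.concat([scores, col.rename("y")], axis=1, join="inner").dropna()
            if len(joined) < 3:
                raise ValueError(
                    f"fewer than 3 overlapping varieties for {name} at {site}")
            r, p = pearson_correlation(joined.iloc[:, 0], joined["y"])
            lo, hi = fisher_ci(r, len(joined))
            rows.append({"site": site, "variable": name, "n": len(joined),
                         "r": r, "p": p, "ci_low": lo, "ci_high": hi})
    out = pd.DataFrame(rows)
    if holm:
        adj = []
        for site, grp in out.groupby("site", sort=False):
            p = grp["p"].to_numpy()
            order = np.argsort(p)
            m = len(p)
            stepped = np.empty(m)
            running = 0.0
            for rank, idx in enumerate(order):
                running = max(running, (m - rank) * p[idx])
                stepped[idx] = min(1.0, running)
            adj.append(pd.Series(stepped, index=grp.index))
        out["p_adj"] = pd.concat(adj).sort_index()
        out["significant"] = out["p_adj"] < alpha
    else:
        out["significant"] = out["p"] < alpha
    out.attrs["alpha"] = alpha
    return out
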