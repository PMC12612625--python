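"""Derivation of the ten phenotypic traits from raw leaf, twig and branch measurements.

Ratio traits are computed per individual sample (leaf, twig or branch) and
then averaged to the tree level — not as ratios of tree-level means. The two
conventions differ whenever replicates vary, and the per-sample convention
matches how the replicated organ measurements are taken.

Units follow the trait canon in :mod:`traitplast.core`:

* LMA = LDM/LA, reported in g m^-2 (inputs g and cm^2; x 1e4)
* LDMC = LDM/LFM, reported in mg g^-1 (x 1e3)
* LL:LW dimensionless; LT = mean of four lamina readings (um)
* SSL = stem length / stem dry mass (cm g^-1)
* A_S = pi/4 * d1 * d2 (ellipse from two perpendicular bark-removed
  diameters, mm -> cm^2); A_S:A_L in cm^2 m^-2
* RBT = 2 * mean bark thickness / mean branch diameter (mm mm^-1)
* BWD is measured upstream (densitometry) and passed through, g cm^-3.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import KEY_COLUMNS, TRAIT_NAMES, TraitTable

CM2_PER_M2 = 1e4
MG_PER_G = 1e3
MM2_TO_CM2 = 1e-2


def _require_positive(**values: float) -> None:
    for name, v in values.items():
        if not v > 0:
            raise ValueError(f"{name} must be strictly positive, got {v}")


@dataclass(frozen=True)
class RawLeafMeasurement:
    """One fully rehydrated leaf, petiole removed.

    LFM/LDM in g, LA in cm^2, LL/LW in cm, four thickness readings in um.
    """

    LFM: float
    LDM: float
    LA: float
    LL: float
    LW: float
    LT_readings: tuple[float, float, float, float]

    def __post_init__(self):
        _require_positive(LFM=self.LFM, LDM=self.LDM, LA=self.LA,
                          LL=self.LL, LW=self.LW)
        if any(r <= 0 for r in self.LT_readings):
            raise ValueError("all LT readings must be strictly positive")
        if self.LDM > self.LFM:
            raise ValueError("dry mass cannot exceed fresh mass")


@dataclass(frozen=True)
class RawTwigMeasurement:
    """One current-year twig: two perpendicular bark-removed diameters (mm),
    twig leaf area A_L (m^2), length (cm), dry mass (g)."""

    d1: float
    d2: float
    A_L: float
    length: float
    dry_mass: float

    def __post_init__(self):
        _require_positive(d1=self.d1, d2=self.d2, A_L=self.A_L,
                          length=self.length, dry_mass=self.dry_mass)


@dataclass(frozen=True)
class RawBranchMeasurement:
    """One branch section: four bark-thickness readings (mm), two
    perpendicular diameters (mm), and its measured wood density (g cm^-3)."""

    bark_readings: tuple[float, ...]
    diam_readings: tuple[float, float]
    BWD: float

    def __post_init__(self):
        if any(b < 0 for b in self.bark_readings):
            raise ValueError("bark readings must be nonnegative")
        if any(d <= 0 for d in self.diam_readings):
            raise ValueError("diameters must be strictly positive")
        _require_positive(BWD=self.BWD)
        if np.mean(self.bark_readings) >= np.mean(self.diam_readings) / 2:
            raise ValueError("mean bark thickness must be < mean diameter / 2")


def derive_leaf_traits(m: RawLeafMeasurement) -> dict[str, float]:
    """LA, LW, LL:LW, LMA, LDMC and LT for one leaf."""
    return {
        "LA": m.LA,
        "LW": m.LW,
        "LL_LW": m.LL / m.LW,
        "LMA": m.LDM / m.LA * CM2_PER_M2,
        "LDMC": m.LDM / m.LFM * MG_PER_G,
        "LT": float(np.mean(m.LT_readings)),
    }


def derive_stem_traits(m: RawTwigMeasurement) -> dict[str, float]:
    """SSL and the sapwood-to-leaf-area ratio for one twig."""
    a_s_cm2 = math.pi / 4.0 * m.d1 * m.d2 * MM2_TO_CM2
    return {
        "SSL": m.length / m.dry_mass,
        "AS_AL": a_s_cm2 / m.A_L,
    }


def derive_branch_traits(m: RawBranchMeasurement) -> dict[str, float]:
    """Relative bark thickness (2 x mean bark / mean diameter) and wood density."""
    rbt = 2.0 * float(np.mean(m.bark_readings)) / float(np.mean(m.diam_readings))
    return {"RBT": rbt, "BWD": m.BWD}


# -- CSV front end ---------------------------------------------------------

LEAF_COLUMNS = ["LFM", "LDM", "LA", "LL", "LW", "LT1", "LT2", "LT3", "LT4"]
TWIG_COLUMNS = ["d1", "d2", "A_L", "length", "dry_mass"]
BRANCH_COLUMNS = ["bark1", "bark2", "bark3", "bark4", "diam1", "diam2", "BWD"]


def _derive_rows(df: pd.DataFrame, deriver, builder) -> pd.DataFrame:
    derived = [deriver(builder(row)) for row in df.itertuples(index=False)]
    out = pd.DataFrame(derived)
    return pd.concat([df[KEY_COLUMNS].reset_index(drop=True), out], axis=1)


def derive_trait_table(leaf_csv=None, twig_csv=None, branch_csv=None) -> TraitTable:
    """Build a tree-level :class:`TraitTable` from per-organ measurement CSVs.

    Each CSV has ``site, variety, tree`` key columns plus, per organ:
    leaf — ``LFM, LDM, LA, LL, LW, LT1..LT4``; twig — ``d1, d2, A_L, length,
    dry_mass``; branch — ``bark1..bark4, diam1, diam2, BWD``. Multiple rows
    per tree (replicate organs) are derived per sample, then averaged.
    """
    pieces = []
    if leaf_csv is not None:
        df = pd.read_csv(leaf_csv, encoding="utf-8")
        pieces.append(_derive_rows(df, derive_leaf_traits, lambda r: RawLeafMeasurement(
            LFM=r.LFM, LDM=r.LDM, LA=r.LA, LL=r.LL, LW=r.LW,
            LT_readings=(r.LT1, r.LT2, r.LT3, r.LT4))))
    if twig_csv is not None:
        df = pd.read_csv(twig_csv, encoding="utf-8")
        pieces.append(_derive_rows(df, derive_stem_traits, lambda r: RawTwigMeasurement(
            d1=r.d1, d2=r.d2, A_L=r.A_L, length=r.length, dry_mass=r.dry_mass)))
    if branch_csv is not None:
        df = pd.read_csv(branch_csv, encoding="utf-8")
        pieces.append(_derive_rows(df, derive_branch_traits, lambda r: RawBranchMeasurement(
            bark_readings=(r.bark1, r.bark2, r.bark3, r.bark4),
            diam_readings=(r.diam1, r.diam2), BWD=r.BWD)))
    if not pieces:
        raise ValueError("at least one organ CSV is required")
    tree_means = [p.groupby(KEY_COLUMNS, sort=False).mean().reset_index() for p in pieces]
    merged = tree_means[0]
    for extra in tree_means[1:]:
        merged = merged.merge(extra, on=KEY_COLUMNS, how="outer")
    traits = [t for t in TRAIT_NAMES if t in merged.columns]
    return TraitTable(merged, trait_names=traits)
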