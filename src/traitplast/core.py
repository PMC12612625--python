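"""Data model and I/O for tree-level trait tables of a two-site clonal common garden.

The universal currency of the pipeline is the :class:`TraitTable`: one row per
tree, keyed by (site, variety, tree), with one column per phenotypic trait.
Varieties are clonally propagated genotypes, so a variety present at both
sites is genetically identical across them ("common" variety); varieties
present at a single site are "distinct". The :class:`StudyDesign` records
that occupancy structure and is always re-derived from the data, never
stored independently.
"""

from __future__ import annotations

import json
import unicodedata
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Canonical trait columns, in table order. Units: LA cm2, LW cm,
#: LL_LW dimensionless, LMA g m-2, LDMC mg g-1, LT um, SSL cm g-1,
#: AS_AL cm2 m-2, BWD g cm-3, RBT mm mm-1.
TRAIT_NAMES = ["LA", "LW", "LL_LW", "LMA", "LDMC", "LT", "SSL", "AS_AL", "BWD", "RBT"]

TRAIT_UNITS = {
    "LA": "cm^2",
    "LW": "cm",
    "LL_LW": "cm cm^-1",
    "LMA": "g m^-2",
    "LDMC": "mg g^-1",
    "LT": "um",
    "SSL": "cm g^-1",
    "AS_AL": "cm^2 m^-2",
    "BWD": "g cm^-3",
    "RBT": "mm mm^-1",
}

KEY_COLUMNS = ["site", "variety", "tree"]


def _norm_label(value) -> str:
    """Exact-match label normalization: Unicode NFC + whitespace trim.

    No fuzzy matching — silent merges of variety names are worse than misses.
    """
    return unicodedata.normalize("NFC", str(value)).strip()


@dataclass(frozen=True)
class StudyDesign:
    """Occupancy structure of a (up to) two-site common-garden trial."""

    sites: tuple[str, ...]
    common: frozenset[str]
    distinct: dict[str, frozenset[str]]

    @classmethod
    def from_occupancy(cls, df: pd.DataFrame) -> "StudyDesign":
        sites = tuple(sorted(df["site"].unique()))
        per_site = {s: frozenset(df.loc[df["site"] == s, "variety"]) for s in sites}
        if len(sites) >= 2:
            common = frozenset.intersection(*per_site.values())
        else:
            common = frozenset()
        distinct = {s: frozenset(v - common) for s, v in per_site.items()}
        return cls(sites=sites, common=common, distinct=distinct)

    def to_dict(self) -> dict:
        return {
            "sites": list(self.sites),
            "common_varieties": sorted(self.common),
            "distinct_varieties": {s: sorted(v) for s, v in self.distinct.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, ensure_ascii=False)


class TraitTable:
    """Tidy tree-level trait records with design bookkeeping.

    Parameters
    ----------
    data
        DataFrame with columns ``site, variety, tree`` plus at least one
        trait column. Missing trait values are ``NaN``.
    trait_names
        Ordered trait columns; defaults to the intersection of
        :data:`TRAIT_NAMES` with the columns present, or to every non-key
        column if none of the canonical names appear.
    require_positive
        Enforce strictly positive trait values (natural-scale tables).
        Standardized (z-scored) tables set this to False.
    """

    def __init__(self, data: pd.DataFrame, trait_names: list[str] | None = None,
                 require_positive: bool = True):
        missing = [c for c in KEY_COLUMNS if c not in data.columns]
        if missing:
            raise ValueError(f"missing mandatory columns: {missing}")
        df = data.copy()
        for col in KEY_COLUMNS:
            df[col] = df[col].map(_norm_label)
        if trait_names is None:
            canon = [t for t in TRAIT_NAMES if t in df.columns]
            trait_names = canon or [c for c in df.columns if c not in KEY_COLUMNS]
        unknown = [t for t in trait_names if t not in df.columns]
        if unknown:
            raise ValueError(f"trait columns not in data: {unknown}")
        if not trait_names:
            raise ValueError("need at least one trait column")
        for t in trait_names:
            df[t] = pd.to_numeric(df[t], errors="raise")
        dup = df.duplicated(subset=KEY_COLUMNS, keep=False)
        if dup.any():
            keys = df.loc[dup, KEY_COLUMNS].drop_duplicates().itertuples(index=False)
            raise ValueError(
                "duplicate (site, variety, tree) keys: "
                + "; ".join(str(tuple(k)) for k in keys)
            )
        if require_positive:
            vals = df[trait_names]
            bad = (vals <= 0) & vals.notna()
            if bad.any().any():
                cols = [c for c in trait_names if bad[c].any()]
                raise ValueError(f"non-positive trait values in columns: {cols}")
        counts = df.groupby(["site", "variety"], sort=False).size()
        odd = counts[(counts < 2) | (counts > 3)]
        if len(odd):
            warnings.warn(
                f"{len(odd)} site x variety cells have tree counts outside 2-3",
                stacklevel=2,
            )
        self.data = df.reset_index(drop=True)[KEY_COLUMNS + trait_names]
        self.trait_names = list(trait_names)
        self.require_positive = require_positive

    # -- basic protocol ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TraitTable):
            return NotImplemented
        return self.trait_names == other.trait_names and self.data.equals(other.data)

    @property
    def design(self) -> StudyDesign:
        return StudyDesign.from_occupancy(self.data)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def read(cls, path, schema: dict[str, str] | None = None,
             require_positive: bool = True) -> "TraitTable":
        """Read a tree-level trait table from CSV (UTF-8, dot decimal).

        ``schema`` maps file column names to canonical names, e.g.
        ``{"Site": "site", "Cultivar": "variety"}``. Empty cells and "NA"
        are read as missing.
        """
        df = pd.read_csv(path, encoding="utf-8", na_values=["NA"], comment="#")
        if schema:
            df = df.rename(columns=schema)
        return cls(df, require_positive=require_positive)

    def write(self, path, provenance: str | None = None) -> None:
        """Write the table as tidy CSV, one row per tree, stable column order."""
        with open(path, "w", encoding="utf-8", newline="") as fh:
            if provenance:
                fh.write(f"# {provenance}\n")
            self.data.to_csv(fh, index=False)

    # -- operations --------------------------------------------------------
    def subset(self, which: str = "all", site: str | None = None) -> "TraitTable":
        """Filter to common varieties, to varieties distinct to ``site``, or identity."""
        design = self.design
        if site is not None and site not in design.sites:
            raise ValueError(f"unknown site label: {site!r}")
        df = self.data
        if which == "all":
            pass
        elif which == "common":
            df = df[df["variety"].isin(design.common)]
        elif which == "distinct":
            if site is None:
                keep = df.apply(
                    lambda r: r["variety"] in design.distinct[r["site"]], axis=1
                )
                df = df[keep] if len(df) else df
            else:
                df = df[(df["site"] == site) & df["variety"].isin(design.distinct[site])]
        else:
            raise ValueError(f"which must be 'common', 'distinct' or 'all', got {which!r}")
        if which != "distinct" and site is not None:
            df = df[df["site"] == site]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return TraitTable(df, self.trait_names, require_positive=self.require_positive)

    def variety_means(self) -> pd.DataFrame:
        """Per-(site, variety, trait) arithmetic mean over trees, ignoring missing.

        Returns a long DataFrame with columns ``site, variety, trait, mean,
        n_trees`` where ``n_trees`` counts the non-missing trees behind each
        mean; a cell with all values missing yields ``mean = NaN, n_trees = 0``.
        """
        long = self.data.melt(
            id_vars=KEY_COLUMNS, value_vars=self.trait_names,
            var_name="trait", value_name="value",
        )
        grouped = long.groupby(["site", "variety", "trait"], sort=False)["value"]
        out = grouped.agg(mean="mean", n_trees="count").reset_index()
        out["n_trees"] = out["n_trees"].astype(int)
        return out

    def trait_vector(self, trait: str, dropna: bool = True) -> pd.DataFrame:
        """Tree-level (site, variety, value) rows for one trait."""
        if trait not in self.trait_names:
            raise KeyError(f"unknown trait: {trait!r}")
        df = self.data[KEY_COLUMNS + [trait]].rename(columns={trait: "value"})
        return df.dropna(subset=["value"]) if dropna else df
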