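"""De Martonne aridity index with supplementary water supply, and class labels.

The De Martonne index I = (MAP + irrigation) / (MAT + 10) summarizes site
aridity from mean annual precipitation (mm), supplementary water supply
(mm, e.g. drip irrigation) and mean annual temperature (deg C); lower
values are more arid. Classes use the standard 10/20/30 thresholds, lower
bound inclusive, except that "humid" is strictly above 30.
"""

from __future__ import annotations

from dataclasses import dataclass

#: (upper bound, label); intervals are [lower, upper) except humid (30, inf).
ARIDITY_CLASSES = [(10.0, "Arid"), (20.0, "Semi-arid"), (30.0, "Subhumid")]


@dataclass(frozen=True)
class ClimateRecord:
    """Mean annual temperature (deg C), precipitation (mm) and irrigation (mm)."""

    MAT: float
    MAP: float
    irrigation: float = 0.0

    def __post_init__(self):
        if self.MAT <= -10.0:
            raise ValueError("De Martonne index undefined for MAT <= -10 degC")
        if self.MAP < 0 or self.irrigation < 0:
            raise ValueError("precipitation and irrigation must be nonnegative")


def de_martonne(record: ClimateRecord) -> float:
    """I = (MAP + irrigation) / (MAT + 10); full precision (round for display)."""
    return (record.MAP + record.irrigation) / (record.MAT + 10.0)


def classify_aridity(index: float) -> str:
    """Map a De Martonne index to its climate class.

    Boundaries: Arid < 10 <= Semi-arid < 20 <= Subhumid <= 30 < Humid
    (30 itself is Subhumid because Humid is strictly ">30").
    """
    if index < 0:
        raise ValueError("aridity index must be nonnegative")
    for upper, label in ARIDITY_CLASSES:
        if index < upper:
            return label
    return "Subhumid" if index == 30.0 else "Humid"
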