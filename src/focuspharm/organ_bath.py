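"""Post-processing of isolated-tissue contraction recordings.

Contraction amplitudes (grams of tension) from organ-bath recordings of
smooth-muscle segments are normalized to active tension (force per estimated
cross-sectional area, g/mm^2) and summarized per drug concentration as
mean +/- SEM. The cross-sectional area of a segment is estimated from its wet
weight and optimal length L0 as wet_weight / (density * L0), with the smooth
muscle density constant 1.05; units follow the recording convention verbatim
(g, mm, g/mm^2) with no conversion layer.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SegmentSpec",
    "ContractionMeasure",
    "active_tension",
    "summarize_response",
    "read_contraction_table",
]

MUSCLE_DENSITY = 1.05


@dataclass(frozen=True)
class SegmentSpec:
    """Physical parameters of one muscle segment."""

    wet_weight: float  # g
    L0: float  # optimal length, mm
    density: float = MUSCLE_DENSITY

    def __post_init__(self) -> None:
        if self.wet_weight <= 0:
            raise ValueError("wet_weight must be positive")
        if self.L0 <= 0:
            raise ValueError("L0 must be positive")
        if self.density <= 0:
            raise ValueError("density must be positive")


@dataclass(frozen=True)
class ContractionMeasure:
    """One contraction amplitude at one drug concentration."""

    concentration: float  # molar
    amplitude: float  # g
    active_tension: float | None = None  # g/mm^2, derived

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")


def active_tension(amplitude: float, segment: SegmentSpec) -> float:
    """Normalize a contraction amplitude to active tension (g/mm^2).

    force/area = amplitude / [wet_weight / (density * L0)], i.e. amplitude
    divided by the estimated cross-sectional area of the segment. Linear in
    amplitude and in L0, inversely proportional to wet weight.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be nonnegative")
    area = segment.wet_weight / (segment.density * segment.L0)
    return amplitude / area


def summarize_response(
    measures: Sequence[ContractionMeasure], value: str = "active_tension"
) -> pd.DataFrame:
    """Per-concentration n, mean and SEM, sorted by concentration.

    SEM = sample standard deviation / sqrt(n); every concentration group must
    have n >= 2 or the SEM is undefined and a ValueError is raised. The
    summary is invariant to the order of measurements within a group.
    """
    if value not in ("active_tension", "amplitude"):
        raise ValueError("value must be 'active_tension' or 'amplitude'")
    rows = []
    for m in measures:
        v = getattr(m, value)
        if v is None:
            raise ValueError(f"measure at {m.concentration} M has no {value}")
        rows.append((m.concentration, v))
    df = pd.DataFrame(rows, columns=["concentration", value])
    counts = df.groupby("concentration")[value].count()
    small = counts[counts < 2]
    if not small.empty:
        raise ValueError(
            f"concentration group(s) with n < 2 (SEM undefined): "
            f"{list(small.index)}"
        )
    out = (
        df.groupby("concentration")[value]
        .agg(n="count", mean="mean", sem=lambda s: s.std(ddof=1) / np.sqrt(len(s)))
        .reset_index()
        .sort_values("concentration")
        .reset_index(drop=True)
    )
    out["n"] = out["n"].astype(int)
    return out


def read_contraction_table(path: str | Path) -> list[ContractionMeasure]:
    """Read a recording CSV (segment_id, concentration, amplitude, wet_weight, L0).

    Active tension is derived per row from that row's segment parameters.
    """
    df = pd.read_csv(path, comment="#")
    required = {"segment_id", "concentration", "amplitude", "wet_weight", "L0"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    measures = []
    for _, row in df.iterrows():
        seg = SegmentSpec(wet_weight=float(row["wet_weight"]), L0=float(row["L0"]))
        amp = float(row["amplitude"])
        measures.append(
            ContractionMeasure(
                concentration=float(row["concentration"]),
                amplitude=amp,
                active_tension=active_tension(amp, seg),
            )
        )
    return measures
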