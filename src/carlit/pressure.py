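"""Land Uses Simplified Index (LUSI) from pressure components.

LUSI = (Urb + Ind + Agr + FW) x coast factor, where the coast factor
corrects for coastline shape (0.75 convex, 1 straight, 1.25 concave).
MA-LUSI-WB values are carried through as metadata, never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

__all__ = ["PressureRecord", "lusi", "lusi_table"]


def lusi(urb: float, ind: float, agr: float, fw: float, coast_factor: float) -> float:
    """LUSI score: component sum scaled by the coast-shape factor."""
    for name, v in (("urb", urb), ("ind", ind), ("agr", agr), ("fw", fw)):
        if v < 0:
            raise ValueError(f"pressure score {name} must be >= 0, got {v}")
    if coast_factor <= 0:
        raise ValueError(f"coast factor must be positive, got {coast_factor}")
    return (urb + ind + agr + fw) * coast_factor


@dataclass(frozen=True)
class PressureRecord:
    """Pressure components of one water body with the derived LUSI."""

    wb: str
    urb: int
    ind: int
    agr: int
    fw: int
    coast_factor: float
    ma_lusi_wb: Optional[float] = None  # passthrough, never computed
    lusi: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "lusi", lusi(self.urb, self.ind, self.agr, self.fw, self.coast_factor)
        )


def lusi_table(pressures: pd.DataFrame) -> pd.DataFrame:
    """Add/replace a ``LUSI`` column computed from Urb/Ind/Agr/FW/Coast."""
    required = {"WB", "Urb", "Ind", "Agr", "FW", "Coast"}
    missing = required - set(pressures.columns)
    if missing:
        raise ValueError(f"pressure table missing columns: {sorted(missing)}")
    out = pressures.copy()
    out["LUSI"] = [
        lusi(r.Urb, r.Ind, r.Agr, r.FW, r.Coast) for r in out.itertuples(index=False)
    ]
    return out
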