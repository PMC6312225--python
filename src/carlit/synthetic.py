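"""Synthetic survey cartographies and EQR panels for testing the pipeline.

``simulate_survey`` draws sector communities from a quality-conditioned
multinomial: category logits are proportional to sensitivity level with a
slope that diverges at the extremes, so latent quality 1 yields only the
most sensitive category (CA5) and quality 0 only the least (BG), while
intermediate qualities spread mass across mid-sensitivity categories.
``simulate_eqr_panel`` draws water-body x year x surveyor panels from the
crossed random-effects structure used by :mod:`carlit.varcomp`.  Both are
deterministic given their seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .catalog import CommunityCatalog, default_catalog
from .scoring import SectorRecord

__all__ = [
    "SurveyScenario",
    "PanelScenario",
    "simulate_survey",
    "simulate_eqr_panel",
    "SURVEY_CATEGORY_POOL",
]

# infralittoral categories eligible for simulated dominance
SURVEY_CATEGORY_POOL = (
    "CA5", "CA4", "CA3", "CA2", "CA1", "CC", "Cor", "EC", "Mgal", "Ulva", "GA", "BG",
)

AREA_NAMES = ("West", "Central", "East")

_DEFAULT_GRS_MIX = {("Low coast", "Natural"): 1.0}


@dataclass(frozen=True)
class SurveyScenario:
    """Design of a simulated cartography.

    ``quality`` is the latent per-water-body quality in [0, 1]; a scalar is
    broadcast to all water bodies.  ``grs_mix`` is a distribution over
    (morphology, substrate) pairs, summing to 1.
    """

    wb_count: int = 1
    sectors_per_area: int = 25
    areas_per_wb: int = 3
    sector_length: float = 50.0
    quality: Union[float, Sequence[float]] = 0.5
    grs_mix: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: dict(_DEFAULT_GRS_MIX)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.wb_count, self.sectors_per_area, self.areas_per_wb) < 1:
            raise ValueError("all counts must be positive")
        if self.sector_length <= 0:
            raise ValueError("sector_length must be positive")
        qs = self.quality_vector()
        if any(not 0 <= q <= 1 for q in qs):
            raise ValueError("quality must lie in [0, 1]")
        total = sum(self.grs_mix.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"grs_mix must sum to 1, got {total}")

    def quality_vector(self) -> list[float]:
        if isinstance(self.quality, (int, float)):
            return [float(self.quality)] * self.wb_count
        qs = [float(q) for q in self.quality]
        if len(qs) != self.wb_count:
            raise ValueError("quality sequence length must equal wb_count")
        return qs


def _category_probabilities(
    quality: float, sls: np.ndarray
) -> np.ndarray:
    """Softmax over scaled sensitivity levels, degenerate at quality 0/1."""
    if quality >= 1.0:
        p = np.zeros(sls.size)
        p[int(np.argmax(sls))] = 1.0
        return p
    if quality <= 0.0:
        p = np.zeros(sls.size)
        p[int(np.argmin(sls))] = 1.0
        return p
    u = (sls - 1.0) / 19.0
    a = 4.0 * math.tan(math.pi * (quality - 0.5))
    logits = np.clip(a * u, -500, 500)
    logits -= logits.max()
    w = np.exp(logits)
    return w / w.sum()


def simulate_survey(
    scenario: SurveyScenario,
    catalog: Optional[CommunityCatalog] = None,
) -> list[SectorRecord]:
    """Generate sector records for every water body of the scenario."""
    catalog = catalog or default_catalog()
    sls = np.array(
        [catalog[a].sensitivity_level for a in SURVEY_CATEGORY_POOL], dtype=float
    )
    rng = np.random.default_rng(scenario.seed)
    grs_keys = list(scenario.grs_mix.keys())
    grs_probs = np.array([scenario.grs_mix[k] for k in grs_keys], dtype=float)
    qualities = scenario.quality_vector()

    sectors: list[SectorRecord] = []
    for w, quality in enumerate(qualities):
        site = f"WB{w + 1:02d}"
        probs = _category_probabilities(quality, sls)
        for a in range(scenario.areas_per_wb):
            area = AREA_NAMES[a] if a < len(AREA_NAMES) else f"Area{a + 1}"
            for _ in range(scenario.sectors_per_area):
                cat = SURVEY_CATEGORY_POOL[int(rng.choice(len(probs), p=probs))]
                morph, nat = grs_keys[int(rng.choice(len(grs_probs), p=grs_probs))]
                sectors.append(
                    SectorRecord(
                        site=site,
                        morphology=morph,
                        substrate=nat,
                        length=scenario.sector_length,
                        community=cat,
                        area=area,
                    )
                )
    return sectors


@dataclass(frozen=True)
class PanelScenario:
    """Generative truth for a WB x Year x Surveyor EQR panel.

    ``var_wb_in_year`` may be a scalar (shared by all water bodies) or a
    mapping keyed by generated water-body names (``WB01`` ...).  Surveyors
    are assigned to contiguous blocks of campaign years.
    """

    n_wb: int = 7
    n_year: int = 4
    n_surveyor: int = 2
    grand_mean: float = 0.7
    var_year: float = 0.0
    var_wb: float = 0.0
    var_surveyor: float = 0.0
    var_wb_in_year: Union[float, Mapping[str, float]] = 0.0
    var_residual: float = 0.004
    clip_to_unit: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_wb, self.n_year, self.n_surveyor) < 1:
            raise ValueError("all counts must be positive")
        slope_vars = self.slope_variances()
        if (
            min(self.var_year, self.var_wb, self.var_surveyor, self.var_residual) < 0
            or any(v < 0 for v in slope_vars.values())
        ):
            raise ValueError("variances must be non-negative")

    def wb_names(self) -> list[str]:
        return [f"WB{i + 1:02d}" for i in range(self.n_wb)]

    def slope_variances(self) -> dict[str, float]:
        if isinstance(self.var_wb_in_year, Mapping):
            return {wb: float(self.var_wb_in_year.get(wb, 0.0)) for wb in self.wb_names()}
        return {wb: float(self.var_wb_in_year) for wb in self.wb_names()}


def simulate_eqr_panel(scenario: PanelScenario) -> pd.DataFrame:
    """Draw one panel (columns WB, Year, Surveyor, EQR) from the truth."""
    rng = np.random.default_rng(scenario.seed)
    wbs = scenario.wb_names()
    years = [2006 + 3 * t for t in range(scenario.n_year)]
    slope_vars = scenario.slope_variances()

    u_year = rng.normal(0.0, math.sqrt(scenario.var_year), size=scenario.n_year)
    u_wb = rng.normal(0.0, math.sqrt(scenario.var_wb), size=scenario.n_wb)
    u_surv = rng.normal(0.0, math.sqrt(scenario.var_surveyor), size=scenario.n_surveyor)
    slopes = {
        wb: rng.normal(0.0, math.sqrt(slope_vars[wb]), size=scenario.n_year)
        for wb in wbs
    }

    rows = []
    for t, year in enumerate(years):
        surv_idx = t * scenario.n_surveyor // scenario.n_year
        for i, wb in enumerate(wbs):
            eqr = (
                scenario.grand_mean
                + u_year[t]
                + u_wb[i]
                + u_surv[surv_idx]
                + slopes[wb][t]
                + rng.normal(0.0, math.sqrt(scenario.var_residual))
            )
            rows.append((wb, str(year), f"S{surv_idx + 1}", eqr))
    panel = pd.DataFrame(rows, columns=["WB", "Year", "Surveyor", "EQR"])
    if scenario.clip_to_unit:
        clipped = panel["EQR"].clip(0.0, 1.0)
        if (clipped != panel["EQR"]).any():
            warnings.warn(
                "EQR values clipped to [0, 1]; variance estimates from clipped "
                "panels are biased",
                stacklevel=2,
            )
        panel["EQR"] = clipped
    return panel
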