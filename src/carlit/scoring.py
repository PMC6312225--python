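"""Sector quality ratios, length-weighted water-body EQR and status classes.

The quality ratio of a sector is the sensitivity level of its dominant
community divided by the reference value EQi of its geomorphological
situation.  Water-body EQR is the sector-length-weighted mean of these
ratios, capped at 1, and the ecological-status class follows the standard
rating scale: 0-0.25 bad, >0.25-0.40 poor, >0.40-0.60 moderate,
>0.60-0.75 good, >0.75-1 high.
"""

from __future__ import annotations

from bisect import bisect_left
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

from .catalog import CommunityCatalog, GeomorphCatalog

__all__ = [
    "SectorRecord",
    "SectorDiagnostic",
    "EqrResult",
    "RatingScale",
    "DEFAULT_SCALE",
    "ConsistencyReport",
    "sector_quality_ratio",
    "waterbody_eqr",
    "classify_es",
    "dominance_profile",
    "intra_seasonal_consistency",
]

ES_CLASSES = ("bad", "poor", "moderate", "good", "high")


@dataclass(frozen=True)
class SectorRecord:
    """One surveyed stretch of coast (typically 50 m).

    ``area`` is optional metadata (e.g. West/Central/East) carried through
    but never used in aggregation: EQR pools all sectors of a water body.
    """

    site: str
    morphology: str
    substrate: str
    length: float
    community: str
    area: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(
                f"sector length must be positive, got {self.length} (site {self.site!r})"
            )


@dataclass(frozen=True)
class SectorDiagnostic:
    """Per-sector ingredients of the water-body EQR."""

    community: str
    sensitivity_level: float
    eq_reference: float
    ratio: float
    length: float
    weight: float


@dataclass(frozen=True)
class EqrResult:
    site: str
    eqr: float
    es_class: str
    total_length: float
    sector_ratios: tuple[SectorDiagnostic, ...] = field(default_factory=tuple)


@dataclass(frozen=True)
class RatingScale:
    """Status-class bands over [0, 1]; boundaries belong to the lower class."""

    boundaries: tuple[float, ...] = (0.25, 0.40, 0.60, 0.75)
    classes: tuple[str, ...] = ES_CLASSES

    def __post_init__(self) -> None:
        if len(self.classes) != len(self.boundaries) + 1:
            raise ValueError("need exactly one more class than boundaries")
        if list(self.boundaries) != sorted(set(self.boundaries)):
            raise ValueError("boundaries must be strictly increasing")
        if self.boundaries and not (0 < self.boundaries[0] and self.boundaries[-1] < 1):
            raise ValueError("boundaries must lie strictly inside (0, 1)")

    def classify(self, eqr: float) -> str:
        if not 0 <= eqr <= 1:
            raise ValueError(f"EQR must lie in [0, 1], got {eqr}")
        return self.classes[bisect_left(self.boundaries, eqr)]

    def rank(self, es_class: str) -> int:
        return self.classes.index(es_class)


DEFAULT_SCALE = RatingScale()


def sector_quality_ratio(
    sector: SectorRecord,
    catalog: CommunityCatalog,
    refs: GeomorphCatalog,
) -> float:
    """SL(community) / EQi(morphology, substrate); may exceed 1 before capping."""
    try:
        sl = catalog.sensitivity_level(sector.community)
        eqi = refs.reference_eq(sector.morphology, sector.substrate)
    except KeyError as exc:
        raise type(exc)(
            f"sector (site {sector.site!r}, community {sector.community!r}): {exc.args[0]}"
        ) from None
    return sl / eqi


def waterbody_eqr(
    sectors: Sequence[SectorRecord],
    catalog: CommunityCatalog,
    refs: GeomorphCatalog,
    *,
    cap: bool = True,
    cap_sectors: bool = False,
    exclude_mediolittoral: bool = False,
    scale: RatingScale = DEFAULT_SCALE,
) -> EqrResult:
    """Length-weighted EQR of one water body and its status class.

    EQR = sum(ratio_s * length_s) / sum(length_s), capped at 1 when ``cap``
    is on (default).  ``cap_sectors`` instead caps each sector ratio at 1
    before averaging.  ``exclude_mediolittoral`` drops sectors whose every
    label component is mediolittoral-only (Trottoir) when infralittoral
    sectors are also present.
    """
    sectors = list(sectors)
    if not sectors:
        raise ValueError("cannot compute EQR of an empty sector list")
    sites = {s.site for s in sectors}
    if len(sites) > 1:
        raise ValueError(f"sectors span multiple sites: {sorted(sites)}")
    site = sectors[0].site

    if exclude_mediolittoral:
        def is_medio(s: SectorRecord) -> bool:
            return all(c.mediolittoral_only for c in catalog.parse_label(s.community))

        infra = [s for s in sectors if not is_medio(s)]
        if infra:
            sectors = infra

    diagnostics = []
    num = 0.0
    total = sum(s.length for s in sectors)
    for s in sectors:
        ratio = sector_quality_ratio(s, catalog, refs)
        if cap_sectors:
            ratio = min(ratio, 1.0)
        weight = s.length / total
        num += ratio * s.length
        diagnostics.append(
            SectorDiagnostic(
                community=s.community,
                sensitivity_level=catalog.sensitivity_level(s.community),
                eq_reference=refs.reference_eq(s.morphology, s.substrate),
                ratio=ratio,
                length=s.length,
                weight=weight,
            )
        )
    eqr = num / total
    if cap:
        eqr = min(eqr, 1.0)
    return EqrResult(
        site=site,
        eqr=eqr,
        es_class=scale.classify(min(eqr, 1.0)),  # class always from the capped value
        total_length=total,
        sector_ratios=tuple(diagnostics),
    )


def classify_es(eqr: float, scale: RatingScale = DEFAULT_SCALE) -> str:
    """Status class of an EQR value under the rating scale."""
    return scale.classify(eqr)


def dominance_profile(
    sectors: Sequence[SectorRecord],
    catalog: Optional[CommunityCatalog] = None,
) -> dict[str, float]:
    """Percent of surveyed length dominated by each community label.

    Compound labels (e.g. ``CC+Cor``) are kept as their own key.  When a
    catalogue is supplied, labels are normalized to canonical acronym case;
    otherwise only whitespace around ``+`` is stripped.
    """
    sectors = list(sectors)
    if not sectors:
        raise ValueError("cannot profile an empty sector list")
    total = sum(s.length for s in sectors)
    profile: dict[str, float] = {}
    for s in sectors:
        if catalog is not None:
            key = catalog.canonical_label(s.community)
        else:
            key = "+".join(p.strip() for p in str(s.community).split("+"))
        profile[key] = profile.get(key, 0.0) + 100.0 * s.length / total
    return profile


@dataclass(frozen=True)
class ConsistencyReport:
    """Agreement of monthly status classes within one site."""

    modal_class: str
    consistent: bool
    deviating_months: frozenset[str]
    tie_broken: bool = False


def intra_seasonal_consistency(
    monthly_results: Sequence[tuple[str, Union[EqrResult, str]]],
    scale: RatingScale = DEFAULT_SCALE,
) -> ConsistencyReport:
    """Check whether monthly surveys of a site agree on the status class.

    Reports the modal class, whether all months agree, and the months that
    deviate from the mode.  Modal ties are broken by dropping the earliest
    month(s) until the tie resolves (later months carry the season's
    developed assemblage); ``tie_broken`` flags when this was needed.
    """
    if len(monthly_results) < 2:
        raise ValueError("need at least two months to assess consistency")
    months = [m for m, _ in monthly_results]
    classes = [
        r.es_class if isinstance(r, EqrResult) else str(r) for _, r in monthly_results
    ]
    for c in classes:
        if c not in scale.classes:
            raise ValueError(f"unknown status class {c!r}")

    def modal(sub: Sequence[str]) -> tuple[Optional[str], bool]:
        counts = Counter(sub)
        top = max(counts.values())
        tied = [c for c, n in counts.items() if n == top]
        if len(tied) == 1:
            return tied[0], False
        return None, True

    mode, tie = modal(classes)
    tie_broken = False
    start = 0
    while mode is None and start < len(classes) - 1:
        start += 1
        tie_broken = True
        mode, tie = modal(classes[start:])
    if mode is None:  # tie persisted to the last month
        mode = classes[-1]
        tie_broken = True

    deviating = frozenset(m for m, c in zip(months, classes) if c != mode)
    return ConsistencyReport(
        modal_class=mode,
        consistent=not deviating,
        deviating_months=deviating,
        tie_broken=tie_broken,
    )
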