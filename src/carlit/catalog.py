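"""Community sensitivity catalogue and geomorphological reference values.

The two catalogues driving the index are shipped as editable CSV data files
(``data/sensitivity_levels.csv`` and ``data/reference_eq.csv``) so regional
recalibrations can be supplied without touching code.  The default sensitivity
catalogue maps the 19 standard community-category acronyms (TR, CB, Cs, CA5,
CA4, CA3, CA2, CC, CA1, DS, Cor, EC, Mgal, Ulva, GA, BG, Pos, Cym, Zos) to
sensitivity levels on the 1-20 scale; the reference catalogue maps the six
geomorphological relevant situations (coastal morphology x substrate) to their
reference ecological-quality value EQi.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Union

__all__ = [
    "CommunityCategory",
    "CommunityCatalog",
    "GeomorphSituation",
    "GeomorphCatalog",
    "UnknownCommunityError",
    "UnknownSituationError",
    "parse_community_label",
    "sensitivity_level",
    "reference_eq",
    "default_catalog",
    "default_references",
]


class UnknownCommunityError(KeyError):
    """A community acronym does not resolve to any catalogue entry."""


class UnknownSituationError(KeyError):
    """A (morphology, substrate) pair matches no reference situation."""


@dataclass(frozen=True)
class CommunityCategory:
    """One community category: acronym, description, sensitivity level.

    ``mediolittoral_only`` flags categories (Trottoir) recorded in the
    mediolittoral zone rather than the infralittoral fringe.
    """

    acronym: str
    description: str
    sensitivity_level: float
    mediolittoral_only: bool = False

    def __post_init__(self) -> None:
        if not 1 <= self.sensitivity_level <= 20:
            raise ValueError(
                f"sensitivity level for {self.acronym!r} must lie in [1, 20], "
                f"got {self.sensitivity_level}"
            )


class CommunityCatalog:
    """A collection of :class:`CommunityCategory` entries keyed by acronym.

    Acronym matching is case-insensitive after whitespace trimming.  Compound
    labels joined with ``+`` denote sectors equally dominated by several
    categories and are scored by averaging the component sensitivity levels.
    """

    def __init__(self, entries: Iterable[CommunityCategory]):
        self._entries: dict[str, CommunityCategory] = {}
        for entry in entries:
            key = entry.acronym.strip().upper()
            if key in self._entries:
                raise ValueError(f"duplicate acronym in catalogue: {entry.acronym!r}")
            self._entries[key] = entry

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[CommunityCategory]:
        return iter(self._entries.values())

    def __contains__(self, acronym: str) -> bool:
        return acronym.strip().upper() in self._entries

    def __getitem__(self, acronym: str) -> CommunityCategory:
        key = acronym.strip().upper()
        try:
            return self._entries[key]
        except KeyError:
            raise UnknownCommunityError(
                f"unknown community category {acronym.strip()!r}"
            ) from None

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "CommunityCatalog":
        """Read a catalogue from a CSV with columns Community, Description, SL.

        An optional ``Zone`` column may mark ``mediolittoral`` categories;
        absent, all entries are treated as infralittoral.
        """
        entries = []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            required = {"Community", "Description", "SL"}
            missing = required - set(reader.fieldnames or [])
            if missing:
                raise ValueError(f"sensitivity table missing columns: {sorted(missing)}")
            for row in reader:
                entries.append(
                    CommunityCategory(
                        acronym=row["Community"].strip(),
                        description=row["Description"].strip(),
                        sensitivity_level=float(row["SL"]),
                        mediolittoral_only=(
                            row.get("Zone", "").strip().lower() == "mediolittoral"
                        ),
                    )
                )
        return cls(entries)

    def parse_label(self, label: str) -> list[CommunityCategory]:
        """Resolve a (possibly compound) community label to catalogue entries.

        Components are separated by ``+`` and matched case-insensitively after
        stripping whitespace; component order is preserved.
        """
        if label is None or not str(label).strip():
            raise ValueError("community label must be non-empty")
        parts = [p.strip() for p in str(label).split("+")]
        if any(not p for p in parts):
            raise ValueError(f"malformed community label {label!r}")
        if len(parts) > 2:
            warnings.warn(
                f"label {label!r} combines {len(parts)} categories; the "
                "co-dominance rule is defined for pairs and is extended by "
                "averaging over all components",
                stacklevel=2,
            )
        return [self[p] for p in parts]

    def sensitivity_level(self, label: str) -> float:
        """Sensitivity level of a label; compound labels average components.

        Example: a sector equally dominated by Cor (SL 8) and Mgal (SL 6)
        scores (8 + 6) / 2 = 7.
        """
        cats = self.parse_label(label)
        return sum(c.sensitivity_level for c in cats) / len(cats)

    def canonical_label(self, label: str) -> str:
        """Normalize a label to catalogue-cased acronyms joined by ``+``."""
        return "+".join(c.acronym for c in self.parse_label(label))


@dataclass(frozen=True)
class GeomorphSituation:
    """One geomorphological relevant situation and its reference value EQi."""

    grs_id: int
    coastal_morphology: str
    substrate: str
    eq_reference: float

    def __post_init__(self) -> None:
        if self.eq_reference <= 0:
            raise ValueError("eq_reference must be positive")


def _grs_key(morphology: str, substrate: str) -> tuple[str, str]:
    return morphology.strip().lower(), substrate.strip().lower()


class GeomorphCatalog:
    """Reference EQi values keyed by (coastal morphology, substrate)."""

    def __init__(self, situations: Iterable[GeomorphSituation]):
        self._by_key: dict[tuple[str, str], GeomorphSituation] = {}
        for s in situations:
            key = _grs_key(s.coastal_morphology, s.substrate)
            if key in self._by_key:
                raise ValueError(
                    f"duplicate situation ({s.coastal_morphology}, {s.substrate})"
                )
            self._by_key[key] = s

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self) -> Iterator[GeomorphSituation]:
        return iter(self._by_key.values())

    def lookup(self, morphology: str, substrate: str) -> GeomorphSituation:
        try:
            return self._by_key[_grs_key(morphology, substrate)]
        except KeyError:
            raise UnknownSituationError(
                f"no reference situation for morphology={morphology.strip()!r}, "
                f"substrate={substrate.strip()!r}"
            ) from None

    def reference_eq(self, morphology: str, substrate: str) -> float:
        return self.lookup(morphology, substrate).eq_reference

    @property
    def morphologies(self) -> set[str]:
        return {s.coastal_morphology for s in self}

    @property
    def substrates(self) -> set[str]:
        return {s.substrate for s in self}

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "GeomorphCatalog":
        """Read references from a CSV with columns GRS, Morphology, NatArt, EQi."""
        situations = []
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            required = {"GRS", "Morphology", "NatArt", "EQi"}
            missing = required - set(reader.fieldnames or [])
            if missing:
                raise ValueError(f"reference table missing columns: {sorted(missing)}")
            for row in reader:
                situations.append(
                    GeomorphSituation(
                        grs_id=int(row["GRS"]),
                        coastal_morphology=row["Morphology"].strip(),
                        substrate=row["NatArt"].strip(),
                        eq_reference=float(row["EQi"]),
                    )
                )
        return cls(situations)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("carlit").joinpath("data", name)))


def default_catalog() -> CommunityCatalog:
    """The shipped 19-category sensitivity catalogue."""
    return CommunityCatalog.from_csv(_data_path("sensitivity_levels.csv"))


def default_references() -> GeomorphCatalog:
    """The shipped six-situation reference table."""
    return GeomorphCatalog.from_csv(_data_path("reference_eq.csv"))


# Functional aliases mirroring the object API.

def parse_community_label(label: str, catalog: CommunityCatalog) -> list[CommunityCategory]:
    return catalog.parse_label(label)


def sensitivity_level(label: str, catalog: CommunityCatalog) -> float:
    return catalog.sensitivity_level(label)


def reference_eq(morphology: str, substrate: str, refs: GeomorphCatalog) -> float:
    return refs.reference_eq(morphology, substrate)
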