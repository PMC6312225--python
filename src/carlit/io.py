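"""CSV readers/writers, GeoJSON export and the pipeline orchestrator.

Survey files follow the field layout: columns Site, Morphology, NatArt,
Length, Community (order-tolerant, names exact; extra columns are ignored
with a warning).  All files are UTF-8, comma-separated, point decimals.
"""

from __future__ import annotations

import json
import logging
import platform
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .catalog import (
    CommunityCatalog,
    GeomorphCatalog,
    default_catalog,
    default_references,
)
from .pressure import lusi_table
from .scoring import (
    EqrResult,
    RatingScale,
    SectorRecord,
    dominance_profile,
    waterbody_eqr,
)
from .varcomp import ModelStructure, VarianceComponents, fit_reml, validate_panel

__all__ = [
    "SurveyValidationError",
    "read_survey",
    "write_survey",
    "read_panel",
    "read_pressures",
    "write_eqr_results",
    "write_dominance",
    "write_variance_report",
    "sectors_to_geojson",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger("carlit")

SURVEY_COLUMNS = ("Site", "Morphology", "NatArt", "Length", "Community")


class SurveyValidationError(ValueError):
    """A survey row failed validation; the message cites the row number."""


def read_survey(
    path: Union[str, Path],
    refs: Optional[GeomorphCatalog] = None,
) -> list[SectorRecord]:
    """Read and validate a survey CSV into sector records.

    Row numbers in error messages count data rows from 1 (header excluded).
    Morphology/substrate vocabulary is checked against ``refs`` (defaults to
    the shipped reference table).
    """
    refs = refs or default_references()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(SURVEY_COLUMNS) - set(df.columns)
    if missing:
        raise SurveyValidationError(
            f"{path}: missing required columns: {sorted(missing)}"
        )
    extras = [c for c in df.columns if c not in SURVEY_COLUMNS]
    if extras:
        warnings.warn(f"{path}: ignoring extra columns {extras}", stacklevel=2)

    morphs = {m.lower() for m in refs.morphologies}
    substrates = {s.lower() for s in refs.substrates}
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            length = float(getattr(row, "Length"))
        except ValueError:
            raise SurveyValidationError(
                f"{path}: row {i}: non-numeric Length {getattr(row, 'Length')!r}"
            ) from None
        if length <= 0:
            raise SurveyValidationError(f"{path}: row {i}: Length must be > 0, got {length}")
        morph = getattr(row, "Morphology").strip()
        nat = getattr(row, "NatArt").strip()
        if morph.lower() not in morphs:
            raise SurveyValidationError(
                f"{path}: row {i}: unknown Morphology {morph!r} "
                f"(expected one of {sorted(refs.morphologies)})"
            )
        if nat.lower() not in substrates:
            raise SurveyValidationError(
                f"{path}: row {i}: unknown NatArt {nat!r} "
                f"(expected one of {sorted(refs.substrates)})"
            )
        records.append(
            SectorRecord(
                site=getattr(row, "Site").strip(),
                morphology=morph,
                substrate=nat,
                length=length,
                community=getattr(row, "Community").strip(),
            )
        )
    return records


def write_survey(sectors: Sequence[SectorRecord], path: Union[str, Path]) -> None:
    df = pd.DataFrame(
        [
            (s.site, s.morphology, s.substrate, s.length, s.community)
            for s in sectors
        ],
        columns=list(SURVEY_COLUMNS),
    )
    df.to_csv(path, index=False)


def read_panel(path: Union[str, Path], *, allow_replicates: bool = False) -> pd.DataFrame:
    return validate_panel(pd.read_csv(path), allow_replicates=allow_replicates)


def read_pressures(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"WB", "Urb", "Ind", "Agr", "FW", "Coast"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: pressure table missing columns: {sorted(missing)}")
    return df


def write_eqr_results(
    results: Sequence[EqrResult], path: Union[str, Path]
) -> None:
    """Write site, eqr (4 decimals) and es_class per water body."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("Site,EQR,ES\n")
        for r in results:
            fh.write(f"{r.site},{r.eqr:.4f},{r.es_class}\n")


def write_dominance(
    profiles: dict[str, dict[str, float]], path: Union[str, Path]
) -> None:
    """Write per-site community dominance percentages (long format)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("Site,Community,PercentLength\n")
        for site in sorted(profiles):
            for label in sorted(profiles[site]):
                fh.write(f"{site},{label},{profiles[site][label]:.4f}\n")


def write_variance_report(
    components: VarianceComponents, path: Union[str, Path]
) -> None:
    """Write a Groups / Std.dev. / Variance / P_samp table."""
    fractions = components.fractions(rounded=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("Groups,Std.dev.,Variance,P_samp\n")
        for name, var in components.as_dict().items():
            fh.write(f"{name},{var ** 0.5:.5f},{var:.6f},{fractions[name]}\n")


def sectors_to_geojson(
    sectors: Sequence[SectorRecord],
    properties: Optional[Sequence[dict]] = None,
) -> dict:
    """GeoJSON FeatureCollection laying sectors end-to-end along the x axis.

    Sectors are abstract 1-D stretches; coordinates are synthetic (meters
    from the start of the survey) and intended for inspection in GIS tools,
    not for georeferencing.
    """
    features = []
    x = 0.0
    for i, s in enumerate(sectors):
        props = {
            "site": s.site,
            "morphology": s.morphology,
            "substrate": s.substrate,
            "length": s.length,
            "community": s.community,
        }
        if s.area is not None:
            props["area"] = s.area
        if properties is not None:
            props.update(properties[i])
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "LineString",
                    "coordinates": [[x, 0.0], [x + s.length, 0.0]],
                },
                "properties": props,
            }
        )
        x += s.length
    return {"type": "FeatureCollection", "features": features}


@dataclass
class RunConfig:
    """Inputs and options for one end-to-end pipeline run."""

    output_dir: Union[str, Path]
    survey: Optional[Union[str, Path]] = None
    sensitivity_table: Optional[Union[str, Path]] = None
    reference_table: Optional[Union[str, Path]] = None
    pressures: Optional[Union[str, Path]] = None
    panel: Optional[Union[str, Path]] = None
    cap: bool = True
    cap_sectors: bool = False
    boundaries: tuple[float, ...] = (0.25, 0.40, 0.60, 0.75)
    structure: ModelStructure = field(default_factory=ModelStructure)
    seed: int = 0
    geojson: bool = False

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        if "structure" in raw and isinstance(raw["structure"], str):
            raw["structure"] = ModelStructure.from_spec(raw["structure"])
        if "boundaries" in raw:
            raw["boundaries"] = tuple(raw["boundaries"])
        return cls(**raw)


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Score surveys, compute LUSI, partition variance; write all outputs.

    Returns a mapping from output name to written path.  Any stage error
    propagates with the stage named in the exception message.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    scale = RatingScale(boundaries=config.boundaries)

    catalog = (
        CommunityCatalog.from_csv(config.sensitivity_table)
        if config.sensitivity_table
        else default_catalog()
    )
    refs = (
        GeomorphCatalog.from_csv(config.reference_table)
        if config.reference_table
        else default_references()
    )

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    if config.survey:
        def score_stage():
            sectors = read_survey(config.survey, refs)
            by_site: dict[str, list[SectorRecord]] = {}
            for s in sectors:
                by_site.setdefault(s.site, []).append(s)
            results = [
                waterbody_eqr(
                    site_sectors,
                    catalog,
                    refs,
                    cap=config.cap,
                    cap_sectors=config.cap_sectors,
                    scale=scale,
                )
                for site_sectors in by_site.values()
            ]
            results.sort(key=lambda r: r.site)
            eqr_path = out_dir / "eqr.csv"
            write_eqr_results(results, eqr_path)
            outputs["eqr"] = eqr_path
            dom_path = out_dir / "dominance.csv"
            write_dominance(
                {
                    site: dominance_profile(site_sectors, catalog)
                    for site, site_sectors in by_site.items()
                },
                dom_path,
            )
            outputs["dominance"] = dom_path
            if config.geojson:
                diag = []
                for site in sorted(by_site):
                    res = next(r for r in results if r.site == site)
                    for d in res.sector_ratios:
                        diag.append({"ratio": d.ratio, "es_class": res.es_class})
                gj_path = out_dir / "sectors.geojson"
                ordered = [s for site in sorted(by_site) for s in by_site[site]]
                with open(gj_path, "w", encoding="utf-8") as fh:
                    json.dump(sectors_to_geojson(ordered, diag), fh, indent=1)
                outputs["geojson"] = gj_path

        _stage("score", score_stage)

    if config.pressures:
        def pressure_stage():
            table = lusi_table(read_pressures(config.pressures))
            path = out_dir / "lusi.csv"
            table.to_csv(path, index=False)
            outputs["lusi"] = path

        _stage("pressure", pressure_stage)

    if config.panel:
        def varcomp_stage():
            panel = read_panel(config.panel)
            components = fit_reml(panel, config.structure, seed=config.seed)
            path = out_dir / "variance_components.csv"
            write_variance_report(components, path)
            outputs["varcomp"] = path

        _stage("varcomp", varcomp_stage)

    log_path = out_dir / "run_log.json"
    log = {
        "carlit_version": __version__,
        "python_version": platform.python_version(),
        "seed": config.seed,
        "config": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in {
                "survey": config.survey,
                "sensitivity_table": config.sensitivity_table,
                "reference_table": config.reference_table,
                "pressures": config.pressures,
                "panel": config.panel,
                "cap": config.cap,
                "cap_sectors": config.cap_sectors,
                "boundaries": list(config.boundaries),
                "structure": config.structure.name,
                "geojson": config.geojson,
            }.items()
        },
        "outputs": {k: str(v) for k, v in outputs.items()},
    }
    with open(log_path, "w", encoding="utf-8") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
    outputs["log"] = log_path
    return outputs
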