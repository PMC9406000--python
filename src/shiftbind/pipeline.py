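"""End-to-end orchestration: CSP → significance → site fits → occupancy.

A :class:`RunConfig` names the input peak lists (reference plus titration
points with their ligand concentrations), the binding-site definitions,
and the analysis parameters; :func:`run_pipeline` executes the stages in
order and returns a validated, machine-readable report.  Deterministic
content and run metadata (timestamps) are kept in separate fields so
that two runs with the same config produce byte-identical results
sections.
"""

from __future__ import annotations

import json
import logging
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .binding_model import (
    BindingSiteDef,
    TTR_SITES,
    fit_site,
    fraction_bound,
    kd_ratio,
    load_sites_yaml,
)
from .csp_profile import build_profile, significance
from .peaklist_io import Condition, read_sparky_list, write_csp_table

__all__ = [
    "RunConfig",
    "PipelineError",
    "Report",
    "run_pipeline",
    "report_json_schema",
]

logger = logging.getLogger("shiftbind")

REPORT_SCHEMA_VERSION = 1


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


class PointSpec(BaseModel):
    path: Path
    ligand_conc: float = Field(ge=0, description="total ligand, mM")


class RunConfig(BaseModel):
    """Validated configuration of one pipeline run."""

    reference: Path
    points: list[PointSpec]
    protein_conc_monomer: float = Field(default=0.1, gt=0, description="mM")
    scale_N: float = Field(default=6.5, gt=0)
    sites: str | Path = "ttr_sites"
    occupancy_ligand_conc: float = Field(
        default=2.4, ge=0, description="free-ligand concentration for the occupancy estimate, mM"
    )
    significance_point: Optional[float] = Field(
        default=None, description="ligand conc (mM) at which to flag; default = last point"
    )
    csp_out: Optional[Path] = None
    seed: int = 0

    def validate_paths(self) -> None:
        missing = [
            str(p)
            for p in [self.reference, *(pt.path for pt in self.points)]
            if not Path(p).exists()
        ]
        if missing:
            raise PipelineError("config", f"input files not found: {missing}")


class SiteFitReport(BaseModel):
    site_id: str
    residues: list[int]
    kd_mM: float
    kd_se_mM: float
    dmax_ppm: dict[str, float]
    dmax_se_ppm: dict[str, float]
    r_squared: float
    p_value: float
    n_obs: int
    converged: bool


class SignificanceReport(BaseModel):
    ligand_conc_mM: float
    mean_ppm: float
    sd_ppm: float
    threshold_ppm: float
    n_tracked: int
    flagged: list[int]


class OccupancyReport(BaseModel):
    site_id: str
    kd_mM: float
    ligand_conc_mM: float
    fraction_bound: float
    percent: int


class ReportResults(BaseModel):
    n_points: int
    n_residues_reference: int
    significance: SignificanceReport
    site_fits: list[SiteFitReport]
    occupancy: list[OccupancyReport]
    kd_ratios: dict[str, float]


class ReportMetadata(BaseModel):
    created_utc: str
    shiftbind_version: str
    config: dict


class Report(BaseModel):
    """Versioned machine-readable pipeline report."""

    schema_version: int = REPORT_SCHEMA_VERSION
    results: ReportResults
    metadata: ReportMetadata


def report_json_schema() -> dict:
    """JSON schema the pipeline report validates against."""
    return Report.model_json_schema()


def _load_sites(source: str | Path) -> dict[str, BindingSiteDef]:
    if str(source) == "ttr_sites":
        return dict(TTR_SITES)
    return load_sites_yaml(source)


def run_pipeline(config: RunConfig) -> Report:
    """Execute csp → significance → site fits → occupancy and report."""
    config.validate_paths()

    stage = "read"
    try:
        ref = read_sparky_list(
            config.reference,
            Condition(
                ligand_conc=0.0, protein_conc_monomer=config.protein_conc_monomer
            ),
        )
        tables = [ref]
        for pt in config.points:
            tables.append(
                read_sparky_list(
                    pt.path,
                    Condition(
                        ligand_conc=pt.ligand_conc,
                        protein_conc_monomer=config.protein_conc_monomer,
                    ),
                )
            )
    except (OSError, ValueError) as exc:
        raise PipelineError(stage, str(exc)) from exc
    logger.info("read %d titration points, %d reference residues", len(tables), len(ref))

    stage = "csp"
    try:
        profile = build_profile(tables, scale_N=config.scale_N)
        if config.csp_out is not None:
            write_csp_table(profile, config.csp_out)
    except (OSError, ValueError) as exc:
        raise PipelineError(stage, str(exc)) from exc

    stage = "significance"
    try:
        if config.significance_point is None:
            idx = len(profile.points) - 1
        else:
            idx = profile.point_index_near(config.significance_point)
        sig = significance(profile, idx)
    except ValueError as exc:
        raise PipelineError(stage, str(exc)) from exc
    logger.info(
        "significance at %g mM: %d tracked, %d flagged",
        profile.points[idx].ligand_conc,
        sig.n_tracked,
        len(sig.flagged),
    )

    stage = "fit"
    try:
        sites = _load_sites(config.sites)
        fits = [
            fit_site(profile, site, T0=config.protein_conc_monomer)
            for site in sites.values()
        ]
    except (OSError, ValueError) as exc:
        raise PipelineError(stage, str(exc)) from exc
    for f in fits:
        logger.info(
            "%s: Kd = %.2f ± %.2f mM (R² = %.4f, n = %d)",
            f.site_id, f.kd, f.kd_se, f.r_squared, f.n_obs,
        )

    stage = "occupancy"
    occupancy = [
        fraction_bound(config.occupancy_ligand_conc, f.kd) for f in fits
    ]
    ratios: dict[str, float] = {}
    for i, a in enumerate(fits):
        for b in fits[i + 1 :]:
            ratios[f"{a.site_id}/{b.site_id}"] = kd_ratio(a.kd, b.kd)[0]

    results = ReportResults(
        n_points=len(profile.points),
        n_residues_reference=len(ref),
        significance=SignificanceReport(
            ligand_conc_mM=profile.points[idx].ligand_conc,
            mean_ppm=sig.mean,
            sd_ppm=sig.sd,
            threshold_ppm=sig.threshold,
            n_tracked=sig.n_tracked,
            flagged=sorted(sig.flagged),
        ),
        site_fits=[
            SiteFitReport(
                site_id=f.site_id,
                residues=list(f.residues),
                kd_mM=f.kd,
                kd_se_mM=f.kd_se,
                dmax_ppm={str(r): v for r, v in f.dmax.items()},
                dmax_se_ppm={str(r): v for r, v in f.dmax_se.items()},
                r_squared=f.r_squared,
                p_value=f.p_value,
                n_obs=f.n_obs,
                converged=f.converged,
            )
            for f in fits
        ],
        occupancy=[
            OccupancyReport(
                site_id=f.site_id,
                kd_mM=o.kd,
                ligand_conc_mM=o.ligand_conc,
                fraction_bound=o.fraction_bound,
                percent=o.percent,
            )
            for f, o in zip(fits, occupancy)
        ],
        kd_ratios=ratios,
    )
    metadata = ReportMetadata(
        created_utc=datetime.now(timezone.utc).isoformat(),
        shiftbind_version=__version__,
        config=json.loads(config.model_dump_json()),
    )
    return Report(results=results, metadata=metadata)


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML; relative paths resolve against the
    config file's directory."""
    path = Path(path)
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    base = path.parent
    raw["reference"] = base / raw["reference"]
    pts = []
    for p in raw.get("points", []):
        if isinstance(p, dict):
            pts.append({"path": base / p["path"], "ligand_conc": p["ligand_conc"]})
        else:  # "file:conc" shorthand
            fname, conc = str(p).rsplit(":", 1)
            pts.append({"path": base / fname, "ligand_conc": float(conc)})
    raw["points"] = pts
    if "sites" in raw and raw["sites"] != "ttr_sites":
        raw["sites"] = base / raw["sites"]
    return RunConfig(**raw)
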