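"""End-to-end pipeline: structure -> permittivity map -> energy ledger ->
titration (-> ensemble statistics), driven by a YAML-able RunConfig.

A run directory receives: the permittivity map (OpenDX), the energy ledger
and interaction matrix (TSV), titration curves (TSV), per-site pKas (JSON),
an uncertainty report (JSON, when frames are given) and a JSON-lines log of
every resolved default.  Reruns with the same config and seed are
deterministic.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dielectric_model import (
    DielectricScene,
    MembraneSlab,
    grid_from_structure,
    write_dx,
)
from .ensemble_stats import averaged_pka, per_frame_components
from .pb_solver import SolverSettings
from .pka_engine import EngineSettings, build_microstate_model, compute_ledger
from .structure_io import (
    SitePolicy,
    assign_parse,
    find_titratable_sites,
    read_frames,
    read_structure,
)
from .titration import EXACT_SITE_LIMIT, titrate_exact, titrate_mc

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    structure: str | None = None
    frames: str | None = None
    output_dir: str = "pka_run"
    seed: int = 0
    grid_spacing: float = 1.0
    grid_margin: float = 15.0
    fine_spacing: float = 0.5
    eps_solvent: float = 81.0
    ionic_strength: float = 0.2
    temperature: float = 298.0
    membrane: dict | None = None  # {z_core: [lo, hi], eps_core, eps_head, headgroup_thickness}
    site_residues: list[str] = field(
        default_factory=lambda: ["ASP", "GLU", "LYS", "ARG", "TYR"]
    )
    tyr_whitelist: list | None = None
    titration_method: str = "auto"
    ph_step: float = 0.2
    ph_min: float = 0.0
    ph_max: float = 14.0
    mc_scans: int | None = None
    strip_solvent: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        if (self.structure is None) == (self.frames is None):
            raise PipelineError("config", "exactly one of 'structure' or 'frames' is required")
        path = self.structure or self.frames
        if not Path(path).exists():
            raise PipelineError("config", f"input file {path} does not exist")

    def slab(self) -> MembraneSlab | None:
        if not self.membrane:
            return None
        zlo, zhi = self.membrane["z_core"]
        return MembraneSlab(
            core_zmin=float(zlo),
            core_zmax=float(zhi),
            headgroup_thickness=float(self.membrane.get("headgroup_thickness", 8.0)),
            eps_core=float(self.membrane.get("eps_core", 2.0)),
            eps_head=float(self.membrane.get("eps_head", 20.0)),
        )

    def policy(self) -> SitePolicy:
        wl = None
        if self.tyr_whitelist is not None:
            wl = frozenset((str(c), int(n)) for c, n in self.tyr_whitelist)
        return SitePolicy(residues=frozenset(self.site_residues), tyr_whitelist=wl)


def run_pipeline(config: RunConfig | str | Path) -> dict:
    """Execute the full chain; returns a summary dict (also written to disk).

    Any stage failure raises PipelineError naming the stage; outputs of the
    stages that already completed stay in the run directory.
    """
    if not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run_log.jsonl"

    def log(event: str, **kw):
        with log_path.open("a") as fh:
            fh.write(json.dumps({"t": time.time(), "event": event, **kw}) + "\n")

    (out / "resolved_config.yaml").write_text(yaml.safe_dump(asdict(config)))
    log("config", resolved=asdict(config))

    stage = "read_structure"
    try:
        if config.structure:
            frames = [read_structure(config.structure, strip_solvent=config.strip_solvent)]
        else:
            frames = read_frames(config.frames, strip_solvent=config.strip_solvent)
        frames = [assign_parse(f) for f in frames]
        log(stage, n_frames=len(frames), n_atoms=len(frames[0].atoms))

        stage = "sites"
        policy = config.policy()
        sites = find_titratable_sites(frames[0], policy)
        if not sites:
            raise PipelineError(stage, "no titratable sites found under the site policy")
        log(stage, n_sites=len(sites), site_ids=[s.site_id for s in sites])

        stage = "eps_map"
        grid = grid_from_structure(frames[0], config.grid_spacing, config.grid_margin)
        scene = DielectricScene(
            structure=frames[0],
            eps_solvent=config.eps_solvent,
            ionic_strength=config.ionic_strength,
            slab=config.slab(),
        )
        dmap = scene.rasterize(grid)
        write_dx(dmap, path=out / "eps_map.dx")
        write_dx(grid, dmap.region_labels.astype(float), path=out / "eps_regions.dx")
        log(stage, dims=list(grid.dims), spacing=grid.spacing)

        solver = SolverSettings(
            ionic_strength=config.ionic_strength, temperature=config.temperature
        )
        settings = EngineSettings(solver=solver, fine_spacing=config.fine_spacing)
        ph_grid = np.arange(config.ph_min, config.ph_max + 1e-9, config.ph_step)

        if len(frames) == 1:
            stage = "energies"
            ledger = compute_ledger(frames[0], sites, dmap, settings)
            ledger.write(out)
            log(stage, intrinsic=[round(v, 3) for v in ledger.intrinsic_pka])

            stage = "titration"
            model = build_microstate_model(ledger, sites, ph_grid)
            use_mc = config.titration_method == "mc" or (
                config.titration_method == "auto" and model.n_sites > EXACT_SITE_LIMIT
            )
            result = (
                titrate_mc(model, scans=config.mc_scans, seed=config.seed)
                if use_mc
                else titrate_exact(model)
            )
            curves = pd.DataFrame(result.fractions, columns=model.site_ids)
            curves.insert(0, "pH", model.ph_grid)
            curves.to_csv(out / "titration_curves.tsv", sep="\t", index=False)
            summary = {
                "seed": config.seed,
                "method": result.method,
                "sites": [
                    {
                        "site_id": model.site_ids[i],
                        "model_pka": float(sites[i].model_pka),
                        "intrinsic_pka": round(float(ledger.intrinsic_pka[i]), 3),
                        "pka_half": _maybe_pka(result, i),
                        "mc_error": (
                            float(np.max(result.mc_error[:, i])) if result.mc_error is not None else 0.0
                        ),
                    }
                    for i in range(model.n_sites)
                ],
            }
        else:
            stage = "ensemble"
            fledger = per_frame_components(frames, grid, scene, policy, settings)
            fledger.component_series().to_csv(out / "frame_components.tsv", sep="\t", index=False)
            report = averaged_pka(fledger, ph_grid=ph_grid, mc_seed=config.seed)
            report.to_frame().to_csv(out / "ensemble_report.tsv", sep="\t", index=False)
            summary = {
                "seed": config.seed,
                "n_frames": fledger.n_frames,
                "median_sd": None if np.isnan(report.median_sd) else round(report.median_sd, 3),
                "sites": [
                    {
                        "site_id": sid,
                        "pka": _nan_none(report.averaged_pka[i]),
                        "uncertainty": _nan_none(report.pka_uncertainty[i]),
                        "sd_total_shift": _nan_none(report.sd_total_shift[i]),
                    }
                    for i, sid in enumerate(report.site_ids)
                ],
            }
        (out / "pka_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
        log("done")
        return summary
    except PipelineError:
        raise
    except Exception as exc:
        log("error", stage=stage, message=str(exc))
        raise PipelineError(stage, str(exc)) from exc


def _maybe_pka(result, i: int):
    from .titration import TitrationError

    try:
        return round(float(result.pka(i)), 3)
    except TitrationError:
        return None


def _nan_none(x: float):
    return None if x is None or np.isnan(x) else round(float(x), 3)
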