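"""Run configuration (strict YAML schema) and the orchestrated run() driver.

The config is deliberately small: a geometry block (builder + parameters or
mesh files), a dielectric block, an emitters block (the synthetic
phthalocyanine-like preset), a scan block and a numerics/output block.
Unknown keys are rejected everywhere.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from . import __version__
from .bem import BEMSolver, polarizability_spectrum
from .dielectric import DielectricModel, load_model, make_drude, make_silver_bb
from .fixtures import phthalocyanine_pair
from .meshing import build_sphere, build_tip_a, build_tip_b, combine, read_mesh
from .scans import distance_scan, fit_exponential, fit_forster, frequency_shift_scan

log = logging.getLogger("nanoret")

__all__ = ["RunConfig", "load_config", "run", "ConfigError"]


class ConfigError(ValueError):
    pass


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GeometryConfig(_Strict):
    builder: Optional[Literal["tip_a", "tip_b", "sphere"]] = "tip_a"
    params: dict = Field(default_factory=dict)
    mesh_files: Optional[list[str]] = None


class DielectricConfig(_Strict):
    name: Literal["silver_bb", "drude"] = "silver_bb"
    file: Optional[str] = None
    plasma_energy_eV: float = 9.0
    damping_eV: float = 0.45
    eps_inf: float = 1.0


class EmittersConfig(_Strict):
    preset: Literal["phthalocyanine_pair"] = "phthalocyanine_pair"
    plane_height_nm: float = 1.5
    dipole_donor_au: float = 2.4
    dipole_acceptor_au: float = 1.7
    omega_donor_eV: float = 2.11
    omega_acceptor_eV: list[float] = Field(default_factory=lambda: [2.02, 2.05])
    eta0_donor: float = 5e-4
    eta0_acceptor: float = 0.6
    representation: Literal["monopoles", "point-dipole"] = "monopoles"
    spread_nm: float = 0.4
    n_charges: int = 24


class ScanConfig(_Strict):
    distances_nm: list[float] = Field(
        default_factory=lambda: list(np.round(np.linspace(1.6, 3.2, 8), 3))
    )
    J_per_eV: float = 1.4
    donor_frequencies_eV: Optional[list[float]] = None  # shift-scan targets
    include_metal: bool = True


class NumericsConfig(_Strict):
    omega_min_eV: float = 2.0
    omega_max_eV: float = 4.0
    omega_step_eV: float = 0.01
    polarization: list[float] = Field(default_factory=lambda: [0.0, 0.0, 1.0])
    modal: bool = True
    seed: int = 7


class OutputConfig(_Strict):
    dir: str = "nanoret_out"


class RunConfig(_Strict):
    geometry: GeometryConfig = Field(default_factory=GeometryConfig)
    dielectric: DielectricConfig = Field(default_factory=DielectricConfig)
    emitters: EmittersConfig = Field(default_factory=EmittersConfig)
    scan: ScanConfig = Field(default_factory=ScanConfig)
    numerics: NumericsConfig = Field(default_factory=NumericsConfig)
    output: OutputConfig = Field(default_factory=OutputConfig)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text()) or {}
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        raise ConfigError(str(exc)) from exc


# ---------------------------------------------------------------------------
# assembly helpers


def build_geometry(cfg: GeometryConfig):
    if cfg.mesh_files:
        meshes = [read_mesh(p) for p in cfg.mesh_files]
        return combine(*meshes) if len(meshes) > 1 else meshes[0]
    if cfg.builder == "sphere":
        return build_sphere(**{"radius": 2.0, "refinement_level": 2, **cfg.params})
    builder = build_tip_a if cfg.builder == "tip_a" else build_tip_b
    tip, substrate = builder(**cfg.params)
    return combine(tip, substrate, label=cfg.builder)


def build_dielectric(cfg: DielectricConfig) -> DielectricModel:
    if cfg.file:
        return load_model(cfg.file)
    if cfg.name == "silver_bb":
        return make_silver_bb()
    return make_drude(cfg.plasma_energy_eV, cfg.damping_eV, cfg.eps_inf)


def build_emitters(cfg: EmittersConfig, separation: float, seed: int):
    return phthalocyanine_pair(
        separation=separation,
        plane_height=cfg.plane_height_nm,
        dipole_donor=cfg.dipole_donor_au,
        dipole_acceptor=cfg.dipole_acceptor_au,
        omega_donor=cfg.omega_donor_eV,
        omega_acceptor=tuple(cfg.omega_acceptor_eV),
        eta0_donor=cfg.eta0_donor,
        eta0_acceptor=cfg.eta0_acceptor,
        representation=cfg.representation,
        spread=cfg.spread_nm,
        n_charges=cfg.n_charges,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# tasks


def run(config: RunConfig, task: str = "scan") -> Path:
    """Execute a task ('spectrum' | 'scan' | 'shift-scan'); returns the run
    directory containing CSV/JSON outputs, a manifest and a log."""
    t_start = time.time()
    outdir = Path(config.output.dir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s %(message)s"))
    logging.getLogger().addHandler(fh)
    outputs = []
    try:
        mesh = build_geometry(config.geometry)
        model = build_dielectric(config.dielectric)
        log.info("mesh %s with %d tesserae; dielectric %s", mesh.label, mesh.n_tesserae, model.label)
        solver = BEMSolver(mesh)
        stages = {"setup_s": time.time() - t_start}

        if task == "spectrum":
            num = config.numerics
            omegas = np.arange(num.omega_min_eV, num.omega_max_eV + 0.5 * num.omega_step_eV,
                               num.omega_step_eV)
            _, alpha, peak = polarizability_spectrum(solver, model, omegas, num.polarization)
            import pandas as pd

            df = pd.DataFrame(
                {"omega_eV": omegas, "Re_alpha_au": alpha.real, "Im_alpha_au": alpha.imag}
            )
            df.to_csv(outdir / "spectrum.csv", index=False)
            (outdir / "peak.json").write_text(
                json.dumps({"peak_omega_eV": peak,
                            "peak_Im_alpha_au": float(alpha.imag.max())}, indent=2)
            )
            outputs += ["spectrum.csv", "peak.json"]
        elif task in ("scan", "shift-scan"):
            donors, acceptors = build_emitters(
                config.emitters, config.scan.distances_nm[0], config.numerics.seed
            )
            if task == "scan":
                results = [
                    distance_scan(
                        solver, model, donors, acceptors, config.scan.distances_nm,
                        J=config.scan.J_per_eV, include_metal=config.scan.include_metal,
                        modal=config.numerics.modal,
                    )
                ]
            else:
                freqs = config.scan.donor_frequencies_eV or [config.emitters.omega_donor_eV]
                results = frequency_shift_scan(
                    solver, model, donors, acceptors, config.scan.distances_nm,
                    freqs, J=config.scan.J_per_eV, modal=config.numerics.modal,
                )
            summary = []
            for res in results:
                tag = f"shift{res.response_shift:+.2f}eV" if res.response_shift else "unshifted"
                res.fit = fit_exponential(res.distances, res.ret_eff)
                res.rate_table().to_csv(outdir / f"scan_{tag}.csv", index=False)
                outputs.append(f"scan_{tag}.csv")
                summary.append(
                    {
                        "response_shift_eV": res.response_shift,
                        "distances_nm": res.distances.tolist(),
                        "ret_eff": res.ret_eff.tolist(),
                        "fit": {**res.fit.params, "r_squared": res.fit.r_squared},
                        "provenance": res.provenance,
                    }
                )
            (outdir / "scan_summary.json").write_text(json.dumps(summary, indent=2))
            outputs.append("scan_summary.json")
        else:
            raise ConfigError(f"unknown task: {task}")

        stages["total_s"] = time.time() - t_start
        manifest = {
            "nanoret_version": __version__,
            "task": task,
            "config": config.model_dump(),
            "config_hash": config.config_hash(),
            "outputs": outputs,
            "timings_s": {k: round(v, 3) for k, v in stages.items()},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    finally:
        logging.getLogger().removeHandler(fh)
        fh.close()
    return outdir
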