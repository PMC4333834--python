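"""Run configuration, pipeline orchestration and oracle fixtures.

A run is described by one YAML file with blocks mirroring the pipeline
stages (model, sampling, kinetics, dynamics, multi_pf).  ``run_pipeline``
executes the requested stages in order, writing TSV/JSON outputs, a
resolved-config snapshot with every default materialized, and a manifest
of file checksums; reruns from the snapshot with the same seed are
bit-reproducible.  The global seed expands into per-stage child seeds by a
fixed counter scheme.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import (
    DissociationConfig,
    LangevinConfig,
    horn_statistics,
    shrinkage_velocity,
    simulate_shrinkage,
)
from .landscape import (
    diffusion_coefficient,
    free_energy_from_distribution,
    kinetics_report,
)
from .model import Composition, ModelParams, cap_composition, params_from_energies
from .sampling import MCConfig, sample_landscape_distribution

__all__ = ["RunConfig", "load_config", "save_config", "run_pipeline", "make_fixture",
           "FIXTURES"]

# stage-name -> fixed child-seed offset, so serial and partial runs agree
_STAGE_OFFSET = {"sample": 1, "dynamics": 2, "multipf": 3}


@dataclass
class ModelBlock:
    b_nm: float = 8.0
    n_subunits: int = 32
    l0_nm: float = 6.5
    lmax_over_l0: float = 1.2
    E_ms_kBT: float = 8.0
    E_mb_kBT: float = 6.8
    theta_D_rad: float = 0.4
    theta_T_rad: float = 0.0
    cap_T_subunits: int = 0
    temperature_factor: float = 1.0

    def params(self) -> ModelParams:
        base = ModelParams(
            b=self.b_nm, N=self.n_subunits, l0=self.l0_nm,
            lmax=self.lmax_over_l0 * self.l0_nm,
            thetaD=self.theta_D_rad, thetaT=self.theta_T_rad,
            temperature_factor=self.temperature_factor,
        )
        return params_from_energies(self.E_ms_kBT, self.E_mb_kBT, base)

    def composition(self) -> Composition:
        m = self.cap_T_subunits
        return cap_composition(m, self.n_subunits - m)


@dataclass
class SamplingBlock:
    n_steps: int = 2_000_000
    window_spacing_nm: float = 10.0
    k_bias: float = 0.05
    bin_width_nm: float = 2.0
    record_every: int = 100


@dataclass
class KineticsBlock:
    a_nm: float = 40.0
    eta_Pa_s: float = 1e-3
    temperature_K: float = 298.0
    A_nm: float = 0.0
    B_nm: float = 125.0
    C_nm: float = 250.0
    minima_prominence_kBT: float = 1.0


@dataclass
class DynamicsBlock:
    dt_s: float = 1e-7
    t_total_s: float = 0.2
    n_trajectories: int = 8
    k_off_per_s: float = 75.0
    rx_gate_nm: float = 8.0
    l_d: float = 1.0
    forces_pN: list = field(default_factory=list)


@dataclass
class RunConfig:
    seed: int = 0
    stages: list = field(default_factory=lambda: ["sample", "landscape", "kinetics"])
    model: ModelBlock = field(default_factory=ModelBlock)
    sampling: SamplingBlock = field(default_factory=SamplingBlock)
    kinetics: KineticsBlock = field(default_factory=KineticsBlock)
    dynamics: DynamicsBlock = field(default_factory=DynamicsBlock)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = dict(d)
        for name, sub in (("model", ModelBlock), ("sampling", SamplingBlock),
                          ("kinetics", KineticsBlock), ("dynamics", DynamicsBlock)):
            if name in kw and isinstance(kw[name], dict):
                kw[name] = sub(**kw[name])
        return cls(**kw)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig, outdir) -> Path:
    """Execute the configured stages, writing one directory per run.

    Layout: resolved config at the root, one subdirectory per stage,
    manifest.json with checksums of every numeric output.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_config(cfg, outdir / "config.resolved.yaml")
    params = cfg.model.params()
    comp = cfg.model.composition()
    written: list[Path] = []
    landscape = None

    if "sample" in cfg.stages or "landscape" in cfg.stages:
        d = outdir / "sample"
        d.mkdir(exist_ok=True)
        mc = MCConfig(
            n_steps=cfg.sampling.n_steps, seed=cfg.seed + _STAGE_OFFSET["sample"],
            record_every=cfg.sampling.record_every,
            bin_width=cfg.sampling.bin_width_nm,
        )
        dist = sample_landscape_distribution(
            comp, params, mc, spacing=cfg.sampling.window_spacing_nm,
            k_bias=cfg.sampling.k_bias,
        )
        landscape = free_energy_from_distribution(dist)
        df = pd.DataFrame({
            "Rx_nm": dist.centers, "P": dist.p,
            "F_kBT": np.where(dist.p > 0, -np.log(np.where(dist.p > 0, dist.p, 1)), np.nan),
        })
        df.to_csv(d / "landscape.tsv", sep="\t", index=False)
        (d / "landscape.json").write_text(json.dumps({
            "seed": mc.seed, "n_steps_per_window": mc.n_steps,
            "n_samples": dist.n_samples,
            "deltaE_kBT": params.deltaE, "Ems_kBT": params.Ems, "Emb_kBT": params.Emb,
        }, indent=1))
        written += [d / "landscape.tsv", d / "landscape.json"]

    if "kinetics" in cfg.stages:
        if landscape is None:
            raise RuntimeError("kinetics stage requires the sample stage")
        d = outdir / "kinetics"
        d.mkdir(exist_ok=True)
        D = diffusion_coefficient(cfg.kinetics.a_nm, cfg.kinetics.eta_Pa_s,
                                  cfg.kinetics.temperature_K)
        rep = kinetics_report(
            landscape, D, cfg.kinetics.minima_prominence_kBT,
            A=cfg.kinetics.A_nm, B=cfg.kinetics.B_nm, C=cfg.kinetics.C_nm,
        )
        (d / "kinetics.json").write_text(json.dumps(rep, indent=1))
        written.append(d / "kinetics.json")

    if "dynamics" in cfg.stages:
        if landscape is None:
            raise RuntimeError("dynamics stage requires the sample stage")
        d = outdir / "dynamics"
        d.mkdir(exist_ok=True)
        D = diffusion_coefficient(cfg.kinetics.a_nm, cfg.kinetics.eta_Pa_s,
                                  cfg.kinetics.temperature_K)
        lcfg = LangevinConfig(dt=cfg.dynamics.dt_s, t_total=cfg.dynamics.t_total_s,
                              seed=cfg.seed + _STAGE_OFFSET["dynamics"], D=D)
        dcfg = DissociationConfig(k_off=cfg.dynamics.k_off_per_s,
                                  rx_gate=cfg.dynamics.rx_gate_nm)
        trajs = []
        for k in range(cfg.dynamics.n_trajectories):
            tr = simulate_shrinkage(
                landscape, dataclasses.replace(lcfg, seed=lcfg.seed + 10 * k),
                dcfg, l_d=cfg.dynamics.l_d, b=params.b, rc=params.rc,
            )
            trajs.append(tr)
        trajs[0].to_frame().to_csv(d / "trajectory0.tsv", sep="\t", index=False)
        v, sem = shrinkage_velocity(trajs)
        horns = horn_statistics(trajs[0])
        (d / "shrinkage.json").write_text(json.dumps({
            "v_minus_nm_s": v, "sem_nm_s": sem,
            "Tu_s": horns.Tu, "Nu_per_s": horns.Nu,
            "k_off_per_s": dcfg.k_off, "rx_gate_nm": dcfg.rx_gate,
            "l_d": cfg.dynamics.l_d, "seeds": [lcfg.seed + 10 * k for k in range(len(trajs))],
        }, indent=1))
        written += [d / "trajectory0.tsv", d / "shrinkage.json"]

    manifest = {p.relative_to(outdir).as_posix(): _checksum(p) for p in written}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir


# ---------------------------------------------------------------------------
# deterministic oracle fixtures

FIXTURES = (
    "flat-landscape", "double-well", "tiny-chain-N2", "tiny-chain-N3",
    "square-wave-traj",
)


def make_fixture(name: str, outdir) -> Path:
    """Write the named synthetic input used by the oracle tests.

    flat-landscape: F = 0 over 0-300 nm; double-well: F = 2 cos(2 pi
    Rx/125.66) kBT; tiny-chain-N2/N3: parameter YAML whose Boltzmann
    marginals are computable by quadrature; square-wave-traj: synthetic
    Rx(t) for excursion statistics.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if name == "flat-landscape":
        x = np.arange(0.0, 301.0, 2.0)
        path = outdir / "flat-landscape.tsv"
        pd.DataFrame({"Rx_nm": x, "F_kBT": np.zeros_like(x)}).to_csv(
            path, sep="\t", index=False)
    elif name == "double-well":
        x = np.arange(0.0, 301.0, 2.0)
        path = outdir / "double-well.tsv"
        pd.DataFrame({"Rx_nm": x, "F_kBT": 2.0 * np.cos(2 * np.pi * x / 125.66)}
                     ).to_csv(path, sep="\t", index=False)
    elif name in ("tiny-chain-N2", "tiny-chain-N3"):
        n = 2 if name.endswith("N2") else 3
        path = outdir / f"{name}.yaml"
        save_config(RunConfig(model=ModelBlock(n_subunits=n, E_ms_kBT=2.0,
                                               E_mb_kBT=1.0)), path)
    elif name == "square-wave-traj":
        t = np.arange(0.0, 10.0, 0.01)
        rx = np.where((t % 2.0) < 1.0, 50.0, 0.0)
        path = outdir / "square-wave-traj.tsv"
        pd.DataFrame({"t_s": t, "Rx_nm": rx, "Nd": 0, "Lobs_nm": 300.0 - rx}
                     ).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown fixture {name!r}; available: {', '.join(FIXTURES)}")
    return path
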