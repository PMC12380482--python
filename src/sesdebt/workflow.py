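"""Config-driven analysis runs: validation, dispatch, provenance, manifests.

A :class:`RunConfig` selects one analysis (equilibria table, branch diagram,
SOS map, ghost passage, perturbation experiment, or a plain trajectory),
the model variant and parameter overrides.  ``run`` validates the config
(unknown keys fail fast), executes the analysis, writes CSV/JSON/PNG
artifacts plus a resolved-config copy next to them, and returns a
checksummed manifest.  Outputs are deterministic given the config (and the
seed, where sampling is enabled).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Literal

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import bifurcation, equilibria, io, plotting, sos, transients
from .bifurcation import BifurcationDiagram
from .params import ModelParams
from .sos import SamplingSpec, SOSMap
from .transients import IntegrateOptions

__all__ = ["RunConfig", "run", "render_figures"]

logger = logging.getLogger("sesdebt")

Analysis = Literal[
    "equilibria", "branch_diagram", "sos_map", "ghost", "perturbation", "trajectory"
]


class _Opts(BaseModel):
    model_config = ConfigDict(extra="forbid")


class EquilibriaOptions(_Opts):
    pass


class BranchOptions(_Opts):
    c0_min: float = 0.0001
    c0_max: float = 0.044
    n_c0: int = 150


class SOSOptions(_Opts):
    c0_min: float | None = None
    c0_max: float | None = None
    n_c0: int | None = None
    h_min: float | None = None
    h_max: float | None = None
    n_h: int | None = None
    n_R: int = 21
    n_P: int = 21
    n_S: int = 0
    horizon: float = transients.DEFAULT_HORIZON
    latin_hypercube: bool = False
    n_samples: int = 441
    compare_with: str | None = None  # a second variant to map and compare against


class GhostOptions(_Opts):
    threshold: float = 0.10
    t_max: float = 1e8
    rtol: float = 1e-8
    atol: float = 1e-10
    dt_report: float = 1.0  # reporting grid of the exported trajectory


class PerturbationOptions(_Opts):
    state0: list[float] | None = None  # default: the stable interior equilibrium
    t_pert: float = 500.0
    phi: float = 0.6
    horizon: float = transients.DEFAULT_HORIZON


class TrajectoryOptions(_Opts):
    state0: list[float]
    t_max: float = transients.DEFAULT_HORIZON
    dt: float = 1.0
    rtol: float = 1e-8
    atol: float = 1e-10


_OPTION_MODELS: dict[str, type[_Opts]] = {
    "equilibria": EquilibriaOptions,
    "branch_diagram": BranchOptions,
    "sos_map": SOSOptions,
    "ghost": GhostOptions,
    "perturbation": PerturbationOptions,
    "trajectory": TrajectoryOptions,
}


class RunConfig(BaseModel):
    """One analysis run; unknown keys anywhere are rejected."""

    model_config = ConfigDict(extra="forbid")

    analysis: Analysis
    variant: str = "extended"
    params: dict[str, Any] = Field(default_factory=dict)
    options: dict[str, Any] = Field(default_factory=dict)
    outdir: str = "out"
    formats: list[Literal["csv", "json", "png"]] = Field(
        default_factory=lambda: ["csv", "json", "png"]
    )
    seed: int | None = None

    def resolved_params(self) -> ModelParams:
        return ModelParams.from_dict(self.params)

    def resolved_options(self) -> _Opts:
        return _OPTION_MODELS[self.analysis](**self.options)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _stage(name: str, t0: float, outputs: list[Path], params_hash: str) -> None:
    logger.info(
        "stage=%s params=%s duration=%.2fs outputs=%s",
        name,
        params_hash,
        time.perf_counter() - t0,
        [str(p) for p in outputs],
    )


def run(config: RunConfig) -> list[dict[str, str]]:
    """Execute the configured analysis and return the artifact manifest."""
    params = config.resolved_params()  # validate before any computation
    opts = config.resolved_options()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    resolved = {
        "analysis": config.analysis,
        "variant": config.variant,
        "params": params.to_dict(),
        "options": opts.model_dump(),
        "outdir": str(outdir),
        "formats": list(config.formats),
        "seed": config.seed,
    }
    resolved_yaml = yaml.safe_dump(resolved, sort_keys=False)
    params_hash = hashlib.sha256(resolved_yaml.encode()).hexdigest()[:12]
    cfg_path = outdir / "config.resolved.yaml"
    cfg_path.write_text(resolved_yaml)
    outputs: list[Path] = [cfg_path]

    t0 = time.perf_counter()
    dispatch = {
        "equilibria": _run_equilibria,
        "branch_diagram": _run_branches,
        "sos_map": _run_sos,
        "ghost": _run_ghost,
        "perturbation": _run_perturbation,
        "trajectory": _run_trajectory,
    }
    outputs += dispatch[config.analysis](config, params, opts, outdir)
    _stage(config.analysis, t0, outputs, params_hash)

    manifest_path = io.write_manifest(outputs, outdir / "manifest.json")
    return io.manifest(outputs) + io.manifest([manifest_path])


def _run_equilibria(config, params, opts, outdir) -> list[Path]:
    records = equilibria.interior_equilibria(params, config.variant)
    records += equilibria.boundary_equilibria(params, config.variant)
    return [io.write_equilibria(records, outdir / "equilibria.csv")]

def _run_branches(config, params, opts, outdir) -> list[Path]:
    grid = np.linspace(opts.c0_min, opts.c0_max, opts.n_c0)
    diagram = bifurcation.branch_diagram(params, grid)
    outputs = []
    if "csv" in config.formats:
        path = outdir / "branches.csv"
        diagram.to_frame().to_csv(path, index=False, float_format="%.17g")
        outputs.append(path)
    if "png" in config.formats:
        outputs.append(plotting.plot_branch_diagram(diagram, outdir / "branches.png"))
    return outputs


def _sos_grids(opts: SOSOptions, params: ModelParams):
    c0_grid = h_grid = None
    if opts.n_c0 is not None:
        c0_grid = np.linspace(opts.c0_min or 0.001, opts.c0_max or 0.044, opts.n_c0)
    if opts.n_h is not None:
        h_grid = np.linspace(opts.h_min or 0.0004, opts.h_max or 0.0132, opts.n_h)
    return c0_grid, h_grid


def _run_sos(config, params, opts, outdir) -> list[Path]:
    sampling = SamplingSpec(
        n_R=opts.n_R,
        n_P=opts.n_P,
        n_S=opts.n_S,
        horizon=opts.horizon,
        latin_hypercube=opts.latin_hypercube,
        n_samples=opts.n_samples,
        seed=config.seed,
    )
    c0_grid, h_grid = _sos_grids(opts, params)
    outputs: list[Path] = []
    maps: dict[str, SOSMap] = {}
    variants = [config.variant] + ([opts.compare_with] if opts.compare_with else [])
    for variant in variants:
        m = sos.sos_map(variant, params, c0_grid, h_grid, sampling)
        maps[variant] = m
        if "csv" in config.formats:
            path = outdir / f"sos_{variant}.csv"
            m.to_frame().to_csv(path, index=False, float_format="%.17g")
            outputs.append(path)
        if "png" in config.formats:
            outputs.append(plotting.plot_sos_map(m, outdir / f"sos_{variant}.png"))
    if opts.compare_with:
        cmp = sos.compare_sos(maps[opts.compare_with], maps[config.variant])
        path = outdir / "sos_comparison.json"
        path.write_text(
            json.dumps(
                {
                    "reference": opts.compare_with,
                    "variant": config.variant,
                    "fraction_lost": cmp.fraction_lost,
                    "fraction_basin_shrunk": cmp.fraction_basin_shrunk,
                },
                indent=2,
            )
        )
        outputs.append(path)
    return outputs


def _run_ghost(config, params, opts, outdir) -> list[Path]:
    transit = transients.ghost_transit_time(
        params, threshold=opts.threshold, t_max=opts.t_max, rtol=opts.rtol, atol=opts.atol
    )
    ghost = bifurcation.ghost_state(params)
    traj = transients.integrate(
        "extended",
        ghost,
        params,
        (0.0, opts.t_max),
        IntegrateOptions(rtol=opts.rtol, atol=opts.atol, max_step=None, dt=None),
    )
    # Resample onto a uniform grid for the speed profile and export.
    dt = max(opts.dt_report, traj.t_end / 20_000.0)
    uniform = transients.integrate(
        "extended",
        ghost,
        params,
        (0.0, max(traj.t_end, 2 * dt)),
        IntegrateOptions(rtol=opts.rtol, atol=opts.atol, max_step=None, dt=dt),
    )
    transients.speed_profile(uniform)
    transients.classify_outcome(uniform, params)
    outputs: list[Path] = []
    summary = outdir / "ghost.json"
    summary.write_text(
        json.dumps(
            {
                "transit_time_years": transit,
                "threshold": opts.threshold,
                "ghost_state": [float(x) for x in ghost],
                "outcome": uniform.outcome,
            },
            indent=2,
        )
    )
    outputs.append(summary)
    if "csv" in config.formats:
        outputs.append(io.write_trajectory(uniform, outdir / "ghost_trajectory.csv"))
    if "png" in config.formats:
        outputs.append(plotting.plot_ghost_passage(uniform, ghost, outdir / "ghost.png"))
    return outputs


def _run_perturbation(config, params, opts, outdir) -> list[Path]:
    state0 = opts.state0
    if state0 is None:
        stable = [
            r for r in equilibria.interior_equilibria(params) if r.stability == "stable"
        ]
        if not stable:
            raise ValueError("no stable interior equilibrium; give state0 explicitly")
        state0 = list(stable[0].state)
    record = transients.perturbation_experiment(
        params, state0, opts.t_pert, opts.phi, opts.horizon
    )
    outputs: list[Path] = []
    summary = outdir / "perturbation.json"
    summary.write_text(
        json.dumps(
            {
                "t_pert": record.t_pert,
                "phi": record.phi,
                "outcome": record.outcome,
                "counterfactual_outcome": record.counterfactual_outcome,
                "quasistatic_outcome": record.quasistatic_outcome,
                "initial_recovery": record.initial_recovery,
                "collapse_onset": record.collapse_onset,
            },
            indent=2,
        )
    )
    outputs.append(summary)
    if "csv" in config.formats:
        for name, traj in (
            ("perturbation_pre", record.pre),
            ("perturbation_post", record.post),
            ("perturbation_counterfactual", record.counterfactual_post),
            ("perturbation_quasistatic", record.quasistatic_post),
        ):
            outputs.append(io.write_trajectory(traj, outdir / f"{name}.csv"))
    if "png" in config.formats:
        outputs.append(plotting.plot_perturbation(record, outdir / "perturbation.png"))
    return outputs


def _run_trajectory(config, params, opts, outdir) -> list[Path]:
    traj = transients.integrate(
        config.variant,
        np.asarray(opts.state0, dtype=float),
        params,
        (0.0, opts.t_max),
        IntegrateOptions(rtol=opts.rtol, atol=opts.atol, dt=opts.dt),
    )
    transients.classify_outcome(traj, params)
    return [io.write_trajectory(traj, outdir / "trajectory.csv")]


def render_figures(outdir: str | Path) -> list[Path]:
    """Regenerate the figures for an existing run directory from its CSVs.

    Raises ``FileNotFoundError`` listing what to run first if the directory
    holds no renderable artifacts.
    """
    import pandas as pd

    outdir = Path(outdir)
    cfg_path = outdir / "config.resolved.yaml"
    if not cfg_path.exists():
        raise FileNotFoundError(
            f"{outdir} has no config.resolved.yaml; run an analysis (e.g. "
            "'sesdebt branches' or 'sesdebt sos') first"
        )
    resolved = yaml.safe_load(cfg_path.read_text())
    params = ModelParams.from_dict(resolved["params"])
    produced: list[Path] = []

    branches_csv = outdir / "branches.csv"
    if branches_csv.exists():
        df = pd.read_csv(branches_csv)
        diagram = _diagram_from_frame(df, params)
        produced.append(plotting.plot_branch_diagram(diagram, outdir / "branches.png"))
    for csv in sorted(outdir.glob("sos_*.csv")):
        variant = csv.stem.removeprefix("sos_")
        produced.append(
            plotting.plot_sos_map(_sos_from_frame(pd.read_csv(csv), variant, params),
                                  outdir / f"sos_{variant}.png")
        )
    ghost_csv = outdir / "ghost_trajectory.csv"
    if ghost_csv.exists():
        traj = io.read_trajectory(ghost_csv, params, "extended")
        produced.append(
            plotting.plot_ghost_passage(traj, bifurcation.ghost_state(params), outdir / "ghost.png")
        )
    if not produced:
        raise FileNotFoundError(
            f"no renderable CSV artifacts in {outdir}; run 'sesdebt branches', "
            "'sesdebt sos' or 'sesdebt ghost' first"
        )
    return produced


def _diagram_from_frame(df, params: ModelParams) -> BifurcationDiagram:
    c0 = np.array(sorted(df["c0"].unique()))
    branches: dict[str, dict[str, dict[str, np.ndarray]]] = {}
    for (variant, branch), grp in df.groupby(["variant", "branch"]):
        grp = grp.sort_values("c0")
        entry = branches.setdefault(variant, {})
        entry[branch] = {
            "R": grp["R"].to_numpy(),
            "P": grp["P"].to_numpy(),
            "S": grp["S"].to_numpy(),
            "stability": grp["stability"].to_numpy(dtype=object),
        }
    fold = None
    if params.h > 0:
        c0f = bifurcation.fold_locus(params, "c0_of_h")(params.h)
        if c0[0] <= c0f <= c0[-1]:
            fold = (c0f, bifurcation.fold_point(params))
    return BifurcationDiagram(params=params, c0=c0, branches=branches, fold=fold, exit=None)


def _sos_from_frame(df, variant: str, params: ModelParams) -> SOSMap:
    c0 = np.array(sorted(df["c0"].unique()))
    h = np.array(sorted(df["h"].unique()))
    labels = np.empty((c0.size, h.size), dtype=object)
    frac = np.zeros_like(labels, dtype=float)
    und = np.zeros_like(frac)
    idx_c0 = {v: i for i, v in enumerate(c0)}
    idx_h = {v: j for j, v in enumerate(h)}
    for row in df.itertuples():
        i, j = idx_c0[row.c0], idx_h[row.h]
        labels[i, j] = row.label
        frac[i, j] = row.basin_fraction
        und[i, j] = row.undecided_fraction
    return SOSMap(
        variant=variant,
        c0=c0,
        h=h,
        labels=labels,
        basin_fraction=frac,
        undecided_fraction=und,
        params=params,
        sampling=SamplingSpec(),
    )
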