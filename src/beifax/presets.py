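"""Named parameter presets and the experiment runner.

Every parameter table ships as a human-readable YAML preset.  Point-membrane
presets (``wb-point``, ``seif-point``, ``beif-point``) resolve to a membrane
model; experiment presets (``myelinated-default``, ``myelinated-wb``,
``unmyelinated-default``, ``an-low``, ``an-high``, ``extracellular-default``)
resolve to a fully-specified model + geometry + protocol bundle.

:func:`run_experiment` executes a resolved configuration and writes the trace,
spike events, an analysis table, the fully materialized config, and a log next
to each other, so any result directory is self-describing and reproducible.
The whole system is deterministic: re-running a config yields identical
tables.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .axon import MyelinatedGeometry, UnmyelinatedGeometry, build_myelinated, build_unmyelinated
from .integrate import SolverConfig, simulate_chain
from .membrane import (
    BEIFModel,
    BEIFParams,
    PassiveParams,
    SEIFModel,
    SEIFParams,
    WBModel,
    WBParams,
)
from .stimulation import ExtracellularSource, IntracellularStep
from .analysis import NoSpikeError, conduction_velocity

__all__ = [
    "available_presets",
    "preset_dict",
    "resolve_preset",
    "ExperimentConfig",
    "ResolvedExperiment",
    "run_experiment",
    "model_from_dict",
]

_POINT_PRESETS = ("wb-point", "seif-point", "beif-point")
_EXPERIMENT_PRESETS = (
    "myelinated-default",
    "myelinated-wb",
    "unmyelinated-default",
    "an-low",
    "an-high",
    "extracellular-default",
)


def available_presets() -> tuple[str, ...]:
    return _POINT_PRESETS + _EXPERIMENT_PRESETS


def preset_dict(name: str) -> dict:
    """Raw parameter dictionary of a named preset (parsed YAML)."""
    if name not in available_presets():
        raise KeyError(
            f"unknown preset {name!r}; valid names: {', '.join(available_presets())}"
        )
    text = resources.files("beifax").joinpath("preset_data", f"{name}.yaml").read_text()
    return yaml.safe_load(text)


def model_from_dict(d: dict):
    """Build a membrane model from a preset-style parameter dict."""
    kind = d.get("model")
    passive = PassiveParams(Cm=float(d["Cm"]), GL=float(d["GL"]), EL=float(d["EL"]))
    if kind == "wb":
        return WBModel(WBParams(
            passive=passive,
            GK=float(d["GK"]), GNa=float(d["GNa"]),
            EK=float(d["EK"]), ENa=float(d["ENa"]),
        ))
    if kind == "seif":
        return SEIFModel(SEIFParams(
            passive=passive,
            VT=float(d["VT"]), KT=float(d["KT"]),
            Vspike=float(d["Vspike"]), Vreset=float(d["Vreset"]),
            tau_ref=float(d["tau_ref"]),
        ))
    if kind == "beif":
        return BEIFModel(BEIFParams(
            passive=passive,
            VT=float(d["VT"]), KT=float(d["KT"]), AT=float(d["AT"]),
            Vrep=float(d["Vrep"]), tau_rep=float(d["tau_rep"]),
            Arep=float(d["Arep"]),
            mode=d.get("mode", "alpha-repolarization"),
        ))
    raise ValueError(f"unknown membrane model kind {kind!r}")


def _geometry_from_dict(d: dict):
    if d["kind"] == "myelinated":
        return MyelinatedGeometry(
            D=float(d["D_um"]), Ln=float(d["Ln_um"]),
            Li=float(d["Li_um"]), n_nodes=int(d["n_nodes"]),
        )
    if d["kind"] == "unmyelinated":
        return UnmyelinatedGeometry(
            D=float(d["D_um"]), dx=float(d["dx_um"]), n_comp=int(d["n_comp"]),
        )
    raise ValueError(f"unknown geometry kind {d['kind']!r}")


@dataclass
class ResolvedExperiment:
    """A fully materialized experiment: model + chain + protocol + solver."""

    name: str
    raw: dict
    model: object
    geometry: object
    chain: object
    stimulus: IntracellularStep | None
    extracellular: ExtracellularSource | None
    solver: SolverConfig
    velocity_nodes: tuple[int, int] | None


def resolve_preset(name: str, overrides: dict | None = None):
    """Resolve a preset name into ready-to-use objects.

    Point presets return a membrane model; experiment presets return a
    :class:`ResolvedExperiment`.  ``overrides`` is a (possibly nested) dict
    merged over the preset values before construction.
    """
    d = preset_dict(name)
    if overrides:
        d = _merge(d, overrides)
    if name in _POINT_PRESETS or "membrane" not in d:
        return model_from_dict(d)

    model = model_from_dict(d["membrane"])
    geometry = _geometry_from_dict(d["geometry"])
    rax = float(d.get("Rax_ohm_cm", 100.0))
    if isinstance(geometry, MyelinatedGeometry):
        chain = build_myelinated(geometry, model, Rax=rax)
    else:
        chain = build_unmyelinated(geometry, model, Rax=rax)

    stimulus = None
    if "stimulus" in d:
        s = d["stimulus"]
        stimulus = IntracellularStep(
            site=int(s["site"]),
            amplitude_nA=float(s["amplitude_pA"]) * 1e-3,
            onset=float(s.get("onset_ms", 0.0)),
            duration=float(s["duration_ms"]),
        )
    extracellular = None
    if "extracellular" in d:
        e = d["extracellular"]
        extracellular = ExtracellularSource(
            I_mA=float(e["I_ex_mA"]),
            onset=float(e.get("onset_ms", 0.0)),
            duration=float(e["pulse_ms"]),
            rho_ex=float(e.get("rho_ex_ohm_m", 3.0)),
            electrode_node=int(e.get("electrode_node", 20)),
            electrode_distance_mm=float(e.get("electrode_distance_mm", 1.0)),
        )
    sv = d.get("solver", {})
    solver = SolverConfig(
        dt=float(sv.get("dt_us", 4.0)) * 1e-3,
        scheme=sv.get("scheme", "euler-cn"),
        duration=float(sv.get("duration_ms", 10.0)),
        record_stride=int(sv.get("record_stride", 1)),
    )
    vn = d.get("velocity_nodes")
    return ResolvedExperiment(
        name=name,
        raw=d,
        model=model,
        geometry=geometry,
        chain=chain,
        stimulus=stimulus,
        extracellular=extracellular,
        solver=solver,
        velocity_nodes=tuple(int(v) for v in vn) if vn else None,
    )


def _merge(base: dict, overrides: dict) -> dict:
    out = dict(base)
    for k, v in overrides.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


@dataclass
class ExperimentConfig:
    """Declarative experiment request: a preset plus optional overrides."""

    preset: str
    outdir: str | Path = "results"
    overrides: dict = field(default_factory=dict)
    record_stride: int = 10  # trace file stride (events stay at full dt)
    save_trace: bool = True

    def __post_init__(self) -> None:
        if self.preset not in available_presets():
            raise ValueError(
                f"preset: unknown name {self.preset!r}; valid: "
                f"{', '.join(available_presets())}"
            )
        if self.preset in _POINT_PRESETS:
            raise ValueError(
                f"preset: {self.preset!r} is a point-membrane preset; "
                "run_experiment needs an axon experiment preset"
            )
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")


def run_experiment(config: ExperimentConfig) -> dict:
    """Run an experiment and write its results bundle to ``config.outdir``.

    Writes ``trace.tsv`` (time + per-compartment voltages, strided),
    ``events.tsv`` (compartment index, spike time), ``analysis.tsv``
    (velocity estimate when the preset defines measurement nodes),
    ``resolved-config.yaml`` and ``run-log.json``.  Returns a summary dict.
    """
    exp = resolve_preset(config.preset, config.overrides)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    t0 = time.perf_counter()
    trace = simulate_chain(
        exp.chain, exp.stimulus, exp.solver, extracellular=exp.extracellular
    )
    wall = time.perf_counter() - t0

    summary: dict = {
        "preset": config.preset,
        "n_compartments": exp.chain.n,
        "n_steps": int(round(exp.solver.duration / exp.solver.dt)),
        "n_spiking_compartments": int(sum(len(e) > 0 for e in trace.events)),
    }
    if exp.velocity_nodes is not None:
        a, b = exp.velocity_nodes
        try:
            est = conduction_velocity(trace, a, b, exp.chain)
            summary["velocity_m_per_s"] = est.velocity
            summary["t_peak_a_ms"] = est.t_peak_a
            summary["t_peak_b_ms"] = est.t_peak_b
        except NoSpikeError:
            summary["velocity_m_per_s"] = None

    if config.save_trace:
        trace.to_delimited(outdir / "trace.tsv", stride=config.record_stride)
    ev = trace.events_table()
    np.savetxt(
        outdir / "events.tsv", ev, delimiter="\t",
        header="compartment\ttime_ms", comments="", fmt=["%d", "%.6f"],
    )
    if "velocity_m_per_s" in summary and summary["velocity_m_per_s"] is not None:
        with open(outdir / "analysis.tsv", "w") as f:
            f.write("node_a\tnode_b\tt_peak_a_ms\tt_peak_b_ms\tvelocity_m_per_s\n")
            f.write(
                f"{a}\t{b}\t{summary['t_peak_a_ms']:.6f}\t"
                f"{summary['t_peak_b_ms']:.6f}\t{summary['velocity_m_per_s']:.6f}\n"
            )
    resolved = yaml.safe_dump(exp.raw, sort_keys=False)
    (outdir / "resolved-config.yaml").write_text(resolved)
    log = {
        "package_version": __version__,
        "preset_sha256": hashlib.sha256(resolved.encode()).hexdigest(),
        "dt_ms": exp.solver.dt,
        "scheme": exp.solver.scheme,
        "duration_ms": exp.solver.duration,
        "total_steps": summary["n_steps"],
        "wall_time_s": wall,
    }
    (outdir / "run-log.json").write_text(json.dumps(log, indent=2))
    summary["outdir"] = str(outdir)
    return summary
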