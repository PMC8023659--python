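"""End-to-end orchestration: simulate → mbar → landscape → correct → report.

A pipeline run is described by a YAML/dict config with a global seed, a
thermal energy kT, an output directory and an ordered stage list.  Each
stage writes its artifacts into the output directory together with
provenance (config hash, seed, package version), so a rerun with the same
config reproduces the same outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correction import (
    apply_offset_to_weights,
    corrected_solution_dg,
    fit_offset,
    records_from_table,
    records_to_table,
)
from .mbar import compute_weights, free_energy_difference, solve_mbar
from .pca_landscape import Axis, build_fes
from .structure_mining import distance_only_c2
from .synthetic_data import (
    SurrogateSpec,
    default_state_chain,
    generate_deltaG_dataset,
    sample_surrogate_ensemble,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "demo_config"]

logger = logging.getLogger(__name__)

KNOWN_STAGES = ("simulate", "mbar", "landscape", "correct", "report")


class PipelineError(ValueError):
    """Configuration or stage-execution failure."""


@dataclass
class PipelineConfig:
    stages: list[dict]
    seed: int = 0
    kT: float = 0.59616
    output_dir: str | Path = "chelafix_out"
    extra: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        if not isinstance(raw, dict) or "stages" not in raw:
            raise PipelineError("config must be a mapping with a 'stages' list")
        stages = []
        for s in raw["stages"]:
            if isinstance(s, str):
                s = {"name": s}
            if "name" not in s:
                raise PipelineError("every stage needs a 'name'")
            if s["name"] not in KNOWN_STAGES:
                raise PipelineError(f"unknown stage name {s['name']!r}")
            stages.append({"name": s["name"],
                           "params": dict(s.get("params", {}))})
        return cls(
            stages=stages,
            seed=int(raw.get("seed", 0)),
            kT=float(raw.get("kT", 0.59616)),
            output_dir=raw.get("output_dir", "chelafix_out"),
            extra={k: v for k, v in raw.items()
                   if k not in ("stages", "seed", "kT", "output_dir")},
        )

    def canonical(self) -> str:
        return json.dumps({
            "stages": self.stages, "seed": self.seed, "kT": self.kT,
            "output_dir": str(self.output_dir), "extra": self.extra,
        }, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def demo_config(output_dir: str | Path = "chelafix_out",
                seed: int = 1) -> PipelineConfig:
    """Small synthetic end-to-end run completing in a couple of minutes."""
    return PipelineConfig(
        stages=[
            {"name": "simulate", "params": {"n_per_state": 400, "n_lambda": 11}},
            {"name": "mbar", "params": {}},
            {"name": "landscape", "params": {"n_bins": 60}},
            {"name": "correct", "params": {"n": 30, "true_bias": 6.1}},
            {"name": "report", "params": {}},
        ],
        seed=seed,
        output_dir=output_dir,
    )


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_simulate(ctx: dict, params: dict, cfg: PipelineConfig) -> dict:
    spec = SurrogateSpec(**params.get("spec", {}))
    states = default_state_chain(spec, n_lambda=int(params.get("n_lambda", 21)))
    archive = sample_surrogate_ensemble(
        spec, states,
        n_per_state=int(params.get("n_per_state", 1000)),
        seed=cfg.seed,
        thin=int(params.get("thin", 10)),
    )
    out = Path(cfg.output_dir) / "archive.npz"
    archive.save(out)
    ctx["archive"] = archive
    return {"archive": str(out), "n_states": archive.n_states,
            "n_per_state": archive.n_per_state}


def _stage_mbar(ctx: dict, params: dict, cfg: PipelineConfig) -> dict:
    if "archive" not in ctx:
        raise PipelineError("mbar stage requires a prior simulate stage")
    archive = ctx["archive"]
    mat = archive.matrix()
    result = solve_mbar(mat, tol=float(params.get("tol", 1e-8)))
    native = next(s.name for s in archive.states
                  if s.lam == 0.0 and s.restraint is None)
    weights = compute_weights(mat, result, native)
    dg = free_energy_difference(
        result, "C3@0.0000", "C2@0.0000", kT=cfg.kT) \
        if "C3@0.0000" in mat.state_names else None
    ctx.update(mbar_result=result, weights=weights, matrix=mat)
    payload = {
        "converged": bool(result.converged),
        "residual": float(result.residual),
        "f_k": {n: float(f) for n, f in zip(mat.state_names, result.f_k)},
        "dg_c3_to_c2_kcal_mol": dg,
    }
    (Path(cfg.output_dir) / "free_energies.json").write_text(
        json.dumps(payload, indent=1))
    return payload


def _stage_landscape(ctx: dict, params: dict, cfg: PipelineConfig) -> dict:
    if "weights" not in ctx:
        raise PipelineError("landscape stage requires a prior mbar stage")
    archive, weights = ctx["archive"], ctx["weights"]
    x = archive.samples_flat
    n_bins = int(params.get("n_bins", 100))
    fes = build_fes(x[:, :2], weights.w_n, kT=cfg.kT, n_bins=n_bins)
    ctx["fes"] = fes
    df = _fes_table(fes)
    out = Path(cfg.output_dir) / "fes_r_theta.csv"
    df.to_csv(out, index=False)
    return {"fes": str(out),
            "n_inaccessible": int(fes.inaccessible_mask.sum())}


def _stage_correct(ctx: dict, params: dict, cfg: PipelineConfig) -> dict:
    table_path = params.get("dg_table")
    if table_path:
        records = records_from_table(pd.read_csv(table_path))
    else:
        records, _truth = generate_deltaG_dataset(
            n=int(params.get("n", 30)),
            true_bias=float(params.get("true_bias", 6.1)),
            noise_sd=float(params.get("noise_sd", 1.0)),
            seed=cfg.seed + 1,
        )
    fit = fit_offset(records)
    payload = {
        "mean_offset": fit.mean_offset,
        "chosen_interval": list(fit.chosen_interval),
        "n_correct": fit.n_correct,
        "n_total": fit.n_total,
    }
    outdir = Path(cfg.output_dir)
    records_to_table(records).to_csv(outdir / "dg_table.csv", index=False)
    (outdir / "offset.json").write_text(json.dumps(payload, indent=1))
    ctx["offset_fit"] = fit
    if "weights" in ctx and "archive" in ctx:
        archive = ctx["archive"]
        mask = distance_only_c2(archive.samples_flat[:, 0])
        ctx["corrected_weights"] = apply_offset_to_weights(
            ctx["weights"], mask, fit.mean_offset, cfg.kT)
        uncorrected = None
        if ctx.get("mbar_result") is not None and \
                "C3@0.0000" in ctx["matrix"].state_names:
            uncorrected = free_energy_difference(
                ctx["mbar_result"], "C3@0.0000", "C2@0.0000", kT=cfg.kT)
            payload["corrected_dg_c3_to_c2"] = corrected_solution_dg(
                uncorrected, fit.mean_offset)
            (outdir / "offset.json").write_text(json.dumps(payload, indent=1))
    return payload


def _stage_report(ctx: dict, params: dict, cfg: PipelineConfig) -> dict:
    summary = {k: v for k, v in ctx.get("stage_outputs", {}).items()}
    lines = ["chelafix pipeline report", "=" * 24]
    for stage, out in summary.items():
        lines.append(f"[{stage}]")
        for k, v in out.items():
            if isinstance(v, dict):
                continue
            lines.append(f"  {k}: {v}")
    text = "\n".join(lines) + "\n"
    (Path(cfg.output_dir) / "report.txt").write_text(text)
    return {"report": str(Path(cfg.output_dir) / "report.txt")}


_STAGE_FUNCS: dict[str, Callable[[dict, dict, PipelineConfig], dict]] = {
    "simulate": _stage_simulate,
    "mbar": _stage_mbar,
    "landscape": _stage_landscape,
    "correct": _stage_correct,
    "report": _stage_report,
}


def _fes_table(fes) -> pd.DataFrame:
    if fes.free_energy.ndim == 1:
        return pd.DataFrame({
            fes.axes[0].name: fes.axes[0].centers,
            "free_energy": fes.free_energy,
            "weight": fes.bin_weight,
            "inaccessible": fes.inaccessible_mask,
        })
    c0, c1 = np.meshgrid(fes.axes[0].centers, fes.axes[1].centers,
                         indexing="ij")
    return pd.DataFrame({
        fes.axes[0].name: c0.ravel(),
        fes.axes[1].name: c1.ravel(),
        "free_energy": fes.free_energy.ravel(),
        "weight": fes.bin_weight.ravel(),
        "inaccessible": fes.inaccessible_mask.ravel(),
    })


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in order; returns the report dict.

    Configuration errors are raised before any stage runs; a stage failure
    leaves earlier artifacts in place and re-raises.
    """
    for s in config.stages:
        if s["name"] not in _STAGE_FUNCS:
            raise PipelineError(f"unknown stage name {s['name']!r}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "pipeline.log")
    log_handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(name)s: %(message)s"))
    logging.getLogger("chelafix").addHandler(log_handler)
    ctx: dict = {"stage_outputs": {}}
    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "kT": config.kT,
        "version": __version__,
        "stages": {},
    }
    t0 = time.time()
    try:
        for s in config.stages:
            name = s["name"]
            logger.info("running stage %s", name)
            out = _STAGE_FUNCS[name](ctx, s["params"], config)
            ctx["stage_outputs"][name] = out
            report["stages"][name] = out
    finally:
        logging.getLogger("chelafix").removeHandler(log_handler)
        log_handler.close()
    report["elapsed_s"] = round(time.time() - t0, 2)
    (outdir / "pipeline_report.json").write_text(json.dumps(report, indent=1))
    return report
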