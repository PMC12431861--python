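"""End-to-end pipeline orchestration from a YAML-serializable config.

Stages run in dependency order (simulate -> balance -> loopscore /
insulation / compartments); each stage records its parameters and the
SHA-256 checksums of its inputs and outputs in a JSON manifest, so a
re-run from the same config and seed is checksum-identical. All
randomness flows from the single global seed.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import balance as balance_mod
from . import compartments as comp_mod
from . import formats_io as io_mod
from . import insulation as ins_mod
from . import loopscore as ls_mod
from . import synthgen

__all__ = ["PipelineError", "load_config", "run_pipeline"]

STAGE_ORDER = ["simulate", "balance", "loopscore", "insulation", "compartments"]


class PipelineError(RuntimeError):
    """A stage could not run; the message names the stage and artifact."""


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineError("config must be a YAML mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _require(stage: str, artifact: str, path: Path | None) -> Path:
    if path is None or not Path(path).exists():
        raise PipelineError(
            f"{stage}: missing required artifact '{artifact}'"
            + (f" ({path})" if path else "")
        )
    return Path(path)


def _sim_params(spec: dict, seed: int) -> synthgen.SimParams:
    loops = [synthgen.LoopSpec(*row) for row in spec.get("loops", [])]
    boundaries = [synthgen.BoundarySpec(*row) for row in spec.get("boundaries", [])]
    labels = spec.get("compartment_labels")
    return synthgen.SimParams(
        n_bins=int(spec.get("n_bins", 300)),
        resolution=int(spec.get("resolution", 10_000)),
        chrom=str(spec.get("chrom", "chrS")),
        decay_exponent=float(spec.get("decay_exponent", 1.0)),
        base_level=float(spec.get("base_level", 1.0)),
        loops=loops,
        boundaries=boundaries,
        compartment_labels=None if labels is None else np.asarray(labels),
        compartment_affinity=float(spec.get("compartment_affinity", 1.0)),
        depth=float(spec.get("depth", 1e6)),
        seed=int(spec.get("seed", seed)),
    )


def run_pipeline(config: dict, outdir: str | Path | None = None) -> dict:
    """Execute the enabled stages and return (and write) the run manifest."""
    outdir = Path(outdir or config.get("outdir", "loopscape_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages_cfg = config.get("stages", {})
    manifest: dict[str, Any] = {
        "schema_version": 1,
        "seed": seed,
        "stages": [],
    }
    manifest_path = outdir / "manifest.json"

    artifacts: dict[str, Path] = {}

    def record(name: str, params: dict, inputs: dict[str, Path],
               outputs: dict[str, Path], counts: dict) -> None:
        manifest["stages"].append(
            {
                "name": name,
                "params": params,
                "inputs": {k: _sha256(p) for k, p in inputs.items()},
                "outputs": {str(p.name): _sha256(p) for p in outputs.values()},
                "counts": counts,
            }
        )

    def fail(exc: Exception) -> None:
        manifest["error"] = str(exc)
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    try:
        for name in STAGE_ORDER:
            spec = stages_cfg.get(name, {})
            if not spec or not spec.get("enabled", False):
                continue
            if name == "simulate":
                params = _sim_params(spec.get("params", {}), seed)
                matrix, truth = synthgen.simulate_contact_map(params)
                mat_path = outdir / "matrix.triplet.tsv"
                bins_path = outdir / "matrix.bins.bed"
                io_mod.write_contact_matrix(matrix, mat_path, bins_path)
                loops_path = outdir / "truth_loops.bedpe"
                io_mod.write_bedpe(truth.loops, loops_path)
                bounds_path = outdir / "truth_boundaries.bed"
                with open(bounds_path, "w") as fh:
                    for iv in truth.boundaries:
                        fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
                outputs = {
                    "matrix": mat_path, "bins": bins_path,
                    "loops": loops_path, "boundaries": bounds_path,
                }
                if truth.compartment_labels is not None:
                    phasing = synthgen.simulate_phasing_track(params)
                    ph_path = outdir / "phasing.bedgraph"
                    io_mod.write_bedgraph(phasing, ph_path)
                    outputs["phasing"] = ph_path
                artifacts.update(outputs)
                record(name, spec.get("params", {}), {}, outputs,
                       {"n_bins": params.n_bins, "n_loops": len(truth.loops)})
            elif name == "balance":
                mat_src = spec.get("matrix", artifacts.get("matrix"))
                mat_path = _require(
                    name, "matrix", Path(mat_src) if mat_src else None
                )
                bins = spec.get("bins", artifacts.get("bins"))
                matrix = io_mod.read_contact_matrix(
                    mat_path,
                    bins_path=bins,
                    n_bins=spec.get("n_bins"),
                )
                bal = balance_mod.ipf_balance(
                    matrix,
                    tol=float(spec.get("tol", 1e-5)),
                    max_iter=int(spec.get("max_iter", 200)),
                )
                out_path = outdir / "matrix.norm.triplet.tsv"
                io_mod.write_contact_matrix(bal.base, out_path)
                w_path = outdir / "weights.tsv"
                with open(w_path, "w") as fh:
                    for b, w in enumerate(bal.weights):
                        fh.write(f"{b}\t{w:.10g}\n")
                artifacts["norm_matrix"] = out_path
                artifacts["_balanced"] = bal  # in-memory handoff
                record(name, {"tol": spec.get("tol", 1e-5)},
                       {"matrix": mat_path}, {"norm": out_path, "weights": w_path},
                       {"n_iterations": bal.n_iterations,
                        "converged": bal.converged})
            elif name == "loopscore":
                bal = artifacts.get("_balanced")
                if bal is None:
                    raise PipelineError(f"{name}: missing required artifact "
                                        "'balanced matrix' (enable balance)")
                loops_path = _require(
                    name, "loops",
                    Path(spec["loops"]) if "loops" in spec
                    else artifacts.get("loops"),
                )
                loop_set = io_mod.read_bedpe(
                    loops_path, resolution=bal.base.resolution
                )
                quants = ls_mod.score_loops(bal, loop_set.loops, seed=seed)
                out_path = outdir / "loop_quants.tsv"
                with open(out_path, "w") as fh:
                    fh.write("loop_index\tbin_i\tbin_j\tsignal_mean\t"
                             "strength_sum\tbackground\tls\tscoreable\n")
                    for k, q in enumerate(quants):
                        fh.write(
                            f"{k}\t{q.loop.centroid_bin_i}\t{q.loop.centroid_bin_j}"
                            f"\t{q.signal_mean:.6g}\t{q.strength_sum:.6g}"
                            f"\t{q.background:.6g}\t{q.ls:.6g}\t{int(q.scoreable)}\n"
                        )
                record(name, {"seed": seed}, {"loops": loops_path},
                       {"quants": out_path},
                       {"n_loops_scored": sum(q.scoreable for q in quants)})
            elif name == "insulation":
                bal = artifacts.get("_balanced")
                if bal is None:
                    raise PipelineError(f"{name}: missing required artifact "
                                        "'balanced matrix' (enable balance)")
                track = ins_mod.insulation_track(
                    bal,
                    s=int(spec.get("s", 3)),
                    d=int(spec.get("d", 5)),
                )
                peaks = ins_mod.insulation_peaks(
                    track,
                    threshold=float(spec.get("threshold", 0.75)),
                    min_run=int(spec.get("min_run", 3)),
                )
                is_path = outdir / "insulation.bedgraph"
                io_mod.write_bedgraph(track, is_path)
                pk_path = outdir / "insulation_peaks.bed"
                res = track.step
                with open(pk_path, "w") as fh:
                    for p in peaks:
                        fh.write(
                            f"{track.chrom}\t{p.start_bin * res}\t"
                            f"{(p.end_bin + 1) * res}\tpeak\t{p.mean_is:.4f}\n"
                        )
                record(name, {"threshold": spec.get("threshold", 0.75)}, {},
                       {"track": is_path, "peaks": pk_path},
                       {"n_peaks": len(peaks)})
            elif name == "compartments":
                bal = artifacts.get("_balanced")
                if bal is None:
                    raise PipelineError(f"{name}: missing required artifact "
                                        "'balanced matrix' (enable balance)")
                ph_path = _require(
                    name, "phasing",
                    Path(spec["phasing"]) if "phasing" in spec
                    else artifacts.get("phasing"),
                )
                phasing = io_mod.read_bedgraph(ph_path)
                result = comp_mod.compartment_eigenvector(bal, phasing)
                n_q = int(spec.get("n_q", 50))
                result = comp_mod.saddle(bal, result, n_q=n_q)
                ev_path = outdir / "eigenvector.bedgraph"
                io_mod.write_bedgraph(result.chosen, ev_path)
                sad_path = outdir / "saddle.tsv"
                np.savetxt(sad_path, result.saddle, delimiter="\t", fmt="%.6g")
                record(name, {"n_q": n_q}, {"phasing": ph_path},
                       {"eigenvector": ev_path, "saddle": sad_path},
                       {"chosen_index": result.chosen_index,
                        "correlation": round(result.correlation_with_phasing, 6)})
    except Exception as exc:  # record the error, keep completed outputs
        fail(exc)
        raise

    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
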