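"""Config-driven end-to-end runs: synth -> superpose -> rmsf / gate / pca /
density, with provenance-stamped plain-text outputs and a summary report.

A run is described by one YAML mapping (see :class:`RunConfig`); one config
= one run = one output directory.  Deterministic stages are byte-
reproducible under a fixed config; stochastic stages under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import yaml

from . import __version__
from .model import HelixSpec, Structure, Trajectory
from .pdbio import read_pdb, read_trajectory, write_pdb, write_trajectory_pdb
from .selection import resolve_selection
from .gate import GatePairSpec, TurnSpec, gate_series
from .fluctuations import pool_rmsf, rmsf
from .pca import (
    fit_pca, landscape, pc_displacement_vectors, project,
    representative_conformation,
)
from .density import density_grid, write_dx
from . import synth as synthmod

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and a machine-readable code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class RunConfig:
    """Validated run description (a plain YAML mapping on disk).

    Keys: ``seed``, ``out_dir``, ``input`` (either ``synth: {...}`` or
    ``topology``/``trajectories`` paths), ``stages`` (mapping of stage name
    to options).  The config is fully serializable; ``config_hash`` stamps
    every output for provenance.
    """

    raw: dict[str, Any]

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise PipelineError("config", "malformed", "config must be a mapping")
        return cls(raw=raw)

    @property
    def seed(self) -> int:
        return int(self.raw.get("seed", 0))

    @property
    def out_dir(self) -> str:
        return str(self.raw.get("out_dir", "gatescope_run"))

    @property
    def stages(self) -> dict[str, Any]:
        return dict(self.raw.get("stages", {}))

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(cfg: RunConfig) -> list[str]:
    return [
        f"# gatescope {__version__}",
        f"# config_hash {cfg.config_hash()}",
        f"# seed {cfg.seed}",
    ]


def write_tsv(
    path: str | os.PathLike,
    header: Sequence[str],
    rows: Sequence[Sequence[Any]],
    provenance: Sequence[str] = (),
) -> None:
    """TSV with ``#`` comment/provenance lines, then a ``#``-prefixed header."""

    def fmt(v: Any) -> str:
        if isinstance(v, float):
            if np.isinf(v):
                return "inf"
            return f"{v:.6f}"
        return str(v)

    with open(path, "w") as fh:
        for line in provenance:
            fh.write(line + "\n")
        fh.write("# " + "\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(fmt(v) for v in row) + "\n")


def _parse_turn(d: dict[str, Any]) -> TurnSpec:
    start = int(d["start"])
    return TurnSpec(
        chain_id=str(d["chain"]),
        residues=tuple(range(start, start + 4)),
        atom_class=str(d.get("atom_class", "all")),
    )


def _parse_helix(d: dict[str, Any]) -> HelixSpec:
    return HelixSpec(
        label=str(d.get("label", "helix")), chain_id=str(d["chain"]),
        first_residue=int(d["first"]), last_residue=int(d["last"]),
    )


def _load_input(cfg: RunConfig, out_dir: str) -> list[Trajectory]:
    inp = cfg.raw.get("input", {})
    if "synth" in inp:
        s = dict(inp["synth"])
        mode = s.get("mode", "harmonic")
        spec = synthmod.SynthSpec(
            seed=cfg.seed,
            n_frames=int(s.get("n_frames", 500)),
            n_replicas=int(s.get("n_replicas", 5)),
        )
        if mode == "harmonic":
            ref = synthmod.make_ideal_helix(int(s.get("n_res", 20)))
            return synthmod.make_harmonic_trajectory(
                ref, float(s.get("sigma", 1.0)), spec
            )
        if mode == "two_state":
            ref = synthmod.make_ideal_helix(int(s.get("n_res", 20)))
            mvec = synthmod.make_collective_mode(ref, cfg.seed)
            trajs, _ = synthmod.make_two_state_trajectory(
                ref, mvec, float(s.get("separation", 6.0)),
                float(s.get("p_major", 0.8)), float(s.get("noise_sigma", 0.5)),
                spec,
            )
            return trajs
        if mode == "gate_toy":
            n_frames = spec.n_frames
            angles = np.asarray(s.get(
                "angle_schedule",
                np.where(np.arange(n_frames) < n_frames // 2, 10.0, 40.0),
            ), dtype=float)
            dists = np.asarray(
                s.get("distance_schedule", np.full(len(angles), 12.0)), dtype=float
            )
            traj, _, _, _ = synthmod.make_gate_toy(angles, dists, spec)
            return [traj]
        if mode == "lipid_field":
            hotspot = None
            if "hotspot" in s:
                h = s["hotspot"]
                hotspot = (np.asarray(h["center"], float),
                           float(h["sigma"]), float(h["fraction"]))
            return synthmod.make_lipid_field(
                int(s.get("n_particles", 2000)), spec, hotspot=hotspot
            )
        raise PipelineError("input", "unknown-mode", f"synth mode {mode!r}")
    if "topology" in inp and "trajectories" in inp:
        top = read_pdb(inp["topology"], model_policy="first")
        return [
            read_trajectory(p, top, replica_id=i)
            for i, p in enumerate(inp["trajectories"])
        ]
    raise PipelineError(
        "input", "missing",
        "config needs input.synth or input.topology + input.trajectories",
    )


def run_pipeline(config: RunConfig | dict[str, Any]) -> str:
    """Execute the configured stages in dependency order; returns out_dir.

    Any stage error aborts the run with a :class:`PipelineError` naming the
    stage.  A ``summary.txt`` report collects per-stage headline numbers.
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig(raw=config)
    out_dir = cfg.out_dir
    os.makedirs(out_dir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(out_dir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("gatescope")
    root.addHandler(handler)
    root.setLevel(cfg.raw.get("log_level", "INFO"))
    prov = _provenance(cfg)
    summary: list[str] = list(prov)
    try:
        trajs = _load_input(cfg, out_dir)
        log.info("loaded %d replica(s), %d frames each, %d atoms",
                 len(trajs), trajs[0].n_frames, trajs[0].n_atoms)
        summary.append(
            f"input: {len(trajs)} replicas x {trajs[0].n_frames} frames, "
            f"{trajs[0].n_atoms} atoms"
        )
        stages = cfg.stages
        top = trajs[0].topology

        if "rmsf" in stages:
            s = stages["rmsf"] or {}
            try:
                fit = s.get("fit", "all")
                analyze = s.get("analyze", "heavy")
                profiles = [rmsf(t, fit, analyze) for t in trajs]
                pooled, sem = pool_rmsf(profiles)
            except Exception as e:  # noqa: BLE001
                raise PipelineError("rmsf", "stage-failed", str(e)) from e
            rows = [
                (k[0], k[1], pooled.residue_rmsf[i], float(sem[i]),
                 int(pooled.n_atoms_per_residue[i]))
                for i, k in enumerate(pooled.residue_keys)
            ]
            write_tsv(os.path.join(out_dir, "rmsf.tsv"),
                      ["chain", "resid", "residue_rmsf", "sem", "n_atoms"],
                      rows, prov)
            summary.append(
                f"rmsf: residue range {pooled.residue_rmsf.min():.3f}"
                f"-{pooled.residue_rmsf.max():.3f} A over {len(rows)} residues"
            )

        if "gate" in stages:
            s = stages["gate"] or {}
            try:
                pairs = [
                    GatePairSpec(str(p.get("label", f"pair{i}")),
                                 _parse_turn(p["turn_a"]), _parse_turn(p["turn_b"]))
                    for i, p in enumerate(s.get("pairs", []))
                ]
                helices = None
                if "helices" in s and s["helices"]:
                    h7, h8 = (_parse_helix(h) for h in s["helices"])
                    helices = (h7, h8)
                series = gate_series(trajs, pairs, helices,
                                     bins=int(s.get("bins", 50)))
            except Exception as e:  # noqa: BLE001
                raise PipelineError("gate", "stage-failed", str(e)) from e
            for label, per_rep in series.distances.items():
                rows = []
                for rep, arr in enumerate(per_rep):
                    rows.extend((rep, f_i, float(v)) for f_i, v in enumerate(arr))
                write_tsv(os.path.join(out_dir, f"gate_{label}.tsv"),
                          ["replica", "frame", "distance_A"], rows, prov)
                pooled_arr = np.concatenate(per_rep)
                summary.append(
                    f"gate {label}: min {pooled_arr.min():.2f} max "
                    f"{pooled_arr.max():.2f} A (start {series.start_values[label]:.2f})"
                )
            if series.eta:
                rows = []
                for rep, arr in enumerate(series.eta):
                    rows.extend((rep, f_i, float(v)) for f_i, v in enumerate(arr))
                write_tsv(os.path.join(out_dir, "gate_eta.tsv"),
                          ["replica", "frame", "eta_deg"], rows, prov)
                pooled_arr = np.concatenate(series.eta)
                summary.append(
                    f"gate eta: range {pooled_arr.min():.1f}-{pooled_arr.max():.1f} deg"
                )
            for label, (edges, _, mean, sem) in series.histograms.items():
                centers = 0.5 * (edges[:-1] + edges[1:])
                write_tsv(os.path.join(out_dir, f"gate_{label}_hist.tsv"),
                          ["bin_center", "mean_rel_freq", "sem"],
                          list(zip(centers, mean, sem)), prov)

        if "pca" in stages:
            s = stages["pca"] or {}
            try:
                fit = s.get("fit", "all")
                analyze = s.get("analyze", "calpha")
                model = fit_pca(trajs, fit, analyze)
                projections = np.concatenate([project(t, model) for t in trajs])
                bins = s.get("bins", 100)
                if isinstance(bins, list):
                    bins = tuple(int(b) for b in bins)
                fel = landscape(projections, bins=bins,
                                temperature=float(s.get("temperature", 300.0)))
                rep, frame = representative_conformation(trajs, model, fel)
            except Exception as e:  # noqa: BLE001
                raise PipelineError("pca", "stage-failed", str(e)) from e
            ef = model.explained_fraction
            write_tsv(os.path.join(out_dir, "pca_spectrum.tsv"),
                      ["component", "eigenvalue_A2", "explained_fraction"],
                      [(i + 1, float(model.eigenvalues[i]), float(ef[i]))
                       for i in range(len(ef))], prov)
            write_tsv(os.path.join(out_dir, "pca_projections.tsv"),
                      ["frame", "pc1", "pc2"],
                      [(i, float(p[0]), float(p[1]))
                       for i, p in enumerate(projections)], prov)
            xc = 0.5 * (fel.x_edges[:-1] + fel.x_edges[1:])
            yc = 0.5 * (fel.y_edges[:-1] + fel.y_edges[1:])
            rows = []
            for i in range(len(xc)):
                for j in range(len(yc)):
                    rows.append((float(xc[i]), float(yc[j]),
                                 int(fel.counts[i, j]), float(fel.delta_g[i, j])))
            write_tsv(os.path.join(out_dir, "landscape.tsv"),
                      ["pc1", "pc2", "count", "delta_g_kcal_mol"], rows, prov)
            write_pdb(trajs[rep].frame_structure(frame),
                      os.path.join(out_dir, "representative.pdb"))
            idx, arrows = pc_displacement_vectors(
                model, 0, scale=float(s.get("arrow_scale", 1.0)),
                cutoff=float(s.get("arrow_cutoff", 0.0)),
            )
            write_tsv(os.path.join(out_dir, "porcupine_pc1.tsv"),
                      ["atom_index", "dx", "dy", "dz"],
                      [(int(i), *map(float, v)) for i, v in zip(idx, arrows)], prov)
            imax = np.unravel_index(int(np.argmax(fel.counts)), fel.counts.shape)
            summary.append(
                f"pca: PC1+PC2 explained fraction {ef[:2].sum():.3f}; "
                f"landscape minimum at bin ({imax[0]}, {imax[1]}), "
                f"representative frame replica {rep} frame {frame}"
            )

        if "density" in stages:
            s = stages["density"] or {}
            try:
                for cls in s.get("classes", [{"label": "all", "select": "all"}]):
                    grids = [
                        density_grid(
                            t, cls["select"], s.get("fit"),
                            spacing=float(s.get("spacing", 1.0)),
                            class_label=cls.get("label", ""),
                        )
                        for t in trajs
                    ]
                    mean_vals = np.mean([g.values for g in grids], axis=0)
                    grid = grids[0]
                    grid.values = mean_vals
                    label = cls.get("label", "density")
                    write_dx(grid, os.path.join(out_dir, f"density_{label}.dx"))
                    summary.append(
                        f"density {label}: peak mean occupancy "
                        f"{mean_vals.max():.4f} per frame"
                    )
            except Exception as e:  # noqa: BLE001
                raise PipelineError("density", "stage-failed", str(e)) from e

        if cfg.raw.get("write_trajectories"):
            for t in trajs:
                write_trajectory_pdb(
                    t, os.path.join(out_dir, f"replica_{t.replica_id}.pdb")
                )

        with open(os.path.join(out_dir, "summary.txt"), "w") as fh:
            fh.write("\n".join(summary) + "\n")
        return out_dir
    finally:
        root.removeHandler(handler)
        handler.close()
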