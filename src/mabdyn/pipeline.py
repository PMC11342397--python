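"""End-to-end two-system comparison pipeline.

Per system: descriptors -> boost weights -> reweighted FES -> minimum-energy
frames -> clustering -> interaction / correlation / SASA analyses restricted
to the minimum-energy frames; then cross-system effect-size statistics on
every shared descriptor.  The pipeline is a pure function of
(inputs, config, seed) and all outputs are plain CSV/JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from mabdyn import __version__, amd, clustering, correlation, geometry, interactions, stats
from mabdyn.core_io import (
    AnnotatedSystem,
    BoostSeries,
    TrajectorySlice,
    load_annotation,
    load_boost_log,
    load_trajectory,
)

__all__ = ["PipelineConfig", "SystemInputs", "PipelineError", "run_pipeline", "run_system"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, system: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for system {system!r}: {cause}")
        self.stage = stage
        self.system = system
        self.cause = cause


@dataclass
class SystemInputs:
    topology: str
    trajectory: list[str]
    annotation: str
    boost: str | None = None
    boost_dialect: str = "plain-table"


@dataclass
class PipelineConfig:
    systems: dict[str, SystemInputs]
    output_dir: str = "mabdyn_out"
    seed: int = 0
    stride: int = 1
    bins: int = 60
    temperature: float = 300.0
    pmf_threshold: float = 0.5
    cluster_cutoff: float = 6.5
    max_clusters: int = 10
    contact_cutoff: float = 4.0
    hbond_freq_cutoff: float = 0.01
    sasa_probe: float = 1.4
    sasa_points: int = 960
    correlation_threshold: float = 0.5
    weight_mode: str = "maclaurin"
    maclaurin_order: int = 10
    ch2_mode: str = "heavy"
    glycan_mode: str = "min-heavy-atom"

    def __post_init__(self) -> None:
        if len(self.systems) != 2:
            raise ValueError("exactly two systems must be configured")
        if self.pmf_threshold <= 0 or self.cluster_cutoff <= 0 or self.contact_cutoff <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 <= self.hbond_freq_cutoff <= 1:
            raise ValueError("hbond_freq_cutoff must be in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        systems = {
            name: SystemInputs(
                topology=s["topology"],
                trajectory=s["trajectory"] if isinstance(s["trajectory"], list) else [s["trajectory"]],
                annotation=s["annotation"],
                boost=s.get("boost"),
                boost_dialect=s.get("boost_dialect", "plain-table"),
            )
            for name, s in raw["systems"].items()
        }
        params = {k: v for k, v in raw.items() if k != "systems"}
        return cls(systems=systems, **params)

    def digest(self) -> str:
        # output_dir is excluded so reruns into different directories are
        # byte-identical
        blob = json.dumps(
            {
                "systems": {k: vars(v) for k, v in sorted(self.systems.items())},
                "params": {
                    k: v for k, v in vars(self).items() if k not in ("systems", "output_dir")
                },
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class SystemResult:
    name: str
    descriptors: pd.DataFrame
    fes: amd.FESGrid
    min_energy_frames: np.ndarray
    min_energy_descriptors: pd.DataFrame
    clusters: clustering.ClusterResult
    region_sasa: pd.DataFrame | None
    blocks: pd.DataFrame
    notes: list[str] = field(default_factory=list)
    frame_counts: dict[str, int] = field(default_factory=dict)


def _write(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def run_system(
    name: str,
    traj: TrajectorySlice,
    ann: AnnotatedSystem,
    boost: BoostSeries | None,
    cfg: PipelineConfig,
    out_dir: Path,
) -> SystemResult:
    """Run the single-system analysis chain, writing tables as it goes."""
    notes: list[str] = []
    sysdir = out_dir / name

    def stage(label: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(label, name, exc) from exc
                return False

        return _Ctx()

    with stage("descriptors"):
        desc = geometry.compute_descriptors(
            traj, ann, ch2_mode=cfg.ch2_mode, glycan_mode=cfg.glycan_mode
        )
        _write(desc, sysdir / "descriptors.csv")

    with stage("reweighting"):
        if boost is None:
            boost = BoostSeries(delta_v=np.zeros(traj.n_frames), frame_index=traj.frame_index)
            notes.append("no boost log supplied; unit weights used")
        boost.aligned_to(traj)
        weights = amd.boost_weights(
            boost, temperature=cfg.temperature, mode=cfg.weight_mode, order=cfg.maclaurin_order
        )
        theta = desc[["theta1", "theta2"]].to_numpy()
        fes = amd.reweighted_fes(theta, weights, bins=cfg.bins, temperature=cfg.temperature)
        _write(fes.to_frame(), sysdir / "fes.csv")

    with stage("minimum_energy_frames"):
        me = amd.minimum_energy_frames(fes, theta, pmf_threshold=cfg.pmf_threshold)
        if me.size == 0:
            raise ValueError("no frames below the PMF threshold")
        me_desc = desc.iloc[me].reset_index(drop=True)
        _write(me_desc, sysdir / "minimum_energy_descriptors.csv")
        me_traj = traj.subset_frames(me)

    with stage("clustering"):
        if me_traj.n_frames >= 2:
            mat = clustering.rmsd_matrix(me_traj)
            clus = clustering.gromos_cluster(mat, cutoff=cfg.cluster_cutoff, max_clusters=cfg.max_clusters)
        else:
            clus = clustering.ClusterResult(
                labels=np.zeros(me_traj.n_frames, dtype=np.int64),
                medoids=np.zeros(min(me_traj.n_frames, 1), dtype=np.int64),
                sizes=np.ones(min(me_traj.n_frames, 1), dtype=np.int64),
                cutoff=cfg.cluster_cutoff,
            )
            notes.append("fewer than 2 minimum-energy frames; trivial clustering")
        ctab = clus.to_frame()
        ctab["source_frame"] = me_traj.frame_index
        _write(ctab, sysdir / "clusters.csv")

    with stage("interactions"):
        top = traj.topology
        # LC heavy atoms vs hinge heavy atoms
        try:
            lc_atoms = np.concatenate(
                [np.flatnonzero((top.chain_ids == ann.chain_id(lc)) & (top.elements != "H")) for lc in ("LC1", "LC2")]
            )
            hinge_atoms = ann.residue_set_atoms(top, "hinge", heavy_only=True)
            contacts = interactions.count_contacts(me_traj, lc_atoms, hinge_atoms, cutoff=cfg.contact_cutoff)
            me_desc = me_desc.assign(lc_hinge_contacts=contacts)
            _write(me_desc, sysdir / "minimum_energy_descriptors.csv")
        except (KeyError, ValueError) as exc:
            notes.append(f"LC-hinge contacts skipped: {exc}")
        try:
            hb = interactions.hydrogen_bonds(me_traj, freq_cutoff=cfg.hbond_freq_cutoff)
            _write(interactions.hbond_table(hb, top), sysdir / "hbonds.csv")
        except ValueError as exc:
            notes.append(f"H-bond analysis skipped: {exc}")
        try:
            _, ss_freq = interactions.secondary_structure(me_traj)
            _write(ss_freq, sysdir / "secondary_structure.csv")
        except ValueError as exc:
            notes.append(f"secondary structure skipped: {exc}")

    region_tab: pd.DataFrame | None = None
    with stage("sasa"):
        sasa_tab = interactions.sasa(
            me_traj, probe_radius=cfg.sasa_probe, n_sphere_points=cfg.sasa_points
        )
        _write(sasa_tab, sysdir / "sasa_residues.csv")
        region_cols: dict[str, np.ndarray] = {}
        for set_name, pairs in ann.residue_sets.items():
            labels = [f"{ann.chain_map.get(c, c)}{r}" for c, r in pairs]
            try:
                region_cols[set_name] = interactions.region_sasa(sasa_tab, labels)
            except ValueError as exc:
                notes.append(f"region SASA for {set_name!r} skipped: {exc}")
        if region_cols:
            region_tab = pd.DataFrame({"frame": sasa_tab["frame"], **region_cols})
            _write(region_tab, sysdir / "sasa_regions.csv")

    with stage("correlation"):
        cmap = correlation.dccm(me_traj)
        _write(cmap.to_frame(), sysdir / "correlation.csv")
        blocks = correlation.domain_block_summary(
            cmap, ann, threshold=cfg.correlation_threshold, require_labels=False
        )
        _write(blocks, sysdir / "correlation_blocks.csv")

    counts = {
        "total_frames": int(traj.n_frames),
        "minimum_energy_frames": int(me.size),
        "clusters": int(clus.n_clusters),
    }
    return SystemResult(
        name=name,
        descriptors=desc,
        fes=fes,
        min_energy_frames=me,
        min_energy_descriptors=me_desc,
        clusters=clus,
        region_sasa=region_tab,
        blocks=blocks,
        notes=notes,
        frame_counts=counts,
    )


def _majority_shape(desc: pd.DataFrame) -> str:
    counts = desc["shape_label"].value_counts()
    return str(counts.index[0])


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full two-system comparison; returns the JSON summary."""
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict[str, SystemResult] = {}
    for name, inputs in cfg.systems.items():
        try:
            traj = load_trajectory(inputs.topology, inputs.trajectory, stride=cfg.stride)
            ann = load_annotation(inputs.annotation)
            boost = None
            if inputs.boost is not None:
                boost = load_boost_log(inputs.boost, dialect=inputs.boost_dialect)
                if cfg.stride > 1:
                    boost = BoostSeries(
                        delta_v=boost.delta_v[:: cfg.stride],
                        frame_index=boost.frame_index[:: cfg.stride],
                    )
        except Exception as exc:
            raise PipelineError("load", name, exc) from exc
        results[name] = run_system(name, traj, ann, boost, cfg, out_dir)

    name_a, name_b = list(cfg.systems)
    res_a, res_b = results[name_a], results[name_b]
    comparison = stats.compare_descriptors(
        res_a.min_energy_descriptors, res_b.min_energy_descriptors
    )
    _write(comparison, out_dir / "comparison_descriptors.csv")
    sasa_cmp = None
    if res_a.region_sasa is not None and res_b.region_sasa is not None:
        sasa_cmp = stats.compare_descriptors(res_a.region_sasa, res_b.region_sasa)
        _write(sasa_cmp, out_dir / "comparison_region_sasa.csv")

    summary = {
        "mabdyn_version": __version__,
        "config_digest": cfg.digest(),
        "seed": cfg.seed,
        "systems": {
            name: {
                "shape_label": _majority_shape(res.min_energy_descriptors),
                "medoid_frames": res.clusters.medoids,
                "cluster_sizes": res.clusters.sizes,
                "frame_counts": res.frame_counts,
                "strong_positive_blocks": res.blocks.loc[
                    res.blocks["strong_positive"] & (res.blocks["kind"] != "intra-domain"),
                    ["domain_a", "domain_b", "kind", "mean_correlation"],
                ].to_dict("records"),
                "notes": res.notes,
            }
            for name, res in results.items()
        },
        "comparisons": {
            "descriptors": comparison.to_dict("records"),
            "region_sasa": None if sasa_cmp is None else sasa_cmp.to_dict("records"),
        },
    }
    summary = _jsonable(summary)
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    log_lines = [f"mabdyn {__version__}", f"config {cfg.digest()}", f"seed {cfg.seed}"]
    for name, res in results.items():
        log_lines.append(f"{name}: {res.frame_counts}")
        log_lines.extend(f"{name}: note: {n}" for n in res.notes)
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return summary
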