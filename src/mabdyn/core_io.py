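"""Readers/writers and the shared data model.

Topologies are read from PDB, trajectories from DCD/XTC/AMBER-NetCDF via
MDAnalysis; annotations are a versioned YAML mapping; boost logs are either
a two-column plain table or an AMBER ``amd.log``.

Conventions: frame indexing is 0-based, lengths in Angstrom, energies in
kcal/mol, angles in degrees.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

CHAIN_LABELS = ("LC1", "LC2", "HC1", "HC2")
#: Domains recognised in annotation configs.
DOMAIN_NAMES = ("VL", "CL", "VH", "CH1", "hinge", "CH2", "CH3")

ANNOTATION_SCHEMA_VERSION = 1


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation configs."""


class TrajectoryError(ValueError):
    """Raised for trajectory/topology mismatches."""


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------


@dataclass
class Topology:
    """Flat per-atom description of the system.

    Parallel arrays of length ``n_atoms``; element symbols are guessed from
    atom names when the source format does not carry them.
    """

    atom_names: np.ndarray
    resids: np.ndarray
    resnames: np.ndarray
    chain_ids: np.ndarray
    elements: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        for name in ("resids", "resnames", "chain_ids", "elements"):
            if len(getattr(self, name)) != n:
                raise TrajectoryError(f"topology field {name!r} has inconsistent length")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def select(self, indices: np.ndarray) -> "Topology":
        return Topology(
            atom_names=self.atom_names[indices],
            resids=self.resids[indices],
            resnames=self.resnames[indices],
            chain_ids=self.chain_ids[indices],
            elements=self.elements[indices],
        )

    def residue_keys(self) -> list[tuple[str, int]]:
        """Unique (chain_id, resid) pairs in order of first appearance."""
        seen: dict[tuple[str, int], None] = {}
        for c, r in zip(self.chain_ids, self.resids):
            seen.setdefault((str(c), int(r)), None)
        return list(seen)

    def atoms_of(
        self,
        chain_id: str | None = None,
        resid: int | None = None,
        names: Iterable[str] | None = None,
        heavy_only: bool = False,
    ) -> np.ndarray:
        """Indices of atoms matching all given criteria."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if chain_id is not None:
            mask &= self.chain_ids == chain_id
        if resid is not None:
            mask &= self.resids == resid
        if names is not None:
            mask &= np.isin(self.atom_names, list(names))
        if heavy_only:
            mask &= self.elements != "H"
        return np.flatnonzero(mask)


_ELEMENT_GUESS = {"C": "C", "N": "N", "O": "O", "S": "S", "H": "H", "P": "P"}


def guess_element(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return _ELEMENT_GUESS.get(ch.upper(), ch.upper())
    return "X"


# ---------------------------------------------------------------------------
# TrajectorySlice
# ---------------------------------------------------------------------------


@dataclass
class TrajectorySlice:
    """Frame-indexed coordinates (Angstrom) for a selected atom subset."""

    coordinates: np.ndarray  # (n_frames, n_atoms, 3)
    topology: Topology
    atom_index: np.ndarray  # indices into the source topology
    frame_index: np.ndarray  # original (pre-stride) frame numbers
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        self.atom_index = np.asarray(self.atom_index, dtype=np.intp)
        self.frame_index = np.asarray(self.frame_index, dtype=np.intp)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise TrajectoryError("coordinates must have shape (frames, atoms, 3)")
        if self.coordinates.shape[1] != self.topology.n_atoms:
            raise TrajectoryError(
                f"coordinate atom count {self.coordinates.shape[1]} does not match "
                f"topology ({self.topology.n_atoms})"
            )
        if self.coordinates.shape[1] != len(self.atom_index):
            raise TrajectoryError("atom_index length does not match coordinates")
        if self.coordinates.shape[0] != len(self.frame_index):
            raise TrajectoryError("frame_index length does not match coordinates")
        if len(self.frame_index) > 1 and np.any(np.diff(self.frame_index) <= 0):
            raise TrajectoryError("frame_index must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def subset_frames(self, frame_positions: Sequence[int]) -> "TrajectorySlice":
        """New slice restricted to the given frame positions (0-based rows)."""
        pos = np.asarray(frame_positions, dtype=np.intp)
        return TrajectorySlice(
            coordinates=self.coordinates[pos],
            topology=self.topology,
            atom_index=self.atom_index,
            frame_index=self.frame_index[pos],
            box=None if self.box is None else self.box[pos],
        )


# ---------------------------------------------------------------------------
# BoostSeries
# ---------------------------------------------------------------------------


@dataclass
class BoostSeries:
    """Per-frame aMD boost energy dV (kcal/mol), aligned to saved frames."""

    delta_v: np.ndarray
    frame_index: np.ndarray

    def __post_init__(self) -> None:
        self.delta_v = np.asarray(self.delta_v, dtype=np.float64)
        self.frame_index = np.asarray(self.frame_index, dtype=np.intp)
        if self.delta_v.ndim != 1:
            raise ValueError("delta_v must be 1-D")
        if len(self.delta_v) != len(self.frame_index):
            raise ValueError("delta_v and frame_index lengths differ")
        if np.any(self.delta_v < 0):
            raise ValueError("aMD boost energies must be non-negative")

    def __len__(self) -> int:
        return len(self.delta_v)

    def aligned_to(self, traj: TrajectorySlice) -> "BoostSeries":
        """Validate alignment against a trajectory; never truncates silently."""
        if len(self) != traj.n_frames:
            raise TrajectoryError(
                f"boost series has {len(self)} frames but trajectory has "
                f"{traj.n_frames}; refusing to truncate"
            )
        return self


# ---------------------------------------------------------------------------
# AnnotatedSystem
# ---------------------------------------------------------------------------


@dataclass
class AnnotatedSystem:
    """Chain identities, domain residue ranges, glycans, residue sets, anchors.

    ``chain_map`` maps the four labels LC1/LC2/HC1/HC2 to chain ids in the
    topology.  ``domain_ranges`` maps ``(chain_label, domain)`` to inclusive
    residue-number intervals.  ``anchors`` name single residues/atoms used by
    descriptors; the conventional keys are ``fab1_apex``/``fab2_apex`` (the
    Fab-tip CA used for the inter-Fab angle), ``hinge_pivot`` (its vertex
    atom) and ``fc_glyco_site_1``/``fc_glyco_site_2`` (the Fc glycosylation
    Asn per heavy chain, used for the CH2 distance).
    """

    chain_map: dict[str, str]
    domain_ranges: dict[tuple[str, str], tuple[int, int]]
    glycans: dict[str, dict] = field(default_factory=dict)
    residue_sets: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    anchors: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [lbl for lbl in CHAIN_LABELS if lbl not in self.chain_map]
        if missing:
            raise AnnotationError(f"chain map missing label(s): {', '.join(missing)}")
        ids = [self.chain_map[lbl] for lbl in CHAIN_LABELS]
        if len(set(ids)) != len(CHAIN_LABELS):
            raise AnnotationError("the four chain labels must map to distinct chains")
        for (label, domain), (lo, hi) in self.domain_ranges.items():
            if label not in self.chain_map:
                raise AnnotationError(f"domain {domain} refers to unknown chain label {label}")
            if lo > hi:
                raise AnnotationError(f"empty interval for ({label}, {domain}): [{lo}, {hi}]")
        # overlapping intervals within one chain label are configuration errors
        by_chain: dict[str, list[tuple[int, int, str]]] = {}
        for (label, domain), (lo, hi) in self.domain_ranges.items():
            by_chain.setdefault(label, []).append((lo, hi, domain))
        for label, ivals in by_chain.items():
            ivals.sort()
            for (lo1, hi1, d1), (lo2, hi2, d2) in zip(ivals, ivals[1:]):
                if lo2 <= hi1:
                    raise AnnotationError(
                        f"overlapping domains on {label}: {d1} [{lo1},{hi1}] and {d2} [{lo2},{hi2}]"
                    )

    # -- resolution against a topology ------------------------------------

    def chain_id(self, label: str) -> str:
        try:
            return self.chain_map[label]
        except KeyError:
            raise AnnotationError(f"unknown chain label {label!r}") from None

    def domain_atoms(
        self,
        top: Topology,
        chain_label: str,
        domain: str,
        names: Iterable[str] | None = ("CA",),
    ) -> np.ndarray:
        """Atom indices of a domain, by default its CA atoms."""
        try:
            lo, hi = self.domain_ranges[(chain_label, domain)]
        except KeyError:
            raise AnnotationError(f"no domain ({chain_label}, {domain}) in annotation") from None
        cid = self.chain_id(chain_label)
        mask = (top.chain_ids == cid) & (top.resids >= lo) & (top.resids <= hi)
        if names is not None:
            mask &= np.isin(top.atom_names, list(names))
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise AnnotationError(f"domain ({chain_label}, {domain}) selects no atoms")
        return idx

    def anchor_atom(self, top: Topology, name: str) -> int:
        """Resolve a named anchor to exactly one atom index."""
        spec = self._anchor_spec(name)
        atom = spec.get("atom")
        if atom is None:
            raise AnnotationError(f"anchor {name!r} has no atom name; use anchor_residue_atoms")
        idx = top.atoms_of(chain_id=self._anchor_chain(spec), resid=int(spec["resid"]), names=[atom])
        if idx.size != 1:
            raise AnnotationError(
                f"anchor {name!r} ({spec}) resolved to {idx.size} atoms, expected exactly 1"
            )
        return int(idx[0])

    def anchor_residue_atoms(self, top: Topology, name: str, heavy_only: bool = True) -> np.ndarray:
        """All (heavy) atoms of the residue a named anchor points at."""
        spec = self._anchor_spec(name)
        idx = top.atoms_of(chain_id=self._anchor_chain(spec), resid=int(spec["resid"]), heavy_only=heavy_only)
        if idx.size == 0:
            raise AnnotationError(f"anchor residue {name!r} ({spec}) not found in topology")
        return idx

    def _anchor_spec(self, name: str) -> dict:
        try:
            return self.anchors[name]
        except KeyError:
            raise AnnotationError(f"no anchor named {name!r} in annotation") from None

    def _anchor_chain(self, spec: Mapping) -> str:
        chain = spec["chain"]
        return self.chain_map.get(chain, chain)

    def glycan_atoms(self, top: Topology, name: str, heavy_only: bool = True) -> np.ndarray:
        try:
            spec = self.glycans[name]
        except KeyError:
            raise AnnotationError(f"no glycan named {name!r} in annotation") from None
        cid = self.chain_map.get(spec["chain"], spec["chain"])
        mask = top.chain_ids == cid
        if "resids" in spec and spec["resids"] is not None:
            mask &= np.isin(top.resids, list(spec["resids"]))
        if heavy_only:
            mask &= top.elements != "H"
        idx = np.flatnonzero(mask)
        if idx.size == 0:
            raise AnnotationError(f"glycan selection {name!r} is empty")
        return idx

    def residue_set_atoms(
        self, top: Topology, set_name: str, names: Iterable[str] | None = None, heavy_only: bool = False
    ) -> np.ndarray:
        try:
            pairs = self.residue_sets[set_name]
        except KeyError:
            raise AnnotationError(f"no residue set named {set_name!r}") from None
        parts = []
        for label, resid in pairs:
            cid = self.chain_map.get(label, label)
            parts.append(top.atoms_of(chain_id=cid, resid=int(resid), names=names, heavy_only=heavy_only))
        if not parts:
            return np.array([], dtype=np.intp)
        return np.concatenate(parts)

    def fab_chain_labels(self, fab: int) -> tuple[str, str]:
        """(HC, LC) chain labels of Fab arm 1 or 2 (annotation order fixes identity)."""
        if fab not in (1, 2):
            raise ValueError("fab must be 1 or 2")
        return (f"HC{fab}", f"LC{fab}")


# ---------------------------------------------------------------------------
# Annotation YAML I/O
# ---------------------------------------------------------------------------


def annotation_to_dict(ann: AnnotatedSystem) -> dict:
    domains: dict[str, dict[str, list[int]]] = {}
    for (label, domain), (lo, hi) in sorted(ann.domain_ranges.items()):
        domains.setdefault(label, {})[domain] = [int(lo), int(hi)]
    return {
        "schema_version": ANNOTATION_SCHEMA_VERSION,
        "chains": dict(ann.chain_map),
        "domains": domains,
        "glycans": {k: dict(v) for k, v in ann.glycans.items()},
        "residue_sets": {k: [[c, int(r)] for c, r in v] for k, v in ann.residue_sets.items()},
        "anchors": {k: dict(v) for k, v in ann.anchors.items()},
    }


def annotation_from_dict(data: Mapping) -> AnnotatedSystem:
    version = data.get("schema_version")
    if version != ANNOTATION_SCHEMA_VERSION:
        raise AnnotationError(f"unsupported annotation schema_version: {version!r}")
    chains = data.get("chains") or {}
    domains_raw = data.get("domains") or {}
    domain_ranges: dict[tuple[str, str], tuple[int, int]] = {}
    for label, table in domains_raw.items():
        for domain, interval in table.items():
            if domain not in DOMAIN_NAMES:
                raise AnnotationError(f"unknown domain name {domain!r} on chain {label}")
            lo, hi = interval
            domain_ranges[(label, domain)] = (int(lo), int(hi))
    required = {("HC1", "VH"), ("HC2", "VH"), ("LC1", "VL"), ("LC2", "VL"),
                ("HC1", "CH2"), ("HC2", "CH2")}
    missing = required - set(domain_ranges)
    if missing:
        raise AnnotationError(f"annotation missing required domains: {sorted(missing)}")
    residue_sets = {
        k: [(str(c), int(r)) for c, r in v] for k, v in (data.get("residue_sets") or {}).items()
    }
    return AnnotatedSystem(
        chain_map={str(k): str(v) for k, v in chains.items()},
        domain_ranges=domain_ranges,
        glycans={str(k): dict(v) for k, v in (data.get("glycans") or {}).items()},
        residue_sets=residue_sets,
        anchors={str(k): dict(v) for k, v in (data.get("anchors") or {}).items()},
    )


def load_annotation(config_path: str | Path) -> AnnotatedSystem:
    """Read and validate an annotation config (YAML mapping, schema v1)."""
    with open(config_path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise AnnotationError(f"{config_path}: annotation config must be a mapping")
    return annotation_from_dict(data)


def write_annotation(ann: AnnotatedSystem, config_path: str | Path) -> None:
    with open(config_path, "w") as fh:
        yaml.safe_dump(annotation_to_dict(ann), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Trajectory I/O (MDAnalysis-backed)
# ---------------------------------------------------------------------------


def _universe(topology_path: str | Path, trajectory_paths: Sequence[str | Path] | None):
    import MDAnalysis as mda

    topology_path = Path(topology_path)
    if not topology_path.exists():
        raise FileNotFoundError(topology_path)
    args = [str(topology_path)]
    if trajectory_paths:
        for p in trajectory_paths:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        args.append([str(p) for p in trajectory_paths])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(*args)


def _topology_from_atomgroup(ag) -> Topology:
    names = np.asarray([a.name for a in ag], dtype=object)
    if hasattr(ag, "elements"):
        elements = np.asarray([str(e).capitalize() or guess_element(n) for e, n in zip(ag.elements, names)], dtype=object)
    else:
        elements = np.asarray([guess_element(n) for n in names], dtype=object)
    try:
        chain_ids = np.asarray([a.chainID for a in ag], dtype=object)
    except Exception:
        chain_ids = np.asarray([a.segid for a in ag], dtype=object)
    return Topology(
        atom_names=names,
        resids=np.asarray([a.resid for a in ag], dtype=np.int64),
        resnames=np.asarray([a.resname for a in ag], dtype=object),
        chain_ids=chain_ids,
        elements=elements,
    )


def load_trajectory(
    topology_path: str | Path,
    trajectory_paths: Sequence[str | Path] | str | Path | None = None,
    atom_selection: str = "all",
    stride: int = 1,
) -> TrajectorySlice:
    """Load a PDB topology plus DCD/XTC/NetCDF trajectory file(s).

    Frames are concatenated in file order, ``stride`` is applied uniformly
    over the concatenated sequence, and coordinates are in Angstrom.
    ``atom_selection`` is an MDAnalysis selection string.
    """
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if isinstance(trajectory_paths, (str, Path)):
        trajectory_paths = [trajectory_paths]
    u = _universe(topology_path, trajectory_paths)
    ag = u.select_atoms(atom_selection)
    if ag.n_atoms == 0:
        raise TrajectoryError(f"selection {atom_selection!r} matched no atoms")
    top = _topology_from_atomgroup(ag)
    coords, frames, boxes = [], [], []
    have_box = False
    for i, ts in enumerate(u.trajectory):
        if i % stride:
            continue
        coords.append(ag.positions.astype(np.float64).copy())
        frames.append(i)
        if ts.dimensions is not None and np.any(ts.dimensions[:3] > 0):
            have_box = True
            boxes.append(np.array(ts.dimensions, dtype=np.float64))
        else:
            boxes.append(np.zeros(6))
    return TrajectorySlice(
        coordinates=np.stack(coords),
        topology=top,
        atom_index=ag.ix.astype(np.intp),
        frame_index=np.asarray(frames, dtype=np.intp),
        box=np.stack(boxes) if have_box else None,
    )


def to_universe(top: Topology, coordinates: np.ndarray):
    """Build an in-memory MDAnalysis Universe from the flat data model."""
    import MDAnalysis as mda

    coordinates = np.asarray(coordinates, dtype=np.float64)
    if coordinates.ndim == 2:
        coordinates = coordinates[None]
    keys = top.residue_keys()
    key_to_rix = {k: i for i, k in enumerate(keys)}
    atom_rix = np.array([key_to_rix[(str(c), int(r))] for c, r in zip(top.chain_ids, top.resids)])
    seg_ids = sorted({c for c, _ in keys})
    seg_to_six = {s: i for i, s in enumerate(seg_ids)}
    res_six = np.array([seg_to_six[c] for c, _ in keys])
    u = mda.Universe.empty(
        n_atoms=top.n_atoms,
        n_residues=len(keys),
        n_segments=len(seg_ids),
        atom_resindex=atom_rix,
        residue_segindex=res_six,
        trajectory=True,
    )
    u.add_TopologyAttr("names", [str(n) for n in top.atom_names])
    u.add_TopologyAttr("elements", [str(e) for e in top.elements])
    u.add_TopologyAttr("resids", [r for _, r in keys])
    u.add_TopologyAttr("resnames", [str(top.resnames[np.flatnonzero(atom_rix == i)[0]]) for i in range(len(keys))])
    u.add_TopologyAttr("segids", seg_ids)
    u.add_TopologyAttr("chainIDs", [str(c) for c in top.chain_ids])
    u.load_new(coordinates.astype(np.float32), order="fac")
    return u


def write_trajectory(traj: TrajectorySlice, topology_path: str | Path, trajectory_path: str | Path | None = None) -> None:
    """Write the slice as a PDB (first frame) plus optional trajectory file."""
    u = to_universe(traj.topology, traj.coordinates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.write(str(topology_path))
        if trajectory_path is not None:
            with __import__("MDAnalysis").Writer(str(trajectory_path), n_atoms=u.atoms.n_atoms) as w:
                for _ in u.trajectory:
                    w.write(u.atoms)


# ---------------------------------------------------------------------------
# Boost logs
# ---------------------------------------------------------------------------


def load_boost_log(path: str | Path, dialect: str = "plain-table") -> BoostSeries:
    """Read per-frame boost energies.

    ``plain-table``: two whitespace-separated columns ``frame  delta_v``;
    lines starting with ``#`` are comments.

    ``amber-amd-log``: AMBER ``amd.log`` records, whose last two numeric
    columns are the total-potential and dihedral boost energies; dV is their
    sum, matching the iamd=3 dual-boost protocol.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "plain-table":
        frames, dvs = [], []
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                frames.append(int(float(parts[0])))
                dvs.append(float(parts[1]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric row: {line!r}") from exc
        return BoostSeries(delta_v=np.asarray(dvs), frame_index=np.asarray(frames))
    if dialect == "amber-amd-log":
        dvs = []
        for lineno, line in enumerate(path.read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                pot_boost, dih_boost = float(parts[-2]), float(parts[-1])
            except (ValueError, IndexError) as exc:
                raise ValueError(f"{path}:{lineno}: cannot parse boost columns: {line!r}") from exc
            dvs.append(pot_boost + dih_boost)
        return BoostSeries(delta_v=np.asarray(dvs), frame_index=np.arange(len(dvs)))
    raise ValueError(f"unknown boost log dialect {dialect!r}")


def write_boost_log(series: BoostSeries, path: str | Path) -> None:
    """Write a BoostSeries as a plain two-column table (round-trips exactly)."""
    buf = io.StringIO()
    buf.write("# frame delta_v_kcal_mol\n")
    for f, dv in zip(series.frame_index, series.delta_v):
        buf.write(f"{int(f)} {float(dv)!r}\n")
    Path(path).write_text(buf.getvalue())
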