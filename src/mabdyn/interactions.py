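"""Contact, hydrogen-bond, secondary-structure, SASA and patch analysis.

All operators work on the flat data model (Topology + coordinate arrays) so
they run identically on loaded trajectories and on generated fixtures.

The secondary-structure operator is a Kabsch-Sander implementation: backbone
amide hydrogens are reconstructed from the preceding carbonyl, H-bonds are
scored with E = 0.084*(1/rON + 1/rCH - 1/rOH - 1/rCN)*332 kcal/mol (bond if
E < -0.5), and the standard turn/helix/bridge patterns give 8-state codes.
The surface-patch operator is a deliberately simplified stand-in for
proprietary surface tooling: exposed residues of one chemical class,
connected within a side-chain distance cutoff, form a patch whose area is
the sum of member-residue SASA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from mabdyn.core_io import Topology, TrajectorySlice

__all__ = [
    "HBondRecord",
    "Patch",
    "PatchSet",
    "count_contacts",
    "hydrogen_bonds",
    "secondary_structure",
    "sasa",
    "surface_patches",
]

# ---------------------------------------------------------------------------
# Contacts
# ---------------------------------------------------------------------------


def count_contacts(
    traj: TrajectorySlice,
    group_a: np.ndarray,
    group_b: np.ndarray,
    cutoff: float = 4.0,
) -> np.ndarray:
    """Per-frame number of atom pairs (a in A, b in B) closer than ``cutoff``."""
    a = np.asarray(group_a, dtype=np.intp)
    b = np.asarray(group_b, dtype=np.intp)
    if a.size == 0 or b.size == 0:
        raise ValueError("contact groups must be non-empty")
    if np.intersect1d(a, b).size:
        raise ValueError("contact groups must be disjoint")
    counts = np.empty(traj.n_frames, dtype=np.int64)
    for f in range(traj.n_frames):
        diff = traj.coordinates[f, a][:, None, :] - traj.coordinates[f, b][None, :, :]
        d2 = (diff**2).sum(axis=2)
        counts[f] = int((d2 < cutoff**2).sum())
    return counts


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HBondRecord:
    """One donor-H...acceptor triplet with its occupancy over frames."""

    donor: int
    hydrogen: int
    acceptor: int
    frequency: float

    def label(self, top: Topology) -> str:
        def atom(i: int) -> str:
            return f"{top.chain_ids[i]}/{top.resnames[i]}{top.resids[i]}:{top.atom_names[i]}"

        return f"{atom(self.donor)}--{atom(self.hydrogen)}...{atom(self.acceptor)}"


_POLAR = ("N", "O", "S")
_COVALENT_H_CUTOFF = 1.25  # Angstrom


def _donor_pairs(top: Topology, coords0: np.ndarray) -> list[tuple[int, int]]:
    """(donor_heavy, hydrogen) pairs: each H bound to its nearest polar atom."""
    h_idx = np.flatnonzero(top.elements == "H")
    polar_idx = np.flatnonzero(np.isin(top.elements, _POLAR))
    pairs = []
    for h in h_idx:
        if polar_idx.size == 0:
            break
        d = np.linalg.norm(coords0[polar_idx] - coords0[h], axis=1)
        j = int(np.argmin(d))
        if d[j] <= _COVALENT_H_CUTOFF:
            pairs.append((int(polar_idx[j]), int(h)))
    return pairs


def hydrogen_bonds(
    traj: TrajectorySlice,
    h_a_cutoff: float = 2.5,
    dha_min_angle: float = 120.0,
    freq_cutoff: float = 0.01,
) -> list[HBondRecord]:
    """Baker-Hubbard-style geometric H-bond detection with a frequency filter.

    A bond is counted in a frame when the H...acceptor distance is below
    ``h_a_cutoff`` (Angstrom) and the donor-H-acceptor angle exceeds
    ``dha_min_angle`` (degrees).  Triplets occurring in fewer than
    ``freq_cutoff`` of the frames are dropped.
    """
    top = traj.topology
    if not np.any(top.elements == "H"):
        raise ValueError("topology contains no hydrogens; cannot detect H-bonds")
    pairs = _donor_pairs(top, traj.coordinates[0])
    acceptors = np.flatnonzero(np.isin(top.elements, _POLAR))
    tallies: dict[tuple[int, int, int], int] = {}
    cos_min = np.cos(np.radians(dha_min_angle))
    for f in range(traj.n_frames):
        xyz = traj.coordinates[f]
        for donor, h in pairs:
            acc = acceptors[acceptors != donor]
            vec_ha = xyz[acc] - xyz[h]
            dist = np.linalg.norm(vec_ha, axis=1)
            close = dist < h_a_cutoff
            if not close.any():
                continue
            vec_hd = xyz[donor] - xyz[h]
            vec_hd = vec_hd / np.linalg.norm(vec_hd)
            cosang = (vec_ha[close] / dist[close, None]) @ vec_hd
            # angle > threshold  <=>  cos(angle) < cos(threshold)
            ok = cosang < cos_min
            for a in acc[close][ok]:
                key = (donor, h, int(a))
                tallies[key] = tallies.get(key, 0) + 1
    records = [
        HBondRecord(donor=d, hydrogen=h, acceptor=a, frequency=c / traj.n_frames)
        for (d, h, a), c in sorted(tallies.items())
    ]
    return [r for r in records if r.frequency >= freq_cutoff]


def hbond_table(records: list[HBondRecord], top: Topology) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "donor": [r.donor for r in records],
            "hydrogen": [r.hydrogen for r in records],
            "acceptor": [r.acceptor for r in records],
            "label": [r.label(top) for r in records],
            "frequency": [r.frequency for r in records],
        }
    )


# ---------------------------------------------------------------------------
# Secondary structure (Kabsch-Sander)
# ---------------------------------------------------------------------------

_Q1Q2_F = 0.084 * 332.0  # kcal/mol * Angstrom
_HB_ENERGY_CUT = -0.5
_NH_BOND = 1.0

#: 8-state to reporting-category mapping
SS_CATEGORY = {
    "H": "helix",
    "G": "helix",
    "I": "helix",
    "E": "extended",
    "B": "extended",
    "T": "turn",
    "S": "bend",
    "-": "none",
}


def _backbone_table(top: Topology) -> pd.DataFrame:
    """One row per residue with N/CA/C/O atom indices (NaN when missing)."""
    rows = {}
    order = []
    for i in range(top.n_atoms):
        key = (str(top.chain_ids[i]), int(top.resids[i]))
        if key not in rows:
            rows[key] = {"chain": key[0], "resid": key[1]}
            order.append(key)
        if top.atom_names[i] in ("N", "CA", "C", "O"):
            rows[key][str(top.atom_names[i])] = i
    return pd.DataFrame([rows[k] for k in order])


def _ks_hbond_matrix(coords: np.ndarray, bb: pd.DataFrame) -> np.ndarray:
    """hb[i, j] True when CO of residue i accepts the NH of residue j."""
    n = len(bb)
    same_chain = bb["chain"].to_numpy()
    n_xyz = coords[bb["N"].to_numpy(dtype=np.intp)]
    c_xyz = coords[bb["C"].to_numpy(dtype=np.intp)]
    o_xyz = coords[bb["O"].to_numpy(dtype=np.intp)]
    # reconstruct amide H from the previous residue's carbonyl
    h_xyz = np.full_like(n_xyz, np.nan)
    for j in range(1, n):
        if same_chain[j] != same_chain[j - 1] or bb["resid"].iat[j] != bb["resid"].iat[j - 1] + 1:
            continue
        co = c_xyz[j - 1] - o_xyz[j - 1]
        h_xyz[j] = n_xyz[j] + _NH_BOND * co / np.linalg.norm(co)
    hb = np.zeros((n, n), dtype=bool)
    valid_h = ~np.isnan(h_xyz[:, 0])
    for i in range(n):  # acceptor CO at i
        for j in range(n):  # donor NH at j
            if abs(i - j) < 2 or not valid_h[j]:
                continue
            r_on = np.linalg.norm(o_xyz[i] - n_xyz[j])
            r_ch = np.linalg.norm(c_xyz[i] - h_xyz[j])
            r_oh = np.linalg.norm(o_xyz[i] - h_xyz[j])
            r_cn = np.linalg.norm(c_xyz[i] - n_xyz[j])
            if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # clash guard
                continue
            e = _Q1Q2_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
            if e < _HB_ENERGY_CUT:
                hb[i, j] = True
    return hb


def _assign_frame(coords: np.ndarray, bb: pd.DataFrame) -> np.ndarray:
    n = len(bb)
    hb = _ks_hbond_matrix(coords, bb)
    chain = bb["chain"].to_numpy()

    def consecutive(i: int, j: int) -> bool:
        return chain[i] == chain[j]

    turn = {k: np.zeros(n, dtype=bool) for k in (3, 4, 5)}
    for k in (3, 4, 5):
        for i in range(n - k):
            if consecutive(i, i + k) and hb[i, i + k]:
                turn[k][i] = True

    helix = {k: np.zeros(n, dtype=bool) for k in (3, 4, 5)}
    for k in (3, 4, 5):
        for i in range(1, n - k):
            if turn[k][i - 1] and turn[k][i]:
                helix[k][i : i + k] = True

    para = np.zeros((n, n), dtype=bool)
    anti = np.zeros((n, n), dtype=bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            if (hb[i - 1, j] and hb[j, i + 1]) or (hb[j - 1, i] and hb[i, j + 1]):
                para[i, j] = para[j, i] = True
            if (hb[i, j] and hb[j, i]) or (hb[i - 1, j + 1] and hb[j - 1, i + 1]):
                anti[i, j] = anti[j, i] = True
    bridge = para | anti
    in_bridge = bridge.any(axis=1)
    # a ladder needs an adjacent bridge; isolated bridges are 'B'
    in_ladder = np.zeros(n, dtype=bool)
    for i in range(n):
        for j in np.flatnonzero(bridge[i]):
            for di, dj in ((1, 1), (-1, -1), (1, -1), (-1, 1)):
                i2, j2 = i + di, j + dj
                if 0 <= i2 < n and 0 <= j2 < n and bridge[i2, j2]:
                    in_ladder[i] = True

    in_turn = np.zeros(n, dtype=bool)
    for k in (3, 4, 5):
        for i in np.flatnonzero(turn[k]):
            in_turn[i + 1 : i + k] = True

    ca_xyz = coords[bb["CA"].to_numpy(dtype=np.intp)]
    bend = np.zeros(n, dtype=bool)
    for i in range(2, n - 2):
        if chain[i - 2] != chain[i] or chain[i] != chain[i + 2]:
            continue
        v1 = ca_xyz[i] - ca_xyz[i - 2]
        v2 = ca_xyz[i + 2] - ca_xyz[i]
        denom = np.linalg.norm(v1) * np.linalg.norm(v2)
        if denom < 1e-9:
            continue
        kappa = np.degrees(np.arccos(np.clip(v1 @ v2 / denom, -1, 1)))
        bend[i] = kappa > 70.0

    codes = np.full(n, "-", dtype=object)
    codes[bend] = "S"
    codes[in_turn] = "T"
    codes[helix[5]] = "I"
    codes[helix[3]] = "G"
    codes[in_bridge & ~in_ladder] = "B"
    codes[in_ladder] = "E"
    codes[helix[4]] = "H"
    return codes


def secondary_structure(
    traj: TrajectorySlice, selection: np.ndarray | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """8-state DSSP-style codes per residue per frame.

    Returns ``(codes, freq)``: a frame x residue table of one-letter codes,
    and a per-residue table of percent content per reporting category
    (helix / extended / turn / bend / none).
    """
    top = traj.topology if selection is None else traj.topology.select(np.asarray(selection, dtype=np.intp))
    coords = traj.coordinates if selection is None else traj.coordinates[:, np.asarray(selection, dtype=np.intp), :]
    bb = _backbone_table(top)
    complete = bb.dropna(subset=[c for c in ("N", "CA", "C", "O") if c in bb.columns]) if {"N", "CA", "C", "O"} <= set(bb.columns) else bb.iloc[0:0]
    if len(complete) < 0.9 * len(bb):
        raise ValueError(
            f"backbone N/CA/C/O missing for {len(bb) - len(complete)} of {len(bb)} residues"
        )
    bb = complete.reset_index(drop=True)
    all_codes = []
    for f in range(traj.n_frames):
        all_codes.append(_assign_frame(coords[f], bb))
    codes = pd.DataFrame(
        np.stack(all_codes),
        columns=[f"{c}{r}" for c, r in zip(bb["chain"], bb["resid"])],
    )
    codes.insert(0, "frame", traj.frame_index[: len(codes)])
    cats = sorted(set(SS_CATEGORY.values()))
    freq_rows = []
    for col in codes.columns[1:]:
        series = codes[col].map(SS_CATEGORY)
        counts = series.value_counts(normalize=True) * 100.0
        row = {"residue": col}
        for cat in cats:
            row[cat] = float(counts.get(cat, 0.0))
        freq_rows.append(row)
    return codes, pd.DataFrame(freq_rows)


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley)
# ---------------------------------------------------------------------------

VDW_RADII = {"C": 1.7, "N": 1.55, "O": 1.52, "S": 1.8, "H": 1.2, "P": 1.8}
DEFAULT_RADIUS = 1.7


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    i = np.arange(n, dtype=np.float64)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z**2)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def atom_radii(top: Topology) -> np.ndarray:
    radii = np.empty(top.n_atoms)
    unknown = set()
    for i, el in enumerate(top.elements):
        r = VDW_RADII.get(str(el))
        if r is None:
            unknown.add(str(el))
            r = DEFAULT_RADIUS
        radii[i] = r
    if unknown:
        warnings.warn(f"unknown element radii for {sorted(unknown)}; using {DEFAULT_RADIUS} A")
    return radii


def sasa_frame(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2) for one frame."""
    coords = np.asarray(coords, dtype=np.float64)
    expanded = np.asarray(radii, dtype=np.float64) + probe_radius
    pts = _sphere_points(n_sphere_points)
    n = len(coords)
    areas = np.empty(n)
    for i in range(n):
        sphere = coords[i] + expanded[i] * pts
        d = np.linalg.norm(coords - coords[i], axis=1)
        neigh = np.flatnonzero((d < expanded + expanded[i]) & (np.arange(n) != i))
        if neigh.size == 0:
            areas[i] = 4.0 * np.pi * expanded[i] ** 2
            continue
        buried = np.zeros(n_sphere_points, dtype=bool)
        for j in neigh:
            dj = np.linalg.norm(sphere - coords[j], axis=1)
            buried |= dj < expanded[j]
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * (~buried).sum() / n_sphere_points
    return areas


def sasa(
    traj: TrajectorySlice,
    selection: np.ndarray | None = None,
    probe_radius: float = 1.4,
    n_sphere_points: int = 960,
    radii: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-residue SASA per frame (A^2), Shrake-Rupley sphere sampling.

    Returns a frame x residue table; residues are labeled ``chain+resid``.
    """
    if selection is not None:
        sel = np.asarray(selection, dtype=np.intp)
        top = traj.topology.select(sel)
        coords = traj.coordinates[:, sel, :]
    else:
        top = traj.topology
        coords = traj.coordinates
    if radii is None:
        radii = atom_radii(top)
    keys = [f"{c}{r}" for c, r in zip(top.chain_ids, top.resids)]
    uniq = list(dict.fromkeys(keys))
    key_pos = {k: i for i, k in enumerate(uniq)}
    atom_res = np.array([key_pos[k] for k in keys])
    rows = np.zeros((traj.n_frames, len(uniq)))
    for f in range(traj.n_frames):
        per_atom = sasa_frame(coords[f], radii, probe_radius, n_sphere_points)
        np.add.at(rows[f], atom_res, per_atom)
    df = pd.DataFrame(rows, columns=uniq)
    df.insert(0, "frame", traj.frame_index)
    return df


def region_sasa(sasa_table: pd.DataFrame, residue_labels: list[str]) -> np.ndarray:
    """Per-frame summed SASA over a named set of residue labels."""
    cols = [c for c in residue_labels if c in sasa_table.columns]
    if not cols:
        raise ValueError("none of the requested residues appear in the SASA table")
    return sasa_table[cols].sum(axis=1).to_numpy()


# ---------------------------------------------------------------------------
# Surface patches (simplified)
# ---------------------------------------------------------------------------

HYDROPHOBIC = {"ALA", "VAL", "LEU", "ILE", "PHE", "MET", "TRP", "PRO"}
POSITIVE = {"ARG", "LYS", "HIS"}
NEGATIVE = {"ASP", "GLU"}

#: theoretical maximum SASA per residue type (Tien et al. style values)
MAX_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLU": 223.0, "GLN": 225.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}
DEFAULT_MAX_SASA = 200.0


def classify_residue(resname: str) -> str:
    if resname in HYDROPHOBIC:
        return "hydrophobic"
    if resname in POSITIVE:
        return "positive"
    if resname in NEGATIVE:
        return "negative"
    return "other"


@dataclass
class Patch:
    kind: str
    residues: list[str]
    area: float


@dataclass
class PatchSet:
    patches: list[Patch] = field(default_factory=list)

    def total_area(self, kind: str) -> float:
        return float(sum(p.area for p in self.patches if p.kind == kind))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patch": range(len(self.patches)),
                "type": [p.kind for p in self.patches],
                "n_residues": [len(p.residues) for p in self.patches],
                "residues": [";".join(p.residues) for p in self.patches],
                "area": [p.area for p in self.patches],
            }
        )


def surface_patches(
    frame_coords: np.ndarray,
    top: Topology,
    sasa_per_residue: dict[str, float],
    residue_classes: dict[str, str] | None = None,
    rel_sasa_threshold: float = 0.25,
    adjacency_cutoff: float = 8.0,
) -> PatchSet:
    """Group exposed same-class residues into spatial patches.

    A residue is exposed when its SASA exceeds ``rel_sasa_threshold`` times
    the per-type maximum; exposed residues of the same class whose CB atoms
    (CA for glycine or when CB is absent) lie within ``adjacency_cutoff``
    are connected, and each connected component becomes one patch with area
    equal to the summed member SASA.  This is an intentionally simplified
    surface-patch model (see module docstring).
    """
    frame_coords = np.asarray(frame_coords, dtype=np.float64)
    labels, anchor, kinds, areas = [], [], [], []
    seen = set()
    for i in range(top.n_atoms):
        key = f"{top.chain_ids[i]}{top.resids[i]}"
        if key in seen:
            continue
        seen.add(key)
        resname = str(top.resnames[i])
        kind = (residue_classes or {}).get(resname, classify_residue(resname))
        if kind == "other":
            continue
        area = float(sasa_per_residue.get(key, 0.0))
        max_area = MAX_SASA.get(resname, DEFAULT_MAX_SASA)
        if area < rel_sasa_threshold * max_area:
            continue
        res_atoms = top.atoms_of(chain_id=str(top.chain_ids[i]), resid=int(top.resids[i]))
        names = top.atom_names[res_atoms]
        if "CB" in names:
            pos = frame_coords[res_atoms[np.flatnonzero(names == "CB")[0]]]
        elif "CA" in names:
            pos = frame_coords[res_atoms[np.flatnonzero(names == "CA")[0]]]
        else:
            pos = frame_coords[res_atoms].mean(axis=0)
        labels.append(key)
        anchor.append(pos)
        kinds.append(kind)
        areas.append(area)
    patches = PatchSet()
    if not labels:
        return patches
    anchor_arr = np.asarray(anchor)
    n = len(labels)
    unvisited = set(range(n))
    while unvisited:
        seed = min(unvisited)
        comp = [seed]
        unvisited.discard(seed)
        queue = [seed]
        while queue:
            cur = queue.pop()
            d = np.linalg.norm(anchor_arr - anchor_arr[cur], axis=1)
            for j in list(unvisited):
                if kinds[j] == kinds[cur] and d[j] <= adjacency_cutoff:
                    unvisited.discard(j)
                    comp.append(j)
                    queue.append(j)
        patches.patches.append(
            Patch(
                kind=kinds[seed],
                residues=[labels[j] for j in sorted(comp)],
                area=float(sum(areas[j] for j in comp)),
            )
        )
    return patches
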