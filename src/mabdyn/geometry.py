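"""Per-frame Fab/Fc geometric descriptors.

An instantaneous reference frame is attached to the Fc and centered at the
hinge for every trajectory frame: z points from the Fc body toward the Fab
arms, x along the CH2-CH2 axis (orthogonalized against z), y = z cross x.
Each Fab centroid is then described by spherical angles theta (polar, from
+z) and phi (longitude, atan2 convention), both in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mabdyn.core_io import AnnotatedSystem, Topology, TrajectorySlice

__all__ = [
    "ReferenceFrame",
    "build_fc_frame",
    "fab_spherical_angles",
    "classify_shape",
    "delta_phi",
    "inter_fab_angle",
    "ch2_distance",
    "glycan_min_distance",
    "compute_descriptors",
]

_DEGENERACY_TOL = 1e-8
#: theta within this many degrees of a pole makes phi numerically meaningless
POLE_TOL_DEG = 1e-9


@dataclass(frozen=True)
class ReferenceFrame:
    """Orthonormal right-handed frame (rows x, y, z) with an origin, in Angstrom."""

    origin: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray

    def __post_init__(self) -> None:
        for a, b in (("x", "y"), ("x", "z"), ("y", "z")):
            if abs(float(np.dot(getattr(self, a), getattr(self, b)))) > 1e-8:
                raise ValueError(f"axes {a} and {b} are not orthogonal")
        if float(np.linalg.det(np.stack([self.x, self.y, self.z]))) < 0:
            raise ValueError("frame is not right-handed")

    def to_local(self, points: np.ndarray) -> np.ndarray:
        """Express lab-frame points in this frame's coordinates."""
        rel = np.atleast_2d(points) - self.origin
        return rel @ np.stack([self.x, self.y, self.z]).T


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < _DEGENERACY_TOL:
        raise ValueError(f"degenerate geometry: {what} has zero length")
    return v / n


def build_fc_frame(frame_coords: np.ndarray, top: Topology, ann: AnnotatedSystem) -> ReferenceFrame:
    """Fc-attached frame for one set of coordinates (n_atoms, 3).

    Origin: CA centroid of the hinge.  z: unit vector from the Fc CA centroid
    (CH2+CH3 of both heavy chains) toward the origin, i.e. pointing from the
    Fc body toward the Fabs.  x: CH2-of-HC1 centroid minus CH2-of-HC2
    centroid, Gram-Schmidt orthogonalized against z.  y: z cross x.
    """
    frame_coords = np.asarray(frame_coords, dtype=np.float64)
    hinge_idx = np.concatenate(
        [ann.domain_atoms(top, hc, "hinge") for hc in ("HC1", "HC2") if (hc, "hinge") in ann.domain_ranges]
    )
    origin = frame_coords[hinge_idx].mean(axis=0)
    fc_parts = []
    for hc in ("HC1", "HC2"):
        for dom in ("CH2", "CH3"):
            if (hc, dom) in ann.domain_ranges:
                fc_parts.append(ann.domain_atoms(top, hc, dom))
    fc_centroid = frame_coords[np.concatenate(fc_parts)].mean(axis=0)
    z = _unit(origin - fc_centroid, "Fc-to-hinge axis")
    ch2_1 = frame_coords[ann.domain_atoms(top, "HC1", "CH2")].mean(axis=0)
    ch2_2 = frame_coords[ann.domain_atoms(top, "HC2", "CH2")].mean(axis=0)
    raw_x = ch2_1 - ch2_2
    if np.linalg.norm(raw_x) < _DEGENERACY_TOL:
        raise ValueError("degenerate geometry: CH2 centroids coincide")
    x = raw_x - np.dot(raw_x, z) * z
    x = _unit(x, "CH2 axis orthogonal to z (CH2 axis parallel to z?)")
    y = np.cross(z, x)
    return ReferenceFrame(origin=origin, x=x, y=y, z=z)


def _fab_centroid(frame_coords: np.ndarray, top: Topology, ann: AnnotatedSystem, fab: int) -> np.ndarray:
    hc, lc = ann.fab_chain_labels(fab)
    parts = [
        ann.domain_atoms(top, hc, "VH"),
        ann.domain_atoms(top, lc, "VL"),
    ]
    for label, dom in ((hc, "CH1"), (lc, "CL")):
        if (label, dom) in ann.domain_ranges:
            parts.append(ann.domain_atoms(top, label, dom))
    return frame_coords[np.concatenate(parts)].mean(axis=0)


def fab_spherical_angles(
    frame_coords: np.ndarray,
    top: Topology,
    ann: AnnotatedSystem,
    frame: ReferenceFrame | None = None,
) -> dict[str, float]:
    """(theta, phi) in degrees for both Fab arms in the Fc frame.

    phi at the poles (theta = 0 or 180) is reported as 0 with the
    ``phi{n}_at_pole`` flag set, so downstream delta-phi never sees NaN.
    """
    frame_coords = np.asarray(frame_coords, dtype=np.float64)
    if frame is None:
        frame = build_fc_frame(frame_coords, top, ann)
    out: dict[str, float] = {}
    for fab in (1, 2):
        local = frame.to_local(_fab_centroid(frame_coords, top, ann, fab))[0]
        r = float(np.linalg.norm(local))
        if r < _DEGENERACY_TOL:
            raise ValueError(f"Fab{fab} centroid coincides with the hinge origin")
        theta = float(np.degrees(np.arccos(np.clip(local[2] / r, -1.0, 1.0))))
        at_pole = theta < POLE_TOL_DEG or theta > 180.0 - POLE_TOL_DEG
        phi = 0.0 if at_pole else float(np.degrees(np.arctan2(local[1], local[0])))
        out[f"theta{fab}"] = theta
        out[f"phi{fab}"] = phi
        out[f"phi{fab}_at_pole"] = bool(at_pole)
    return out


def classify_shape(theta1: float, theta2: float) -> str:
    """'Y' iff both polar angles are < 90 degrees, else 'T'."""
    for t in (theta1, theta2):
        if not 0.0 <= t <= 180.0:
            raise ValueError(f"theta out of [0, 180]: {t}")
    return "Y" if (theta1 < 90.0 and theta2 < 90.0) else "T"


def delta_phi(phi_series: np.ndarray, unwrap: bool = True) -> np.ndarray:
    """Longitude change relative to the first frame, in degrees.

    With ``unwrap`` the series is first made continuous (jumps larger than
    180 degrees corrected by +-360), so a full rotation accumulates to 360
    rather than aliasing; without it, the raw circular difference is mapped
    to (-180, 180].
    """
    phi = np.asarray(phi_series, dtype=np.float64)
    if phi.size == 0:
        raise ValueError("empty phi series")
    if unwrap:
        cont = np.degrees(np.unwrap(np.radians(phi)))
        return cont - cont[0]
    raw = phi - phi[0]
    wrapped = -(np.mod(-raw + 180.0, 360.0) - 180.0)  # maps to (-180, 180]
    return wrapped


def inter_fab_angle(frame_coords: np.ndarray, top: Topology, ann: AnnotatedSystem) -> float:
    """Vertex angle (degrees) at the hinge pivot between the two Fab apices."""
    frame_coords = np.asarray(frame_coords, dtype=np.float64)
    a = frame_coords[ann.anchor_atom(top, "fab1_apex")]
    v = frame_coords[ann.anchor_atom(top, "hinge_pivot")]
    b = frame_coords[ann.anchor_atom(top, "fab2_apex")]
    u1 = _unit(a - v, "fab1 apex-to-pivot vector (coincident anchors?)")
    u2 = _unit(b - v, "fab2 apex-to-pivot vector (coincident anchors?)")
    return float(np.degrees(np.arccos(np.clip(np.dot(u1, u2), -1.0, 1.0))))


def ch2_distance(frame_coords: np.ndarray, top: Topology, ann: AnnotatedSystem, mode: str = "heavy") -> float:
    """Distance between the two Fc glycosylation-site residues (Angstrom).

    ``heavy`` uses the residue heavy-atom centroid, ``ca`` the CA atoms.
    """
    frame_coords = np.asarray(frame_coords, dtype=np.float64)
    points = []
    for name in ("fc_glyco_site_1", "fc_glyco_site_2"):
        if mode == "heavy":
            idx = ann.anchor_residue_atoms(top, name, heavy_only=True)
            points.append(frame_coords[idx].mean(axis=0))
        elif mode == "ca":
            spec = dict(ann.anchors[name], atom="CA")
            tmp = AnnotatedSystem(
                chain_map=ann.chain_map,
                domain_ranges=ann.domain_ranges,
                anchors={name: spec},
            )
            points.append(frame_coords[tmp.anchor_atom(top, name)])
        else:
            raise ValueError(f"unknown mode {mode!r}; use 'heavy' or 'ca'")
    return float(np.linalg.norm(points[0] - points[1]))


def glycan_min_distance(
    frame_coords: np.ndarray,
    top: Topology,
    ann: AnnotatedSystem,
    mode: str = "min-heavy-atom",
    glycan_names: tuple[str, str] = ("fc_glycan_1", "fc_glycan_2"),
) -> float:
    """Separation of the two Fc glycan chains (Angstrom).

    ``min-heavy-atom`` is the closest heavy-atom pair distance (the methods
    description); ``center-of-mass`` the centroid distance (the results
    description); both are exposed because the source text uses both.
    """
    frame_coords = np.asarray(frame_coords, dtype=np.float64)
    a = frame_coords[ann.glycan_atoms(top, glycan_names[0])]
    b = frame_coords[ann.glycan_atoms(top, glycan_names[1])]
    if mode == "min-heavy-atom":
        diff = a[:, None, :] - b[None, :, :]
        return float(np.sqrt((diff**2).sum(axis=2)).min())
    if mode == "center-of-mass":
        return float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))
    raise ValueError(f"unknown mode {mode!r}")


def compute_descriptors(
    traj: TrajectorySlice,
    ann: AnnotatedSystem,
    unwrap_phi: bool = True,
    ch2_mode: str = "heavy",
    glycan_mode: str = "min-heavy-atom",
) -> pd.DataFrame:
    """Full per-frame descriptor table.

    Columns: frame, theta1, theta2, phi1, phi2, dphi1, dphi2,
    inter_fab_angle, ch2_distance, glycan_min_distance (NaN when no glycans
    are annotated), shape_label, pole flags.
    """
    top = traj.topology
    has_anchors = all(k in ann.anchors for k in ("fab1_apex", "fab2_apex", "hinge_pivot"))
    has_sites = all(k in ann.anchors for k in ("fc_glyco_site_1", "fc_glyco_site_2"))
    has_glycans = {"fc_glycan_1", "fc_glycan_2"} <= set(ann.glycans)
    rows = []
    for f in range(traj.n_frames):
        xyz = traj.coordinates[f]
        row: dict[str, object] = {"frame": int(traj.frame_index[f])}
        row.update(fab_spherical_angles(xyz, top, ann))
        if has_anchors:
            row["inter_fab_angle"] = inter_fab_angle(xyz, top, ann)
        if has_sites:
            row["ch2_distance"] = ch2_distance(xyz, top, ann, mode=ch2_mode)
        if has_glycans:
            row["glycan_min_distance"] = glycan_min_distance(xyz, top, ann, mode=glycan_mode)
        row["shape_label"] = classify_shape(row["theta1"], row["theta2"])
        rows.append(row)
    df = pd.DataFrame(rows)
    for fab in (1, 2):
        df[f"dphi{fab}"] = delta_phi(df[f"phi{fab}"].to_numpy(), unwrap=unwrap_phi)
    lead = ["frame", "theta1", "theta2", "phi1", "phi2", "dphi1", "dphi2"]
    rest = [c for c in df.columns if c not in lead]
    return df[lead + rest]
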