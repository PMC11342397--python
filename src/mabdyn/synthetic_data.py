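"""Synthetic systems with known ground truth.

Three families of generators:

* a coarse (CA-resolution) four-chain pseudo-antibody whose Fab arms follow
  prescribed per-frame (theta, phi) schedules, built so that the geometry
  descriptors invert the construction exactly on noise-free frames;
* boosted angle ensembles drawn from a designed 2-D free-energy surface,
  with per-sample boost energies, for reweighting tests;
* small all-atom fixtures (ideal helix, antiparallel sheet, donor-H-acceptor
  triads, one/two-sphere systems) for secondary-structure, H-bond and SASA
  operators.

Everything is seed-deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from mabdyn.core_io import (
    AnnotatedSystem,
    BoostSeries,
    Topology,
    TrajectorySlice,
    write_annotation,
    write_boost_log,
    write_trajectory,
)

KB = 0.0019872041  # kcal/mol/K

# ---------------------------------------------------------------------------
# Toy antibody
# ---------------------------------------------------------------------------

# residue numbering of the generated chains (inclusive); the apex anchor
# lives at resid 34 outside every domain interval, hence 4 <= n <= 10
_VH_START, _CH1_START = 1, 101
_HINGE_START, _PIVOT_RESID, _APEX_RESID = 225, 228, 34
_CH2_START, _FC_SITE_RESID = 290, 299
_CH3_START = 310


@dataclass
class ToyAntibodySpec:
    """Parameters of the generated pseudo-antibody trajectory.

    Angle schedules are per-frame targets in degrees; scalars broadcast to
    ``n_frames``. ``noise_sigma`` is the per-coordinate Gaussian sd in
    Angstrom added on top of the deterministic construction.
    """

    theta1: Sequence[float] | float = 70.0
    theta2: Sequence[float] | float = 70.0
    phi1: Sequence[float] | float = 0.0
    phi2: Sequence[float] | float = 180.0
    n_frames: int = 5
    residues_per_domain: int = 8
    arm_length: float = 40.0
    noise_sigma: float = 0.0
    seed: int = 0
    with_glycans: bool = True

    def schedules(self) -> np.ndarray:
        """(n_frames, 4) array of (theta1, theta2, phi1, phi2) in degrees."""
        cols = []
        for raw in (self.theta1, self.theta2, self.phi1, self.phi2):
            arr = np.atleast_1d(np.asarray(raw, dtype=np.float64))
            if arr.size == 1:
                arr = np.full(self.n_frames, float(arr[0]))
            if arr.size != self.n_frames:
                raise ValueError(
                    f"schedule length {arr.size} does not match n_frames={self.n_frames}"
                )
            cols.append(arr)
        return np.stack(cols, axis=1)

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValueError("zero-length schedules: n_frames must be >= 1")
        if not 4 <= self.residues_per_domain <= 10:
            raise ValueError("residues_per_domain must be in [4, 10]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.arm_length <= 0:
            raise ValueError("arm_length must be positive")


def _blob_pattern(n: int, scale: float = 0.6) -> np.ndarray:
    """Deterministic zero-mean (n, 3) offsets giving a blob 3-D extent."""
    rng = np.random.default_rng(1234567)
    pat = rng.standard_normal((n, 3)) * scale
    return pat - pat.mean(axis=0)


def toy_annotation(spec: ToyAntibodySpec) -> AnnotatedSystem:
    n = spec.residues_per_domain
    dom = {}
    for lc in ("LC1", "LC2"):
        dom[(lc, "VL")] = (_VH_START, _VH_START + n - 1)
        dom[(lc, "CL")] = (_CH1_START, _CH1_START + n - 1)
    for hc in ("HC1", "HC2"):
        dom[(hc, "VH")] = (_VH_START, _VH_START + n - 1)
        dom[(hc, "CH1")] = (_CH1_START, _CH1_START + n - 1)
        dom[(hc, "hinge")] = (_HINGE_START, _HINGE_START + n - 1)
        dom[(hc, "CH2")] = (_CH2_START, _FC_SITE_RESID)
        dom[(hc, "CH3")] = (_CH3_START, _CH3_START + n - 1)
    hinge_set = [(hc, r) for hc in ("HC1", "HC2") for r in range(_HINGE_START, _HINGE_START + n)]
    fcgr3a = [(hc, r) for hc in ("HC1", "HC2") for r in (_CH2_START, _CH2_START + 1)]
    fcrn = [(hc, r) for hc in ("HC1", "HC2") for r in (_CH3_START, _CH3_START + 1)]
    glycans = {}
    if spec.with_glycans:
        glycans = {"fc_glycan_1": {"chain": "E"}, "fc_glycan_2": {"chain": "F"}}
    return AnnotatedSystem(
        chain_map={"LC1": "A", "LC2": "B", "HC1": "C", "HC2": "D"},
        domain_ranges=dom,
        glycans=glycans,
        residue_sets={"hinge": hinge_set, "fcgr3a_site": fcgr3a, "fcrn_site": fcrn},
        anchors={
            "fab1_apex": {"chain": "HC1", "resid": _APEX_RESID, "atom": "CA"},
            "fab2_apex": {"chain": "HC2", "resid": _APEX_RESID, "atom": "CA"},
            "hinge_pivot": {"chain": "HC1", "resid": _PIVOT_RESID, "atom": "SG"},
            "fc_glyco_site_1": {"chain": "HC1", "resid": _FC_SITE_RESID},
            "fc_glyco_site_2": {"chain": "HC2", "resid": _FC_SITE_RESID},
        },
    )


def _toy_topology(spec: ToyAntibodySpec) -> tuple[Topology, dict]:
    """Atom table plus a layout dict mapping structural roles to atom rows."""
    n = spec.residues_per_domain
    names, resids, resnames, chains, elements = [], [], [], [], []
    layout: dict[str, list[int]] = {}

    def add(role: str, chain: str, resid: int, name: str, resname: str, element: str) -> None:
        layout.setdefault(role, []).append(len(names))
        names.append(name)
        resids.append(resid)
        resnames.append(resname)
        chains.append(chain)
        elements.append(element)

    def add_blob(role: str, chain: str, start_resid: int, resid_list=None) -> None:
        rlist = resid_list if resid_list is not None else range(start_resid, start_resid + n)
        for r in rlist:
            add(role, chain, r, "CA", "GLY", "C")

    ch2_resids = list(range(_CH2_START, _CH2_START + n - 1)) + [_FC_SITE_RESID]
    for arm, (lc, hc) in enumerate((("A", "C"), ("B", "D")), start=1):
        add_blob(f"VL{arm}", lc, _VH_START)
        add_blob(f"CL{arm}", lc, _CH1_START)
        add_blob(f"VH{arm}", hc, _VH_START)
        add(f"apex{arm}", hc, _APEX_RESID, "CA", "VAL", "C")
        add_blob(f"CH1_{arm}", hc, _CH1_START)
        add_blob(f"hinge{arm}", hc, _HINGE_START)
        if arm == 1:
            add("pivot", hc, _PIVOT_RESID, "SG", "CYS", "S")
        add_blob(f"CH2_{arm}", hc, _CH2_START, ch2_resids)
        add(f"fc_site_{arm}_cb", hc, _FC_SITE_RESID, "CB", "ASN", "C")
        add(f"fc_site_{arm}_nd2", hc, _FC_SITE_RESID, "ND2", "ASN", "N")
        add_blob(f"CH3_{arm}", hc, _CH3_START)
    if spec.with_glycans:
        for arm, gchain in ((1, "E"), (2, "F")):
            for j in range(4):
                add(f"glycan{arm}", gchain, 1, f"C{j + 1}", "BGC", "C")
    top = Topology(
        atom_names=np.asarray(names, dtype=object),
        resids=np.asarray(resids, dtype=np.int64),
        resnames=np.asarray(resnames, dtype=object),
        chain_ids=np.asarray(chains, dtype=object),
        elements=np.asarray(elements, dtype=object),
    )
    return top, layout


def _direction(theta_deg: float, phi_deg: float) -> np.ndarray:
    t, p = np.radians(theta_deg), np.radians(phi_deg)
    return np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])


def make_toy_antibody(spec: ToyAntibodySpec) -> tuple[AnnotatedSystem, TrajectorySlice]:
    """Build the pseudo-antibody trajectory following the angle schedules.

    The hinge CA centroid sits at the origin, the Fc body extends along -z
    (so the Fc-frame z-axis is +z), the CH2 centroids straddle the x-axis,
    and each Fab-arm CA centroid sits exactly at ``arm_length`` times the
    scheduled direction -- which makes the descriptor recovery exact.
    """
    spec.validate()
    ann = toy_annotation(spec)
    top, layout = _toy_topology(spec)
    n = spec.residues_per_domain
    pat = _blob_pattern(n)
    sched = spec.schedules()
    rng = np.random.default_rng(spec.seed)

    base = np.zeros((top.n_atoms, 3))

    def place_blob(role: str, center: np.ndarray) -> None:
        rows = layout[role]
        base[rows] = center + pat[: len(rows)]

    # static Fc half: hinge blobs straddle the origin, CH2/CH3 below
    place_blob("hinge1", np.array([1.5, 0.0, 0.0]))
    place_blob("hinge2", np.array([-1.5, 0.0, 0.0]))
    base[layout["pivot"]] = np.array([0.0, 0.0, 0.0])
    ch2_centers = {1: np.array([5.0, 0.0, -12.0]), 2: np.array([-5.0, 0.0, -12.0])}
    ch3_centers = {1: np.array([4.0, 0.0, -24.0]), 2: np.array([-4.0, 0.0, -24.0])}
    for arm in (1, 2):
        place_blob(f"CH2_{arm}", ch2_centers[arm])
        place_blob(f"CH3_{arm}", ch3_centers[arm])
        site_ca = base[layout[f"CH2_{arm}"][-1]]  # resid 299 is the blob's last CA
        base[layout[f"fc_site_{arm}_cb"]] = site_ca + np.array([0.9, 0.4, 0.2])
        base[layout[f"fc_site_{arm}_nd2"]] = site_ca + np.array([1.6, -0.3, 0.5])
    if spec.with_glycans:
        goff = np.array([[0.0, 0.0, 0.0], [1.0, 0.3, 0.1], [1.8, -0.2, 0.4], [2.4, 0.5, -0.3]])
        base[layout["glycan1"]] = np.array([2.5, 0.5, -13.0]) + goff
        base[layout["glycan2"]] = np.array([-2.5, -0.5, -13.0]) - goff

    coords = np.repeat(base[None], spec.n_frames, axis=0)
    zhat = np.array([0.0, 0.0, 1.0])
    for f in range(spec.n_frames):
        t1, t2, p1, p2 = sched[f]
        for arm, (t, p) in ((1, (t1, p1)), (2, (t2, p2))):
            u = _direction(t, p)
            w = np.cross(zhat, u)
            if np.linalg.norm(w) < 1e-9:
                w = np.array([1.0, 0.0, 0.0])
            else:
                w = w / np.linalg.norm(w)
            center = spec.arm_length * u
            for role, offset in (
                (f"VH{arm}", 3.0 * u),
                (f"CH1_{arm}", -3.0 * u),
                (f"VL{arm}", 1.5 * w),
                (f"CL{arm}", -1.5 * w),
            ):
                rows = layout[role]
                coords[f, rows] = center + offset + pat[: len(rows)]
            coords[f, layout[f"apex{arm}"]] = (spec.arm_length + 8.0) * u
    if spec.noise_sigma > 0:
        coords = coords + rng.normal(0.0, spec.noise_sigma, size=coords.shape)

    traj = TrajectorySlice(
        coordinates=coords,
        topology=top,
        atom_index=np.arange(top.n_atoms),
        frame_index=np.arange(spec.n_frames),
    )
    return ann, traj


def export_toy_system(
    spec: ToyAntibodySpec,
    out_dir: str | Path,
    prefix: str = "toy",
    boost: BoostSeries | None = None,
) -> dict[str, Path]:
    """Write PDB + DCD + annotation YAML + boost table for file-level runs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ann, traj = make_toy_antibody(spec)
    paths = {
        "topology": out_dir / f"{prefix}.pdb",
        "trajectory": out_dir / f"{prefix}.dcd",
        "annotation": out_dir / f"{prefix}_annotation.yaml",
        "boost": out_dir / f"{prefix}_boost.txt",
    }
    write_trajectory(traj, paths["topology"], paths["trajectory"])
    write_annotation(ann, paths["annotation"])
    if boost is None:
        boost = BoostSeries(delta_v=np.zeros(traj.n_frames), frame_index=traj.frame_index)
    write_boost_log(boost, paths["boost"])
    return paths


# ---------------------------------------------------------------------------
# Designed PMFs and boosted ensembles
# ---------------------------------------------------------------------------


@dataclass
class DesignedPMF:
    """Analytic PMF over (theta1, theta2) in kcal/mol, minimum 0 by shift."""

    func: Callable[[np.ndarray, np.ndarray], np.ndarray]
    temperature: float = 300.0
    domain: tuple[float, float] = (0.0, 180.0)
    _shift: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        lo, hi = self.domain
        g = np.linspace(lo, hi, 721)
        t1, t2 = np.meshgrid(g, g, indexing="ij")
        self._shift = float(np.min(self.func(t1, t2)))

    def __call__(self, theta1: np.ndarray, theta2: np.ndarray) -> np.ndarray:
        return self.func(np.asarray(theta1, float), np.asarray(theta2, float)) - self._shift


def harmonic_pmf(
    minima: tuple[float, float] = (70.0, 70.0),
    curvature: tuple[float, float] = (0.002, 0.002),
    temperature: float = 300.0,
) -> DesignedPMF:
    """Sum of two 1-D harmonic wells: 0.5*k*(theta - m)^2 per axis."""
    m1, m2 = minima
    k1, k2 = curvature

    def f(t1, t2):
        return 0.5 * k1 * (t1 - m1) ** 2 + 0.5 * k2 * (t2 - m2) ** 2

    return DesignedPMF(func=f, temperature=temperature)


def double_well_pmf(
    minima: tuple[float, float] = (60.0, 110.0),
    barrier: float = 1.5,
    temperature: float = 300.0,
    domain: tuple[float, float] = (50.0, 120.0),
) -> DesignedPMF:
    """Quartic double well along theta1, gentle harmonic along theta2.

    The amplitudes are kept small enough that beta*dV of the flattening
    boost stays within the Maclaurin-expansion validity range.
    """
    a, b = minima
    c, w = 0.5 * (a + b), 0.5 * (b - a)

    def f(t1, t2):
        return barrier * (((t1 - c) / w) ** 2 - 1.0) ** 2 + 0.5 * 0.001 * (t2 - 70.0) ** 2

    return DesignedPMF(func=f, temperature=temperature, domain=domain)


def flattening_boost(designed_pmf: DesignedPMF) -> Callable[[np.ndarray, np.ndarray], np.ndarray]:
    """The boost that perfectly flattens the designed PMF.

    aMD raises low-energy regions, so the flattening boost fills the wells:
    dV(theta) = max(PMF) - PMF(theta) over the PMF's domain.  Sampling under
    this boost is uniform, and reweighting must recover the design.
    """
    lo, hi = designed_pmf.domain
    g = np.linspace(lo, hi, 721)
    t1, t2 = np.meshgrid(g, g, indexing="ij")
    fmax = float(np.max(designed_pmf(t1, t2)))

    def dv(t1, t2):
        return fmax - designed_pmf(t1, t2)

    return dv


def simulate_boosted_ensemble(
    designed_pmf: DesignedPMF,
    boost_spec: Callable[[np.ndarray, np.ndarray], np.ndarray] | float,
    n_frames: int,
    seed: int,
) -> tuple[np.ndarray, BoostSeries]:
    """Draw (theta1, theta2) samples from a boosted ensemble.

    The boost is *added* to the surface (the aMD convention), so samples
    follow a density proportional to exp(-(PMF + dV)/kT) and reweighting a
    sample by exp(+beta*dV) recovers the unbiased density.  Samples are
    drawn continuously by vectorized rejection sampling and each carries its
    matching dV.  ``boost_spec`` is a constant or a function of
    (theta1, theta2); use :func:`flattening_boost` for the
    uniform-sampling case.  Negative boosts are rejected.

    Returns ``(samples, boost)`` where samples has shape (n_frames, 2).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    kt = KB * designed_pmf.temperature
    lo, hi = designed_pmf.domain

    if callable(boost_spec):
        boost_fn = boost_spec
    else:
        const = float(boost_spec)
        boost_fn = lambda t1, t2: np.full_like(np.asarray(t1, float), const)  # noqa: E731

    def boosted_pmf(t1, t2):
        f = designed_pmf(t1, t2)
        dv = np.asarray(boost_fn(t1, t2), float)
        return f + dv, dv

    # envelope for rejection sampling: density max over a fine grid
    g = np.linspace(lo, hi, 721)
    t1g, t2g = np.meshgrid(g, g, indexing="ij")
    fb, dvg = boosted_pmf(t1g, t2g)
    if np.any(dvg < -1e-12):
        raise ValueError("boost_spec produced negative boost energies")
    log_env = float(np.max(-fb / kt))

    samples = np.empty((0, 2))
    dvs = np.empty(0)
    span = hi - lo
    while samples.shape[0] < n_frames:
        m = max(4 * (n_frames - samples.shape[0]), 1000)
        cand = lo + span * rng.random((m, 2))
        f_cand, dv_cand = boosted_pmf(cand[:, 0], cand[:, 1])
        log_p = -f_cand / kt - log_env
        keep = np.log(rng.random(m)) < log_p
        samples = np.vstack([samples, cand[keep]])
        dvs = np.concatenate([dvs, dv_cand[keep]])
    samples = samples[:n_frames]
    dvs = np.maximum(dvs[:n_frames], 0.0)
    boost = BoostSeries(delta_v=dvs, frame_index=np.arange(n_frames))
    return samples, boost


# ---------------------------------------------------------------------------
# All-atom structure fixtures
# ---------------------------------------------------------------------------


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray, r: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D from internal coordinates against anchor atoms A, B, C."""
    ang, dih = np.radians(angle_deg), np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [-r * np.cos(ang), r * np.sin(ang) * np.cos(dih), r * np.sin(ang) * np.sin(dih)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


_BB = {  # ideal backbone internal coordinates
    "n_ca": 1.458,
    "ca_c": 1.525,
    "c_n": 1.329,
    "c_o": 1.231,
    "ang_n_ca_c": 111.2,
    "ang_ca_c_n": 116.2,
    "ang_c_n_ca": 121.7,
    "ang_ca_c_o": 120.8,
}


def _build_chain(n_res: int, phi: float, psi: float, omega: float = 180.0) -> np.ndarray:
    """Poly-backbone (N, CA, C, O per residue) from constant (phi, psi)."""
    atoms = []  # flat list in N, CA, C order; O appended after
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([_BB["n_ca"], 0.0, 0.0])
    ang = np.radians(_BB["ang_n_ca_c"])
    c0 = ca0 + _BB["ca_c"] * np.array([np.cos(np.pi - ang), np.sin(np.pi - ang), 0.0])
    atoms.extend([n0, ca0, c0])
    for i in range(1, n_res):
        a_prev_n, a_prev_ca, a_prev_c = atoms[-3], atoms[-2], atoms[-1]
        n_i = _nerf(a_prev_n, a_prev_ca, a_prev_c, _BB["c_n"], _BB["ang_ca_c_n"], psi)
        ca_i = _nerf(a_prev_ca, a_prev_c, n_i, _BB["n_ca"], _BB["ang_c_n_ca"], omega)
        c_i = _nerf(a_prev_c, n_i, ca_i, _BB["ca_c"], _BB["ang_n_ca_c"], phi)
        atoms.extend([n_i, ca_i, c_i])
    coords = []
    for i in range(n_res):
        n_i, ca_i, c_i = atoms[3 * i], atoms[3 * i + 1], atoms[3 * i + 2]
        if i + 1 < n_res:
            n_next = atoms[3 * (i + 1)]
            # carbonyl O opposite the next N in the peptide plane
            d1 = (c_i - ca_i) / np.linalg.norm(c_i - ca_i)
            d2 = (c_i - n_next) / np.linalg.norm(c_i - n_next)
            o_dir = d1 + d2
            o_i = c_i + _BB["c_o"] * o_dir / np.linalg.norm(o_dir)
        else:
            o_i = _nerf(n_i, ca_i, c_i, _BB["c_o"], _BB["ang_ca_c_o"], -40.0)
        coords.extend([n_i, ca_i, c_i, o_i])
    return np.asarray(coords)


def _backbone_topology(n_res: int, chain: str = "A", start_resid: int = 1) -> Topology:
    names, resids, resnames, chains, elements = [], [], [], [], []
    for i in range(n_res):
        for nm, el in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            names.append(nm)
            resids.append(start_resid + i)
            resnames.append("ALA")
            chains.append(chain)
            elements.append(el)
    return Topology(
        atom_names=np.asarray(names, dtype=object),
        resids=np.asarray(resids, dtype=np.int64),
        resnames=np.asarray(resnames, dtype=object),
        chain_ids=np.asarray(chains, dtype=object),
        elements=np.asarray(elements, dtype=object),
    )


def ideal_helix(n_res: int = 14) -> tuple[Topology, np.ndarray]:
    """Ideal poly-alanine alpha-helix backbone (phi=-57, psi=-47)."""
    if n_res < 4:
        raise ValueError("helix fixture needs >= 4 residues")
    return _backbone_topology(n_res), _build_chain(n_res, phi=-57.0, psi=-47.0)


def antiparallel_sheet(n_res: int = 8, separation: float = 3.8, shift: float = 0.0) -> tuple[Topology, np.ndarray]:
    """Two antiparallel extended strands with an H-bonded register.

    The partner strand is the first one rotated 180 degrees about the
    in-plane axis perpendicular to the strand direction (reversing the chain
    direction while keeping the sheet plane) and displaced by ``separation``
    along that perpendicular; ``shift`` slides the register along the strand
    axis.  The defaults sit in the middle of the plateau where Kabsch-Sander
    assigns 'E' to every interior residue of both strands.
    """
    strand = _build_chain(n_res, phi=-180.0, psi=180.0)
    ca = strand.reshape(n_res, 4, 3)[:, 1]
    axis = ca[-1] - ca[0]
    axis /= np.linalg.norm(axis)
    perp = np.cross([0.0, 0.0, 1.0], axis)
    perp /= np.linalg.norm(perp)
    rot = 2.0 * np.outer(perp, perp) - np.eye(3)  # 180-degree rotation about perp
    center = strand.mean(axis=0)
    partner = (strand - center) @ rot.T + center + separation * perp + shift * axis
    coords = np.vstack([strand, partner])
    t1 = _backbone_topology(n_res, chain="A")
    t2 = _backbone_topology(n_res, chain="B")
    top = Topology(
        atom_names=np.concatenate([t1.atom_names, t2.atom_names]),
        resids=np.concatenate([t1.resids, t2.resids]),
        resnames=np.concatenate([t1.resnames, t2.resnames]),
        chain_ids=np.concatenate([t1.chain_ids, t2.chain_ids]),
        elements=np.concatenate([t1.elements, t2.elements]),
    )
    return top, coords


def hbond_triad(h_a_distance: float = 1.8, dha_angle: float = 180.0) -> tuple[Topology, np.ndarray]:
    """Donor N-H plus acceptor O at a parameterized H...A distance/angle."""
    n = np.array([0.0, 0.0, 0.0])
    h = np.array([1.0, 0.0, 0.0])
    ang = np.radians(dha_angle)
    to_d = (n - h) / np.linalg.norm(n - h)
    perp = np.array([0.0, 1.0, 0.0])
    a = h + h_a_distance * (np.cos(ang) * to_d + np.sin(ang) * perp)
    top = Topology(
        atom_names=np.asarray(["N", "H", "O"], dtype=object),
        resids=np.asarray([1, 1, 2], dtype=np.int64),
        resnames=np.asarray(["ASN", "ASN", "SER"], dtype=object),
        chain_ids=np.asarray(["A", "A", "A"], dtype=object),
        elements=np.asarray(["N", "H", "O"], dtype=object),
    )
    return top, np.stack([n, h, a])


def single_sphere() -> tuple[Topology, np.ndarray]:
    top = Topology(
        atom_names=np.asarray(["C1"], dtype=object),
        resids=np.asarray([1], dtype=np.int64),
        resnames=np.asarray(["SPH"], dtype=object),
        chain_ids=np.asarray(["A"], dtype=object),
        elements=np.asarray(["C"], dtype=object),
    )
    return top, np.zeros((1, 3))


def two_spheres(separation: float) -> tuple[Topology, np.ndarray]:
    top = Topology(
        atom_names=np.asarray(["C1", "C2"], dtype=object),
        resids=np.asarray([1, 2], dtype=np.int64),
        resnames=np.asarray(["SPH", "SPH"], dtype=object),
        chain_ids=np.asarray(["A", "A"], dtype=object),
        elements=np.asarray(["C", "C"], dtype=object),
    )
    return top, np.array([[0.0, 0.0, 0.0], [separation, 0.0, 0.0]])


def make_structure_fixtures() -> dict[str, tuple[Topology, np.ndarray]]:
    """Default fixture library for DSSP / H-bond / SASA operator tests."""
    return {
        "helix": ideal_helix(14),
        "sheet": antiparallel_sheet(8),
        "triad_ideal": hbond_triad(1.8, 180.0),
        "triad_bent": hbond_triad(1.8, 90.0),
        "sphere": single_sphere(),
        "two_spheres": two_spheres(2.0),
    }
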