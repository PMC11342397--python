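"""Dynamic cross-correlation of CA fluctuations and domain-block summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from mabdyn.core_io import AnnotatedSystem, TrajectorySlice

__all__ = ["CorrelationMap", "dccm", "domain_block_summary"]


@dataclass
class CorrelationMap:
    """Residue x residue normalized covariance of positional fluctuations.

    ``matrix`` entries lie in [-1, 1] with unit diagonal; rows of
    zero-variance residues are masked with NaN and listed in ``masked``.
    ``residue_labels`` holds (chain_id, resid) per row.
    """

    matrix: np.ndarray
    residue_labels: list[tuple[str, int]]
    masked: list[int]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{c}{r}" for c, r in self.residue_labels]
        df = pd.DataFrame(self.matrix, columns=cols)
        df.insert(0, "residue", cols)
        return df


def _superpose_all(xyz: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Least-squares fit every frame onto the reference coordinates."""
    out = np.empty_like(xyz)
    ref_c = ref - ref.mean(axis=0)
    for f in range(xyz.shape[0]):
        mob = xyz[f]
        mob_c = mob - mob.mean(axis=0)
        h = mob_c.T @ ref_c
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(u @ vt))
        rot = u @ np.diag([1.0, 1.0, d]) @ vt
        out[f] = mob_c @ rot + ref.mean(axis=0)
    return out


def dccm(
    traj: TrajectorySlice,
    selection: np.ndarray | None = None,
    superpose: bool = True,
    iterative_mean: bool = False,
) -> CorrelationMap:
    """Normalized covariance map C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>).

    Frames are superposed onto the first analyzed frame before fluctuations
    are computed (or onto an iteratively refined mean structure when
    ``iterative_mean`` is set).  The default selection is all CA atoms.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    top = traj.topology
    if selection is None:
        selection = np.flatnonzero(top.atom_names == "CA")
    selection = np.asarray(selection, dtype=np.intp)
    if selection.size == 0:
        raise ValueError("empty selection")
    xyz = traj.coordinates[:, selection, :].astype(np.float64)
    if superpose:
        xyz = _superpose_all(xyz, xyz[0])
        if iterative_mean:
            for _ in range(5):
                xyz = _superpose_all(xyz, xyz.mean(axis=0))
    mean = xyz.mean(axis=0)
    dr = xyz - mean
    cov = np.einsum("fik,fjk->ij", dr, dr) / traj.n_frames
    var = np.diag(cov).copy()
    masked = [int(i) for i in np.flatnonzero(var <= 1e-12)]
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = cov / denom
    corr = np.clip(corr, -1.0, 1.0)
    ok = var > 1e-12
    np.fill_diagonal(corr, np.where(ok, 1.0, np.nan))
    corr[~ok, :] = np.nan
    corr[:, ~ok] = np.nan
    labels = [
        (str(top.chain_ids[i]), int(top.resids[i])) for i in selection
    ]
    return CorrelationMap(matrix=corr, residue_labels=labels, masked=masked)


_HALF = {"LC1": 1, "HC1": 1, "LC2": 2, "HC2": 2}


def _residue_domain_labels(
    cmap: CorrelationMap, ann: AnnotatedSystem
) -> list[tuple[str, str] | None]:
    """(chain_label, domain) per map row; None for unlabeled residues."""
    id_to_label = {v: k for k, v in ann.chain_map.items()}
    out: list[tuple[str, str] | None] = []
    for chain_id, resid in cmap.residue_labels:
        label = id_to_label.get(chain_id)
        found = None
        if label is not None:
            for (clabel, domain), (lo, hi) in ann.domain_ranges.items():
                if clabel == label and lo <= resid <= hi:
                    found = (label, domain)
                    break
        out.append(found)
    return out


def domain_block_summary(
    cmap: CorrelationMap,
    ann: AnnotatedSystem,
    threshold: float = 0.5,
    require_labels: bool = True,
) -> pd.DataFrame:
    """Mean correlation per (domain_a, domain_b) block with classification.

    Blocks between chains of the same antibody half (LC1-HC1 or LC2-HC2)
    are tagged ``inter-chain``, blocks across halves ``inter-halves`` and
    same-chain blocks ``intra-chain``.  Blocks with mean correlation at or
    above ``threshold`` are flagged strong positive.
    """
    labels = _residue_domain_labels(cmap, ann)
    if require_labels and any(l is None for l in labels):
        missing = [cmap.residue_labels[i] for i, l in enumerate(labels) if l is None]
        raise ValueError(f"unlabeled residues in correlation map: {missing[:5]}...")
    groups: dict[tuple[str, str], list[int]] = {}
    for i, lab in enumerate(labels):
        if lab is not None:
            groups.setdefault(lab, []).append(i)
    keys = sorted(groups)
    rows = []
    for a_i, key_a in enumerate(keys):
        for key_b in keys[a_i:]:
            block = cmap.matrix[np.ix_(groups[key_a], groups[key_b])]
            if key_a == key_b:
                kind = "intra-domain"
            elif key_a[0] == key_b[0]:
                kind = "intra-chain"
            elif _HALF[key_a[0]] == _HALF[key_b[0]]:
                kind = "inter-chain"
            else:
                kind = "inter-halves"
            mean = float(np.nanmean(block))
            rows.append(
                {
                    "domain_a": f"{key_a[0]}:{key_a[1]}",
                    "domain_b": f"{key_b[0]}:{key_b[1]}",
                    "kind": kind,
                    "mean_correlation": mean,
                    "strong_positive": bool(mean >= threshold),
                }
            )
    return pd.DataFrame(rows)
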