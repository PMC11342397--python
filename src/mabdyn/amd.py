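"""Accelerated-MD parameter computation and ensemble reweighting.

The boosted ensemble is reweighted with a truncated Maclaurin expansion of
exp(beta*dV) (default order 10), binned on a 2-D grid over the two Fab
latitude angles, and converted to a potential of mean force
PMF = -kT ln p*, shifted so the occupied-bin minimum is 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np
import pandas as pd

from mabdyn.core_io import BoostSeries

KB = 0.0019872041  # kcal/mol/K

__all__ = [
    "AmdParameters",
    "FESGrid",
    "amd_parameters",
    "maclaurin_weights",
    "exact_weights",
    "cumulant_weights",
    "reweighted_fes",
    "minimum_energy_frames",
]


@dataclass(frozen=True)
class AmdParameters:
    """Dual-boost aMD thresholds and smoothing parameters (kcal/mol)."""

    ethresh_p: float
    alpha_p: float
    ethresh_d: float
    alpha_d: float
    coeffs: dict

    def __post_init__(self) -> None:
        if self.alpha_p <= 0 or self.alpha_d <= 0:
            raise ValueError("alpha parameters must be positive")


def amd_parameters(
    avg_eptot: float,
    avg_dihed: float,
    n_atoms: int,
    n_res: int,
    coeffs: dict | None = None,
) -> AmdParameters:
    """Standard dual-boost recipe from cMD averages.

    ethresh_p = <EPTOT> + c_p * n_atoms, alpha_p = c_p * n_atoms,
    ethresh_d = <DIHED> + c_d * n_res,  alpha_d = c_d * n_res / divisor,
    with defaults c_p = 0.2 kcal/mol/atom, c_d = 3.5 kcal/mol/residue,
    divisor = 5.  The coefficients are configurable.
    """
    if n_atoms <= 0 or n_res <= 0:
        raise ValueError("n_atoms and n_res must be positive")
    c = {"c_p": 0.2, "c_d": 3.5, "alpha_d_divisor": 5.0}
    if coeffs:
        c.update(coeffs)
    return AmdParameters(
        ethresh_p=avg_eptot + c["c_p"] * n_atoms,
        alpha_p=c["c_p"] * n_atoms,
        ethresh_d=avg_dihed + c["c_d"] * n_res,
        alpha_d=(c["c_d"] * n_res) / c["alpha_d_divisor"],
        coeffs=c,
    )


def _delta_v(boost: BoostSeries | np.ndarray) -> np.ndarray:
    if isinstance(boost, BoostSeries):
        return boost.delta_v
    return np.asarray(boost, dtype=np.float64)


def maclaurin_weights(boost: BoostSeries | np.ndarray, temperature: float = 300.0, order: int = 10) -> np.ndarray:
    """Per-frame weights sum_{k=0..order} (beta*dV)^k / k!.

    Truncated series for exp(beta*dV); order 0 gives unit weights.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    if order < 0:
        raise ValueError("order must be >= 0")
    x = _delta_v(boost) / (KB * temperature)
    w = np.ones_like(x)
    term = np.ones_like(x)
    for k in range(1, order + 1):
        term = term * x / k
        w = w + term
    return w


def exact_weights(boost: BoostSeries | np.ndarray, temperature: float = 300.0) -> np.ndarray:
    """exp(beta*dV) weights (reference mode; numerically noisy for large dV)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return np.exp(_delta_v(boost) / (KB * temperature))


def cumulant_weights(boost: BoostSeries | np.ndarray, temperature: float = 300.0) -> np.ndarray:
    """Second-order cumulant weights exp(beta<dV> + beta^2 var(dV)/2), uniform.

    This is the ensemble-level cumulant expansion; it returns one common
    scale factor per frame and is provided for validation only.
    """
    x = _delta_v(boost) / (KB * temperature)
    return np.full_like(x, np.exp(x.mean() + 0.5 * x.var()))


_WEIGHT_MODES = {
    "maclaurin": maclaurin_weights,
    "exact": exact_weights,
    "cumulant": cumulant_weights,
}


def boost_weights(boost, temperature: float = 300.0, mode: str = "maclaurin", order: int = 10) -> np.ndarray:
    if mode == "maclaurin":
        return maclaurin_weights(boost, temperature, order)
    try:
        return _WEIGHT_MODES[mode](boost, temperature)
    except KeyError:
        raise ValueError(f"unknown weighting mode {mode!r}") from None


@dataclass
class FESGrid:
    """2-D reweighted free-energy surface over (theta1, theta2)."""

    edges1: np.ndarray
    edges2: np.ndarray
    counts: np.ndarray
    probability: np.ndarray
    pmf: np.ndarray  # kcal/mol; NaN on masked (empty) bins
    mask: np.ndarray  # True where the bin is empty
    temperature: float

    @property
    def centers1(self) -> np.ndarray:
        return 0.5 * (self.edges1[:-1] + self.edges1[1:])

    @property
    def centers2(self) -> np.ndarray:
        return 0.5 * (self.edges2[:-1] + self.edges2[1:])

    def bin_of(self, theta1: np.ndarray, theta2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Bin indices of samples; the right-most edge is inclusive."""
        i = np.digitize(theta1, self.edges1) - 1
        j = np.digitize(theta2, self.edges2) - 1
        i = np.clip(i, 0, len(self.edges1) - 2)
        j = np.clip(j, 0, len(self.edges2) - 2)
        return i, j

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: theta1_bin, theta2_bin, centers, count, PMF."""
        i, j = np.meshgrid(np.arange(self.counts.shape[0]), np.arange(self.counts.shape[1]), indexing="ij")
        return pd.DataFrame(
            {
                "theta1_bin": i.ravel(),
                "theta2_bin": j.ravel(),
                "theta1_center": self.centers1[i.ravel()],
                "theta2_center": self.centers2[j.ravel()],
                "count": self.counts.ravel(),
                "probability": self.probability.ravel(),
                "pmf": self.pmf.ravel(),
            }
        )


def reweighted_fes(
    theta_samples: np.ndarray,
    weights: np.ndarray | None,
    bins: int | tuple[int, int] = 60,
    temperature: float = 300.0,
    angle_range: tuple[float, float] = (0.0, 180.0),
) -> FESGrid:
    """Weighted 2-D histogram of (theta1, theta2) converted to a PMF."""
    samples = np.asarray(theta_samples, dtype=np.float64)
    if samples.ndim != 2 or samples.shape[1] != 2:
        raise ValueError("theta_samples must have shape (n, 2)")
    if np.any(~np.isfinite(samples)):
        raise ValueError("theta_samples contain NaN/inf")
    if weights is None:
        weights = np.ones(len(samples))
    weights = np.asarray(weights, dtype=np.float64)
    if len(weights) != len(samples):
        raise ValueError("weights not aligned with samples")
    if not np.any(weights > 0):
        raise ValueError("all weights are zero")
    if isinstance(bins, int):
        bins = (bins, bins)
    if min(bins) < 2:
        raise ValueError("need at least 2 bins per axis")
    hist, e1, e2 = np.histogram2d(samples[:, 0], samples[:, 1], bins=bins, range=[angle_range, angle_range], weights=weights)
    counts, _, _ = np.histogram2d(samples[:, 0], samples[:, 1], bins=[e1, e2])
    mask = counts == 0
    prob = hist / hist.sum()
    pmf = np.full_like(prob, np.nan)
    occ = ~mask & (prob > 0)
    kt = KB * temperature
    pmf[occ] = -kt * np.log(prob[occ])
    pmf[occ] -= np.nanmin(pmf[occ])
    # occupied bins that received zero net weight sit at the top of the scale
    zero_w = ~mask & ~occ
    if np.any(zero_w):
        pmf[zero_w] = np.inf
    return FESGrid(edges1=e1, edges2=e2, counts=counts, probability=prob, pmf=pmf, mask=mask, temperature=temperature)


def minimum_energy_frames(
    fes: FESGrid, theta_samples: np.ndarray, pmf_threshold: float = 0.5
) -> np.ndarray:
    """Frame positions whose (theta1, theta2) bin has PMF below the threshold.

    Order-preserving; masked (empty) bins can never be selected.
    """
    if pmf_threshold <= 0:
        raise ValueError("pmf_threshold must be positive")
    samples = np.asarray(theta_samples, dtype=np.float64)
    i, j = fes.bin_of(samples[:, 0], samples[:, 1])
    below = np.zeros_like(fes.mask, dtype=bool)
    occ = ~fes.mask & np.isfinite(fes.pmf)
    below[occ] = fes.pmf[occ] < pmf_threshold
    return np.flatnonzero(below[i, j])
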