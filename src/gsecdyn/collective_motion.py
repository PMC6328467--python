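"""Principal component analysis of Cα coordinate covariance.

Frames are first superposed on a fit selection (removing global rigid
motion), then the 3M × 3M covariance matrix of the measure atoms' Cartesian
deviations from their mean is eigendecomposed.  No mass weighting (the
measure atoms are normally all Cα).  Covariance uses the unbiased (N−1)
normalization; eigenvector sign is canonicalized (largest-magnitude
component positive) so outputs are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import AtomSelection, TimeSeries, Trajectory
from .structural_metrics import align_trajectory


@dataclass
class PcaResult:
    """Eigenmodes of positional covariance, eigenvalues descending (Å²)."""

    mean_coords: np.ndarray     # (3M,)
    eigenvalues: np.ndarray     # (3M,) descending, >= 0
    eigenvectors: np.ndarray    # (3M, 3M), columns are modes
    atom_indices: np.ndarray    # measure atoms the modes refer to

    @property
    def n_modes(self) -> int:
        return len(self.eigenvalues)

    def variance_fraction(self, k: int) -> float:
        return variance_fraction(self, k)


def _canonical_signs(vectors: np.ndarray) -> np.ndarray:
    flips = np.sign(vectors[np.abs(vectors).argmax(axis=0), np.arange(vectors.shape[1])])
    flips[flips == 0] = 1.0
    return vectors * flips


def covariance_pca(
    traj: Trajectory,
    fit: AtomSelection,
    measure: AtomSelection,
    ddof: int = 1,
    already_aligned: bool = False,
) -> PcaResult:
    """PCA of the measure atoms' positional covariance after fitting on *fit*."""
    if traj.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    if len(measure) < 2:
        raise ValueError("PCA needs at least 2 measure atoms")
    aligned = traj if already_aligned else align_trajectory(traj, fit, 0)
    X = aligned.coordinates[:, measure.indices, :].reshape(traj.n_frames, -1).astype(float)
    mean = X.mean(axis=0)
    dev = X - mean
    cov = dev.T @ dev / (traj.n_frames - ddof)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = _canonical_signs(evecs[:, order])
    return PcaResult(
        mean_coords=mean, eigenvalues=evals, eigenvectors=evecs,
        atom_indices=measure.indices.copy(),
    )


def variance_fraction(result: PcaResult, k: int) -> float:
    """Cumulative fraction of total positional variance in the first k modes."""
    if not 1 <= k <= result.n_modes:
        raise ValueError(f"k must be in [1, {result.n_modes}]")
    total = result.eigenvalues.sum()
    if total == 0:
        raise ValueError("zero total variance")
    return float(result.eigenvalues[:k].sum() / total)


def project(
    traj: Trajectory,
    result: PcaResult,
    mode_index: int,
    fit: AtomSelection | None = None,
    already_aligned: bool = True,
) -> TimeSeries:
    """Per-frame scalar projection onto mode *mode_index* (0-based).

    The trajectory must be in the same aligned frame as the PCA input (pass
    *fit* with ``already_aligned=False`` to align here).  The projection
    variance of the PCA's own input equals the mode's eigenvalue.
    """
    if not 0 <= mode_index < result.n_modes:
        raise ValueError("mode index out of range")
    aligned = traj if already_aligned else align_trajectory(traj, fit, 0)
    X = aligned.coordinates[:, result.atom_indices, :].reshape(traj.n_frames, -1)
    proj = (X - result.mean_coords) @ result.eigenvectors[:, mode_index]
    return TimeSeries(values=proj, units="Å", label=f"PC{mode_index + 1}")


def mode_extremes(
    result: PcaResult, mode_index: int, amplitude: float = 2.0
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates displaced by ±amplitude·sqrt(λ_k) along mode k.

    Returns two (M, 3) coordinate arrays around the mean structure, suitable
    for export as a two-model PDB to visualize the motion.
    """
    if not 0 <= mode_index < result.n_modes:
        raise ValueError("mode index out of range")
    lam = result.eigenvalues[mode_index]
    if lam <= 1e-10:
        raise ValueError("zero-variance mode has no extremes")
    step = amplitude * np.sqrt(lam) * result.eigenvectors[:, mode_index]
    plus = (result.mean_coords + step).reshape(-1, 3)
    minus = (result.mean_coords - step).reshape(-1, 3)
    return plus, minus
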