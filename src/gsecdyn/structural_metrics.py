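"""Rigid-body superposition and positional-fluctuation statistics.

Superposition is least-squares (Kabsch); RMSD series, per-residue RMSD maps
(including the cross-trajectory noise-subtracted variant), crystallographic
B-factors and radii of gyration all operate on :class:`~gsecdyn.core_io.Trajectory`
objects after an explicit fit.

B-factor convention: ``B = (8*pi^2/3) * <|r - <r>|^2>`` over aligned frames,
so an isotropic Gaussian jitter of per-coordinate standard deviation sigma
gives ``B = 8*pi^2*sigma^2`` — the crystallographic convention, which matches
the Å² magnitudes quoted for immobilized lipid chains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .core_io import AtomSelection, MolecularSystem, TimeSeries, Trajectory

B_PREFACTOR = 8.0 * np.pi**2 / 3.0


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

@dataclass
class Transform:
    """Proper rigid motion ``x -> R x + t`` (rotation + translation, Å)."""

    rotation: np.ndarray    # (3, 3)
    translation: np.ndarray  # (3,)

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthogonal with determinant +1")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> tuple[Transform, float]:
    """Optimal weighted least-squares superposition of *mobile* onto *reference*.

    Returns the transform and the minimized RMSD (Å).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("mobile and reference must have equal shapes")
    if mobile.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")
    if weights is None:
        w = np.ones(mobile.shape[0])
    else:
        w = np.asarray(weights, dtype=float)
        if np.all(w == 0):
            raise ValueError("all-zero weights")
    wsum = w.sum()
    cm = (w[:, None] * mobile).sum(0) / wsum
    cr = (w[:, None] * reference).sum(0) / wsum
    rot, rssd = Rotation.align_vectors(reference - cr, mobile - cm, weights=w)
    R = rot.as_matrix()
    t = cr - R @ cm
    rmsd = float(rssd / np.sqrt(wsum))
    return Transform(rotation=R, translation=t), rmsd


def _resolve_reference(traj: Trajectory, reference) -> np.ndarray:
    if isinstance(reference, (int, np.integer)):
        return traj.coordinates[int(reference)]
    return np.asarray(reference, dtype=float)


def align_trajectory(
    traj: Trajectory,
    fit: AtomSelection,
    reference=0,
) -> Trajectory:
    """Superpose every frame's *fit* atoms onto the reference; move ALL atoms.

    *reference* is a frame index or a full-system coordinate array.  The box,
    if any, is carried over unchanged: periodic wrapping is no longer
    meaningful after rotation, so unwrap before aligning when that matters.
    """
    ref = _resolve_reference(traj, reference)
    ref_fit = ref[fit.indices]
    out = np.empty_like(traj.coordinates)
    for f in range(traj.n_frames):
        tr, _ = superpose(traj.coordinates[f][fit.indices], ref_fit)
        out[f] = tr.apply(traj.coordinates[f])
    return Trajectory(coordinates=out, frame_period=traj.frame_period, box=traj.box)


def rmsd_series(
    traj: Trajectory,
    fit: AtomSelection,
    measure: AtomSelection,
    reference=0,
    label: str = "RMSD",
) -> TimeSeries:
    """Per-frame RMSD of *measure* atoms after fitting each frame on *fit*."""
    ref = _resolve_reference(traj, reference)
    ref_fit = ref[fit.indices]
    ref_measure = ref[measure.indices]
    values = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        tr, _ = superpose(traj.coordinates[f][fit.indices], ref_fit)
        moved = tr.apply(traj.coordinates[f][measure.indices])
        values[f] = np.sqrt(np.mean(np.sum((moved - ref_measure) ** 2, axis=1)))
    return TimeSeries(values=values, units="Å", label=label)


# ---------------------------------------------------------------------------
# Per-residue RMSD maps
# ---------------------------------------------------------------------------

@dataclass
class ResidueRmsdMap:
    """Residue × frame RMSD matrix (Å). Missing residues are NaN, never 0."""

    residues: list[str]          # "SUBUNIT:resid" keys, ordered
    values: np.ndarray           # (R, F)
    reference_tag: str = ""

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def per_residue_rmsd(
    traj: Trajectory,
    system: MolecularSystem,
    reference: np.ndarray,
    fit: AtomSelection,
    residues: list[str] | None = None,
    atom_name: str = "CA",
    reference_tag: str = "",
) -> ResidueRmsdMap:
    """Per-residue RMSD vs *reference* after a global fit of each frame.

    Residues are ``"SUBUNIT:resid"`` keys; default is every protein residue
    that has an atom of *atom_name* (residues lacking it are flagged NaN).
    """
    keys = system.residue_keys()
    name_mask = system.atom_names.astype(str) == atom_name
    if residues is None:
        from .core_io import NON_PROTEIN_SUBUNITS
        prot = ~np.isin(system.subunit_of.astype(str), list(NON_PROTEIN_SUBUNITS))
        residues = list(dict.fromkeys(keys[prot]))
    ref = np.asarray(reference, dtype=float)
    ref_fit = ref[fit.indices]
    groups = [np.flatnonzero((keys == r) & name_mask) for r in residues]
    values = np.full((len(residues), traj.n_frames), np.nan)
    for f in range(traj.n_frames):
        tr, _ = superpose(traj.coordinates[f][fit.indices], ref_fit)
        moved = tr.apply(traj.coordinates[f])
        for ri, idx in enumerate(groups):
            if len(idx) == 0:
                continue
            d2 = np.sum((moved[idx] - ref[idx]) ** 2, axis=1)
            values[ri, f] = np.sqrt(np.mean(d2))
    return ResidueRmsdMap(residues=list(residues), values=values, reference_tag=reference_tag)


def rmsd_noise_subtract(self_map: ResidueRmsdMap, cross_map: ResidueRmsdMap) -> ResidueRmsdMap:
    """Entrywise ``|cross - self|``: deviations beyond a system's own noise."""
    if self_map.residues != cross_map.residues or self_map.values.shape != cross_map.values.shape:
        raise ValueError("maps must share residues and frame counts")
    return ResidueRmsdMap(
        residues=list(self_map.residues),
        values=np.abs(cross_map.values - self_map.values),
        reference_tag=f"|{cross_map.reference_tag} - {self_map.reference_tag}|",
    )


# ---------------------------------------------------------------------------
# B-factors and radius of gyration
# ---------------------------------------------------------------------------

@dataclass
class MobilityProfile:
    """B-factors (Å²) keyed by atom index, residue key or chain id."""

    keys: list
    bfactor: np.ndarray

    def as_dict(self) -> dict:
        return dict(zip(self.keys, self.bfactor))


def mean_structure(traj: Trajectory, fit: AtomSelection, reference=0) -> np.ndarray:
    """Arithmetic per-atom mean of frames aligned on *fit* to *reference*."""
    aligned = align_trajectory(traj, fit, reference)
    return aligned.coordinates.mean(axis=0)


def bfactors(
    traj: Trajectory,
    system: MolecularSystem,
    fit: AtomSelection,
    measure: AtomSelection,
    grouping: str = "atom",
    reference: str | int | np.ndarray = "mean",
) -> MobilityProfile:
    """Crystallographic B-factors of *measure* atoms on the fitted trajectory.

    ``reference="mean"`` aligns to the trajectory mean structure (two-pass,
    the convention for protein residues); an integer frame index or explicit
    coordinates align there instead (first frame is the lipid convention).
    Grouping: ``atom`` (per atom), ``residue`` (its CA atom's B) or
    ``chain``/``subunit`` (mean of member-atom B).
    """
    if traj.n_frames < 2:
        raise ValueError("B-factors need at least 2 frames")
    if isinstance(reference, str) and reference == "mean":
        ref = mean_structure(traj, fit, 0)
    else:
        ref = _resolve_reference(traj, reference)
    aligned = align_trajectory(traj, fit, ref)
    sub = aligned.coordinates[:, measure.indices, :]
    disp2 = np.sum((sub - sub.mean(axis=0)) ** 2, axis=2)  # (F, M)
    b_atom = B_PREFACTOR * disp2.mean(axis=0)

    if grouping == "atom":
        return MobilityProfile(keys=[int(i) for i in measure.indices], bfactor=b_atom)
    keys_all = system.residue_keys()
    if grouping == "residue":
        names = system.atom_names.astype(str)[measure.indices]
        rkeys = keys_all[measure.indices]
        out_keys, out_b = [], []
        for key in dict.fromkeys(rkeys):
            ca = np.flatnonzero((rkeys == key) & (names == "CA"))
            if len(ca) == 0:
                raise ValueError(f"residue {key} has no CA atom in the measure selection")
            out_keys.append(str(key))
            out_b.append(b_atom[ca[0]])
        return MobilityProfile(keys=out_keys, bfactor=np.asarray(out_b))
    if grouping in ("chain", "subunit"):
        labels = system.subunit_of.astype(str)[measure.indices]
        out_keys = list(dict.fromkeys(labels))
        out_b = [float(b_atom[labels == lab].mean()) for lab in out_keys]
        return MobilityProfile(keys=out_keys, bfactor=np.asarray(out_b))
    raise ValueError(f"unknown grouping {grouping!r}")


def radius_of_gyration(
    traj: Trajectory,
    measure: AtomSelection,
    masses: np.ndarray | None = None,
    label: str = "Rg",
) -> TimeSeries:
    """Per-frame radius of gyration of *measure* atoms.

    Unweighted by default (the Cα-only convention); pass *masses* for the
    mass-weighted variant.
    """
    if len(measure) < 2:
        raise ValueError("radius of gyration needs at least 2 atoms")
    sub = traj.coordinates[:, measure.indices, :].astype(float)
    if masses is None:
        w = np.ones(sub.shape[1])
    else:
        w = np.asarray(masses, dtype=float)[measure.indices] if len(masses) != sub.shape[1] \
            else np.asarray(masses, dtype=float)
    com = (w[None, :, None] * sub).sum(axis=1) / w.sum()
    d2 = np.sum((sub - com[:, None, :]) ** 2, axis=2)
    rg = np.sqrt((w[None, :] * d2).sum(axis=1) / w.sum())
    return TimeSeries(values=rg, units="Å", label=label)
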