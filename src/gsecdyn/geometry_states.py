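"""Tilt angles, inter-residue geometry and active-site state segmentation.

Implements the tilt-angle protocols (principal-axis helix tilt and
center-of-mass domain tilt against the membrane normal +z, after a common
fit), distance/angle time series with minimum-image treatment, the
single-changepoint inactive/active segmentation of a monitored distance
series, and frame classification by hydrogen-bond or water-bridge geometry.

The segmentation follows the convention used for catalytic-aspartate
distance series: the higher-mean segment is the *inactive* state (far
aspartates), the lower-mean segment *active*; a symmetric buffer around the
changepoint is excluded from per-state statistics, which are always computed
on the raw (un-averaged) series.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_io import AtomSelection, MolecularSystem, TimeSeries, Trajectory, running_average, select
from .structural_metrics import superpose

Z_AXIS = np.array([0.0, 0.0, 1.0])


# ---------------------------------------------------------------------------
# Axes and tilts
# ---------------------------------------------------------------------------

def helix_axis(coords: np.ndarray, orient: bool = True) -> np.ndarray:
    """Principal axis of a helix's Cα point cloud, oriented N→C.

    *coords* must be in N-terminal→C-terminal order; the axis is the
    largest-variance direction of the points (robust to end fraying).
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 4:
        raise ValueError("helix axis needs at least 4 Cα atoms")
    dev = coords - coords.mean(axis=0)
    if np.allclose(dev, 0):
        raise ValueError("degenerate (coincident) helix coordinates")
    _, _, vt = np.linalg.svd(dev, full_matrices=False)
    axis = vt[0]
    if orient and axis @ (coords[-1] - coords[0]) < 0:
        axis = -axis
    return axis / np.linalg.norm(axis)


def domain_axis_com(
    top: np.ndarray, bottom: np.ndarray, masses_top=None, masses_bottom=None
) -> np.ndarray:
    """Unit vector from the bottom-selection COM to the top-selection COM."""
    top = np.asarray(top, dtype=float)
    bottom = np.asarray(bottom, dtype=float)
    if top.size == 0 or bottom.size == 0:
        raise ValueError("empty selection for domain axis")
    wt = np.ones(len(top)) if masses_top is None else np.asarray(masses_top, float)
    wb = np.ones(len(bottom)) if masses_bottom is None else np.asarray(masses_bottom, float)
    com_t = (wt[:, None] * top).sum(0) / wt.sum()
    com_b = (wb[:, None] * bottom).sum(0) / wb.sum()
    v = com_t - com_b
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("coincident COMs")
    return v / n


def angle_to_z(axis: np.ndarray) -> float:
    """Angle (degrees, [0, 180)) between an oriented axis and +z."""
    c = np.clip(np.asarray(axis, float) @ Z_AXIS / np.linalg.norm(axis), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


@dataclass
class TiltResult:
    """Tilt angles vs +z per structure/frame and their ensemble spread."""

    angles: np.ndarray          # degrees; NaN where the helix was unresolved
    axis_definition: str        # "helix-principal-axis" | "com-top-bottom"
    ddof: int = 1

    @property
    def spread(self) -> float:
        """Sample standard deviation (degrees) over resolved entries."""
        ok = self.angles[np.isfinite(self.angles)]
        return float(np.std(ok, ddof=self.ddof))


def tilt_series(
    coords_ensemble: Trajectory | np.ndarray | list,
    fit: AtomSelection,
    helix: AtomSelection,
    axis_mode: str = "helix",
    top: AtomSelection | None = None,
    bottom: AtomSelection | None = None,
    reference: int | np.ndarray = 0,
    ddof: int = 1,
) -> TiltResult:
    """Tilt-vs-+z angles for each structure/frame after a common fit.

    Every structure (an ensemble list, a coordinate stack or a Trajectory)
    is superposed on *reference* using the *fit* atoms; the helix axis
    (``axis_mode="helix"``, principal axis of the *helix* Cα) or domain axis
    (``axis_mode="com"``, bottom→top COM vector) is then measured against
    the mutual +z axis.  Structures where the helix atoms are unresolved
    (non-finite) are flagged NaN and excluded from the spread.
    """
    if isinstance(coords_ensemble, Trajectory):
        stack = coords_ensemble.coordinates
    else:
        stack = np.asarray(coords_ensemble, dtype=float)
        if stack.ndim == 2:
            stack = stack[None]
    ref = stack[reference] if isinstance(reference, (int, np.integer)) else np.asarray(reference)
    ref_fit = ref[fit.indices]
    angles = np.full(stack.shape[0], np.nan)
    for i, frame in enumerate(stack):
        tr, _ = superpose(frame[fit.indices], ref_fit)
        moved = tr.apply(frame)
        if axis_mode == "helix":
            pts = moved[helix.indices]
            if not np.all(np.isfinite(pts)):
                continue
            axis = helix_axis(pts)
        elif axis_mode == "com":
            if top is None or bottom is None:
                raise ValueError("com axis mode needs top and bottom selections")
            axis = domain_axis_com(moved[top.indices], moved[bottom.indices])
        else:
            raise ValueError(f"unknown axis_mode {axis_mode!r}")
        angles[i] = angle_to_z(axis)
    definition = "helix-principal-axis" if axis_mode == "helix" else "com-top-bottom"
    return TiltResult(angles=angles, axis_definition=definition, ddof=ddof)


def ensemble_tilt_from_structures(
    structures: list[tuple[MolecularSystem, np.ndarray]],
    fit_expression: str,
    helix_expression: str | None = None,
    axis_mode: str = "helix",
    top_expression: str | None = None,
    bottom_expression: str | None = None,
    ddof: int = 1,
) -> TiltResult:
    """Tilt spread over independently loaded structures (e.g. a Cryo-EM
    ensemble of the same complex with different resolved residues).

    Fit and helix atoms are matched across structures by their
    (subunit, residue id, atom name) key; only residues resolved in every
    member enter the fit, so ensembles with differing coverage remain
    comparable.  The first structure is the alignment reference.
    """
    def keyed(system, expr):
        sel = select(system, expr)
        return {
            (str(system.subunit_of[i]), int(system.residue_ids[i]),
             str(system.atom_names[i])): int(i)
            for i in sel.indices
        }

    fit_maps = [keyed(s, fit_expression) for s, _ in structures]
    common_fit = sorted(set.intersection(*(set(m) for m in fit_maps)))
    if len(common_fit) < 3:
        raise ValueError("fewer than 3 common fit atoms across the ensemble")
    ref_system, ref_coords = structures[0]
    ref_fit = ref_coords[[fit_maps[0][k] for k in common_fit]]
    angles = np.full(len(structures), np.nan)
    for i, (system, coords) in enumerate(structures):
        fit_idx = [fit_maps[i][k] for k in common_fit]
        tr, _ = superpose(coords[fit_idx], ref_fit)
        moved = tr.apply(coords)
        if axis_mode == "helix":
            hsel = select(system, helix_expression)
            pts = moved[hsel.indices]
            if len(hsel) < 4 or not np.all(np.isfinite(pts)):
                continue
            axis = helix_axis(pts)
        else:
            tsel = select(system, top_expression)
            bsel = select(system, bottom_expression)
            axis = domain_axis_com(moved[tsel.indices], moved[bsel.indices])
        angles[i] = angle_to_z(axis)
    definition = "helix-principal-axis" if axis_mode == "helix" else "com-top-bottom"
    return TiltResult(angles=angles, axis_definition=definition, ddof=ddof)


# ---------------------------------------------------------------------------
# Distances and angles
# ---------------------------------------------------------------------------

def residue_site(
    system: MolecularSystem, subunit: str, resid: int, site: str = "CA"
) -> AtomSelection:
    """Selection for a residue's measurement site: one atom name, or COM
    of heavy side-chain atoms (``site="sidechain"``) / all heavy atoms
    (``site="COM"``)."""
    base = f"{subunit} and resid {resid}"
    if site == "COM":
        sel = select(system, base)
        heavy = sel.indices[system.elements.astype(str)[sel.indices] != "H"]
        return AtomSelection(indices=heavy, expression=f"{base} (heavy)")
    if site == "sidechain":
        sel = select(system, base)
        names = system.atom_names.astype(str)[sel.indices]
        elements = system.elements.astype(str)[sel.indices]
        keep = (~np.isin(names, ["CA", "C", "N", "O"])) & (elements != "H")
        return AtomSelection(indices=sel.indices[keep], expression=f"{base} (sidechain heavy)")
    sel = select(system, f"{base} and name {site}")
    if len(sel) == 0:
        raise KeyError(f"site {site!r} unresolvable for {subunit}:{resid}")
    return sel


def _site_positions(traj: Trajectory, sel: AtomSelection) -> np.ndarray:
    """(F, 3) position of a site: the atom if single, else the centroid."""
    if len(sel) == 0:
        raise ValueError("unresolvable (empty) site selection")
    sub = traj.coordinates[:, sel.indices, :]
    return sub[:, 0, :].astype(float) if len(sel) == 1 else sub.mean(axis=1).astype(float)


def minimum_image(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors."""
    if box is None:
        return delta
    return delta - box * np.round(delta / box)


def distance_series(
    traj: Trajectory,
    a: AtomSelection,
    b: AtomSelection,
    label: str = "distance",
) -> TimeSeries:
    """Per-frame Euclidean distance (Å) between two sites, minimum-image
    when the trajectory has a periodic box."""
    d = _site_positions(traj, a) - _site_positions(traj, b)
    d = minimum_image(d, traj.box)
    return TimeSeries(values=np.linalg.norm(d, axis=1), units="Å", label=label)


def angle_series(
    traj: Trajectory,
    a: AtomSelection,
    b: AtomSelection,
    c: AtomSelection,
    label: str = "angle",
) -> TimeSeries:
    """Per-frame angle (degrees, [0, 180]) at vertex *b*."""
    pa, pb, pc = (_site_positions(traj, s) for s in (a, b, c))
    v1 = minimum_image(pa - pb, traj.box)
    v2 = minimum_image(pc - pb, traj.box)
    n1 = np.linalg.norm(v1, axis=1)
    n2 = np.linalg.norm(v2, axis=1)
    if np.any(n1 == 0) or np.any(n2 == 0):
        raise ValueError("degenerate (coincident) points in angle computation")
    cosang = np.clip(np.sum(v1 * v2, axis=1) / (n1 * n2), -1.0, 1.0)
    return TimeSeries(values=np.degrees(np.arccos(cosang)), units="degrees", label=label)


# ---------------------------------------------------------------------------
# State segmentation
# ---------------------------------------------------------------------------

def _series_stats(x: np.ndarray) -> dict[str, float]:
    return {
        "mean": float(np.mean(x)), "std": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0,
        "min": float(np.min(x)), "max": float(np.max(x)), "n": int(len(x)),
    }


@dataclass
class StateSegmentation:
    """Per-frame inactive/active/buffer labels with per-state statistics."""

    labels: np.ndarray                       # (F,) of {"inactive","active","buffer"}
    transition_frame: int | None
    per_state: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    orientation_rule: str = "higher mean = inactive (distance-type series)"

    def frames_of(self, state: str) -> np.ndarray:
        return np.flatnonzero(self.labels == state)

    def stats_for(self, series: TimeSeries) -> dict[str, dict[str, float]]:
        """Per-state stats of a companion series on the raw values."""
        out = {}
        for state in ("inactive", "active"):
            idx = self.frames_of(state)
            if len(idx):
                out[state] = _series_stats(series.values[idx])
        self.per_state[series.label or "series"] = out
        return out


def least_squares_changepoint(values: np.ndarray) -> int:
    """Exact single changepoint minimizing total within-segment squared
    deviation; returns the first index of the second segment."""
    y = np.asarray(values, dtype=float)
    n = len(y)
    s1 = np.cumsum(y)
    s2 = np.cumsum(y * y)
    k = np.arange(1, n)              # left segment = y[:k]
    left = s2[k - 1] - s1[k - 1] ** 2 / k
    rs1 = s1[-1] - s1[k - 1]
    rs2 = s2[-1] - s2[k - 1]
    right = rs2 - rs1 ** 2 / (n - k)
    return int(k[np.argmin(left + right)])


def segment_states(
    series: TimeSeries,
    buffer: int = 50,
    window: int = 100,
    higher_mean_label: str = "inactive",
) -> StateSegmentation:
    """Two-state segmentation of a monitored series.

    The changepoint is the least-squares split of the running-averaged
    series; for aspartate-distance series the higher-mean segment is labeled
    inactive.  ``buffer`` frames on each side of the changepoint are labeled
    ``buffer`` and excluded from per-state statistics, which are computed on
    the raw series.
    """
    y = series.values
    n = len(y)
    if n < 2 * buffer + 2:
        raise ValueError("series too short for the requested buffer")
    labels = np.empty(n, dtype=object)
    if np.ptp(y) == 0:
        labels[:] = higher_mean_label
        seg = StateSegmentation(labels=labels, transition_frame=None)
        seg.per_state[series.label or "series"] = {higher_mean_label: _series_stats(y)}
        return seg
    smooth = running_average(series, min(window, n)).values
    cp = least_squares_changepoint(smooth)
    lower_label = "active" if higher_mean_label == "inactive" else "inactive"
    first, second = (higher_mean_label, lower_label) if y[:cp].mean() >= y[cp:].mean() \
        else (lower_label, higher_mean_label)
    labels[:cp] = first
    labels[cp:] = second
    lo, hi = max(0, cp - buffer), min(n, cp + buffer)
    labels[lo:hi] = "buffer"
    seg = StateSegmentation(labels=labels, transition_frame=cp)
    seg.stats_for(series)
    return seg


# ---------------------------------------------------------------------------
# Hydrogen bonds and water bridges
# ---------------------------------------------------------------------------

@dataclass
class BondedFrameStats:
    """Fraction of frames satisfying a geometric criterion, with companion-
    series statistics conditioned on those frames."""

    fraction: float
    mask: np.ndarray                     # over the evaluated frame subset
    frames: np.ndarray                   # absolute frame indices evaluated
    companion_mean: float | None = None
    companion_std: float | None = None


def _min_cross_distance(traj: Trajectory, a: AtomSelection, b: AtomSelection) -> np.ndarray:
    """(F,) minimum distance between any atom of *a* and any of *b*."""
    pa = traj.coordinates[:, a.indices, :].astype(float)
    pb = traj.coordinates[:, b.indices, :].astype(float)
    diff = pa[:, :, None, :] - pb[:, None, :, :]
    if traj.box is not None:
        diff = diff - traj.box[:, None, None, :] * np.round(diff / traj.box[:, None, None, :])
    return np.sqrt(np.min(np.sum(diff**2, axis=3), axis=(1, 2)))


def _finalize(mask: np.ndarray, frames: np.ndarray, companion: TimeSeries | None) -> BondedFrameStats:
    stats = BondedFrameStats(fraction=float(mask.mean()), mask=mask, frames=frames)
    if companion is not None and mask.any():
        vals = companion.values[frames][mask]
        stats.companion_mean = float(vals.mean())
        stats.companion_std = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return stats


def hbond_fraction(
    traj: Trajectory,
    donor: AtomSelection,
    acceptor: AtomSelection,
    hydrogens: AtomSelection | None = None,
    dist_cutoff: float = 3.5,
    angle_min: float = 120.0,
    frames: np.ndarray | None = None,
    companion: TimeSeries | None = None,
) -> BondedFrameStats:
    """Classify frames as hydrogen-bonded on heavy-atom geometry.

    A frame is bonded when the closest donor-heavy/acceptor-heavy pair is
    within *dist_cutoff* Å and, if hydrogens are supplied, some D–H···A
    angle is at least *angle_min* degrees.  Returns the bonded fraction over
    the evaluated frames plus companion-series stats on bonded frames.
    """
    idx = np.arange(traj.n_frames) if frames is None else np.asarray(frames, int)
    if len(idx) == 0:
        raise ValueError("no frames in subset")
    sub = Trajectory(traj.coordinates[idx], traj.frame_period,
                     None if traj.box is None else traj.box[idx])
    bonded = _min_cross_distance(sub, donor, acceptor) <= dist_cutoff
    if hydrogens is not None and len(hydrogens) and bonded.any():
        ph = sub.coordinates[:, hydrogens.indices, :]
        pd = sub.coordinates[:, donor.indices, :].mean(axis=1)
        pa = sub.coordinates[:, acceptor.indices, :].mean(axis=1)
        v1 = pd[:, None, :] - ph
        v2 = pa[:, None, :] - ph
        cosang = np.sum(v1 * v2, axis=2) / (
            np.linalg.norm(v1, axis=2) * np.linalg.norm(v2, axis=2))
        best = np.degrees(np.arccos(np.clip(cosang, -1, 1))).max(axis=1)
        bonded &= best >= angle_min
    return _finalize(bonded, idx, companion)


def water_bridge_stats(
    traj: Trajectory,
    oxygens_a: AtomSelection,
    oxygens_b: AtomSelection,
    waters: AtomSelection,
    cutoff: float = 3.5,
    frames: np.ndarray | None = None,
    companion: TimeSeries | None = None,
) -> BondedFrameStats:
    """Classify frames as water-bridged between two carboxylate groups.

    A frame is bridged when at least one water oxygen lies within *cutoff*
    of ≥1 oxygen of EACH group simultaneously.
    """
    if len(waters) == 0:
        raise ValueError("empty water selection")
    idx = np.arange(traj.n_frames) if frames is None else np.asarray(frames, int)
    if len(idx) == 0:
        raise ValueError("no frames in subset")
    bridged = np.zeros(len(idx), dtype=bool)
    for i, f in enumerate(idx):
        w = traj.coordinates[f, waters.indices, :].astype(float)
        da = np.linalg.norm(
            w[:, None, :] - traj.coordinates[f, oxygens_a.indices, :], axis=2).min(axis=1)
        db = np.linalg.norm(
            w[:, None, :] - traj.coordinates[f, oxygens_b.indices, :], axis=2).min(axis=1)
        bridged[i] = bool(np.any((da <= cutoff) & (db <= cutoff)))
    return _finalize(bridged, idx, companion)
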