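"""Synthetic membrane-protein systems and trajectories with planted truth.

No trajectory data accompany the study this package re-implements, so every
analysis stage is validated against synthetic stand-ins whose statistical
structure is known exactly: harmonic positional fluctuations with prescribed
per-residue amplitudes, planted low-rank collective modes, a two-state
catalytic-aspartate distance process, helix tilt wobble, a two-regime
interior hydration field against uniform bulk slabs, and lipids that are
either freely diffusing or harmonically trapped at named protein segments.

The default parameters ARE the study conditions: inactive/active Cα–Cα
distances 9.1±0.6 / 8.3±0.6 Å, Cγ–Cγ 8.0±0.7 / 6.0±1.0 Å (the active state
being a 26%/74% mixture of directly hydrogen-bonded frames at 7.5±0.3 Å and
water-bridged frames at 8.6±0.4 Å — a mixture that reproduces the quoted
active-state moments), a transition at frame 1750 of 3500, binding-region
water counts 34.8 with σ 4.4→3.0, dual-proximity water means 1.0→2.6, and
tilt wobble of a few degrees.  Dynamics are sampled fluctuations, not
integrated physics: the analyses assume only distributional structure, so a
statistical generator is the honest desk-scale stand-in.

Everything is deterministic per seed (single RNG stream per trajectory).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core_io import MolecularSystem, Trajectory

RISE_PER_RESIDUE = 1.5     # Å, ideal alpha helix
TWIST_PER_RESIDUE = 100.0  # degrees
CA_RADIUS = 2.3            # Å from helix axis
CB_RADIUS = 3.4


# ---------------------------------------------------------------------------
# Specification
# ---------------------------------------------------------------------------

@dataclass
class SubunitSpec:
    label: str
    segment_names: list[str]
    resid_starts: list[int]
    center_xy: tuple[float, float]
    ring_radius: float
    residues_per_helix: int = 20


@dataclass
class TransitionSpec:
    """Two-state catalytic-distance process with helix repositioning."""

    frame: int = 1750
    ca_inactive: tuple[float, float] = (9.1, 0.6)
    hbond_fraction_active: float = 0.26
    ca_hbond: tuple[float, float] = (7.5, 0.3)
    ca_bridged: tuple[float, float] = (8.6, 0.4)
    cg_inactive: tuple[float, float] = (8.0, 0.7)
    cg_hbond: tuple[float, float] = (4.6, 0.3)
    cg_bridged: tuple[float, float] = (6.5, 0.5)
    # inward shift magnitude (Å) applied to whole segments in the active state
    shifts: dict[str, float] = field(default_factory=lambda: {
        "PS1-TMD6": 1.0, "PS1-TMD7": 0.6, "PS1-TMD1": 0.4,
    })

    @property
    def ca_active_mean(self) -> float:
        p = self.hbond_fraction_active
        return p * self.ca_hbond[0] + (1 - p) * self.ca_bridged[0]

    @property
    def cg_active_mean(self) -> float:
        p = self.hbond_fraction_active
        return p * self.cg_hbond[0] + (1 - p) * self.cg_bridged[0]


@dataclass
class TiltWobbleSpec:
    segment: str = "PEN2-H3"
    mean_deg: float = 15.0
    sigma_deg: float = 2.0


@dataclass
class SolventSpec:
    """Bulk slabs plus planted interior count distributions."""

    bulk_density: float = 0.0045          # waters / Å³ (desk scale)
    slab_z: tuple[float, float] = (25.0, 40.0)   # mirrored below the membrane
    slab_xy_halfwidth: float = 40.0
    binding_counts: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "inactive": (34.8, 4.4), "active": (34.8, 3.0)})
    upper_counts: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        "inactive": (88.4, 8.0), "active": (88.4, 8.0)})
    dual_water_mean: dict[str, float] = field(default_factory=lambda: {
        "inactive": 1.0, "active": 2.6})
    dual_cutoff: float = 4.0


@dataclass
class LipidSpec:
    n_trapped: int = 10
    n_diffusive: int = 290
    tether_sigma: float = 0.8     # Å, per-frame xy fluctuation about the site
    step_length: float = 1.0      # Å per frame for diffusive walkers
    n_beads: int = 6
    box_xy: float = 130.0
    # trap sites: pairs of adjacent PS1 TMD indices (1-based)
    trap_pairs: list[tuple[int, int]] = field(default_factory=lambda: [
        (1, 2), (2, 3), (4, 5), (6, 7), (8, 9)])


@dataclass
class SyntheticSpec:
    n_frames: int = 3500
    frame_period: float = 1.0
    jitter_sigma: float = 0.4                      # Å per coordinate, default
    sigma_by_segment: dict[str, float] = field(default_factory=dict)
    mode_variances: tuple[float, ...] = ()         # Å², planted collective modes
    mode_support: str = "all"                      # "all" | "CA": atoms the modes move
    transition: TransitionSpec | None = field(default_factory=TransitionSpec)
    tilt_wobble: TiltWobbleSpec | None = field(default_factory=TiltWobbleSpec)
    tumble_sigma_deg: float = 0.0                  # optional global rigid wobble
    solvent: SolventSpec | None = field(default_factory=SolventSpec)
    lipids: LipidSpec | None = field(default_factory=LipidSpec)
    subunits: list[SubunitSpec] = field(default_factory=lambda: default_subunits())
    catalytic: tuple[tuple[str, int], tuple[str, int]] = (("PS1", 257), ("PS1", 385))

    def __post_init__(self) -> None:
        if self.jitter_sigma <= 0 or any(s <= 0 for s in self.sigma_by_segment.values()):
            raise ValueError("all jitter sigmas must be positive")
        if self.transition is not None and not 0 < self.transition.frame < self.n_frames:
            raise ValueError("transition frame must lie inside the trajectory")


def default_subunits() -> list[SubunitSpec]:
    """A nine-helix catalytic bundle with PEN-2- and APH-1a-like neighbours.

    PS1 helix numbering is chosen so the catalytic residues carry their
    canonical ids (257 on TMD6, 385 on TMD7)."""
    return [
        SubunitSpec("PS1", [f"PS1-TMD{i}" for i in range(1, 10)],
                    [82, 133, 164, 195, 221, 248, 377, 407, 433],
                    center_xy=(0.0, 0.0), ring_radius=11.0),
        SubunitSpec("PEN2", [f"PEN2-H{i}" for i in range(1, 4)],
                    [17, 41, 63], center_xy=(25.0, 0.0), ring_radius=5.0),
        SubunitSpec("APH1", [f"APH1-TMD{i}" for i in range(1, 8)],
                    [10, 40, 70, 100, 130, 160, 190],
                    center_xy=(-27.0, 0.0), ring_radius=9.0),
    ]


@dataclass
class GroundTruth:
    """Planted parameter values keyed to match each analysis output."""

    seed: int
    planted: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))
        Path(path).write_text(json.dumps(
            {"seed": self.seed, "planted": self.planted}, indent=2, default=default))


# ---------------------------------------------------------------------------
# Bundle construction
# ---------------------------------------------------------------------------

def _ideal_helix(n_res: int, axis_xy: tuple[float, float], phase: float = 0.0):
    """CA and CB coordinates of an ideal helix along +z, centred at z=0."""
    t = np.arange(n_res)
    ang = np.radians(phase + TWIST_PER_RESIDUE * t)
    z = RISE_PER_RESIDUE * (t - (n_res - 1) / 2.0)
    ca = np.column_stack([axis_xy[0] + CA_RADIUS * np.cos(ang),
                          axis_xy[1] + CA_RADIUS * np.sin(ang), z])
    cb = np.column_stack([axis_xy[0] + CB_RADIUS * np.cos(ang),
                          axis_xy[1] + CB_RADIUS * np.sin(ang), z])
    return ca, cb


def build_bundle(spec: SyntheticSpec) -> tuple[MolecularSystem, np.ndarray]:
    """Ideal α-helix bundle with Cα/Cβ pseudo-atoms and carboxyl-bearing
    catalytic residues; emits segment definitions.

    Helices are placed on a circle per subunit; raises if helix axes come
    closer than a 5 Å packing bound (geometrically impossible spec).
    """
    catalytic = set(spec.catalytic)
    ids, names, elements, masses = [], [], [], []
    resids, resnames, subunit_of = [], [], []
    coords = []
    segments: dict[str, tuple[str, list[tuple[int, int]]]] = {}
    axis_positions = []
    aid = 0
    for sub in spec.subunits:
        n_hel = len(sub.segment_names)
        for h, (seg, start) in enumerate(zip(sub.segment_names, sub.resid_starts)):
            theta = 2 * np.pi * h / n_hel
            axy = (sub.center_xy[0] + sub.ring_radius * np.cos(theta),
                   sub.center_xy[1] + sub.ring_radius * np.sin(theta))
            axis_positions.append(axy)
            ca, cb = _ideal_helix(sub.residues_per_helix, axy, phase=np.degrees(theta))
            segments[seg] = (sub.label, [(start, start + sub.residues_per_helix - 1)])
            for r in range(sub.residues_per_helix):
                resid = start + r
                is_cat = (sub.label, resid) in catalytic
                resname = "ASP" if is_cat else "ALA"
                atom_list = [("CA", "C", 12.011, ca[r]), ("CB", "C", 12.011, cb[r])]
                if is_cat:
                    out = cb[r] - ca[r]
                    out[2] = 0.0
                    out /= np.linalg.norm(out)
                    cg = cb[r] + 1.3 * out
                    atom_list += [("CG", "C", 12.011, cg),
                                  ("OD1", "O", 15.999, cg + [0.0, 0.0, 1.0]),
                                  ("OD2", "O", 15.999, cg + [0.0, 0.0, -1.0])]
                for nm, el, m, xyz in atom_list:
                    ids.append(aid); aid += 1
                    names.append(nm); elements.append(el); masses.append(m)
                    resids.append(resid); resnames.append(resname)
                    subunit_of.append(sub.label)
                    coords.append(np.asarray(xyz, dtype=float))
    axis_positions = np.asarray(axis_positions)
    d = np.linalg.norm(axis_positions[:, None] - axis_positions[None, :], axis=2)
    np.fill_diagonal(d, np.inf)
    if d.min() < 5.0:
        raise ValueError(f"helix axes too close ({d.min():.1f} Å): overlapping helices")
    system = MolecularSystem(
        atom_ids=np.array(ids), atom_names=np.array(names, dtype=object),
        elements=np.array(elements, dtype=object), masses=np.array(masses),
        residue_ids=np.array(resids), residue_names=np.array(resnames, dtype=object),
        subunit_of=np.array(subunit_of, dtype=object),
    )
    system = system.with_segments(segments)
    return system, np.asarray(coords)


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

def _segment_atom_indices(system: MolecularSystem, segment: str) -> np.ndarray:
    subunit, ranges = system.segments[segment]
    mask = system.subunit_of.astype(str) == subunit
    rmask = np.zeros(system.n_atoms, dtype=bool)
    for a, b in ranges:
        rmask |= (system.residue_ids >= a) & (system.residue_ids <= b)
    return np.flatnonzero(mask & rmask)


def _atom_index(system: MolecularSystem, subunit: str, resid: int, name: str) -> int:
    hit = np.flatnonzero(
        (system.subunit_of.astype(str) == subunit)
        & (system.residue_ids == resid)
        & (system.atom_names.astype(str) == name))
    if len(hit) != 1:
        raise KeyError(f"{subunit}:{resid}:{name} not uniquely resolvable")
    return int(hit[0])


def _rigid_body_basis(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis (3N × 6) of rigid translations and infinitesimal
    rotations about the centroid of *coords*."""
    n = len(coords)
    cen = coords - coords.mean(axis=0)
    vecs = []
    for ax in range(3):
        v = np.zeros((n, 3))
        v[:, ax] = 1.0
        vecs.append(v.ravel())
    for ax in range(3):
        e = np.zeros(3)
        e[ax] = 1.0
        vecs.append(np.cross(cen, e).ravel())
    q, _ = np.linalg.qr(np.array(vecs).T)
    return q


def make_random_modes(
    ref_coords: np.ndarray,
    variances,
    rng: np.random.Generator,
    support: np.ndarray | None = None,
) -> list[tuple[np.ndarray, float]]:
    """Orthonormal random 3N mode vectors with prescribed variances (Å²).

    With *support* (atom indices), modes move only those atoms — useful when
    the analysis measures a subset (e.g. Cα) and the planted variance should
    be fully visible to it.  Rigid-body components are projected out so the
    planted motion is entirely internal: an alignment-based analysis can
    only ever observe the quotient of a mode by rigid motion."""
    n_atoms = len(ref_coords)
    dim = 3 * n_atoms
    sup = np.arange(n_atoms) if support is None else np.asarray(support)
    rows = (3 * sup[:, None] + np.arange(3)).ravel()
    raw = rng.standard_normal((len(rows), len(variances)))
    rigid = _rigid_body_basis(ref_coords[sup])
    raw -= rigid @ (rigid.T @ raw)
    q, _ = np.linalg.qr(raw)
    out = []
    for k, v in enumerate(variances):
        vec = np.zeros(dim)
        vec[rows] = q[:, k]
        out.append((vec, float(v)))
    return out


def _draw_two_state_series(
    n_frames: int, t_frame: int, tr: TransitionSpec, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(d_ca, d_cg, hbond_flag) per frame for the catalytic pair."""
    d_ca = np.empty(n_frames)
    d_cg = np.empty(n_frames)
    hbond = np.zeros(n_frames, dtype=bool)
    pre = slice(0, t_frame)
    post = slice(t_frame, n_frames)
    d_ca[pre] = rng.normal(*tr.ca_inactive, t_frame)
    d_cg[pre] = rng.normal(*tr.cg_inactive, t_frame)
    n_post = n_frames - t_frame
    hb = rng.random(n_post) < tr.hbond_fraction_active
    hbond[post] = hb
    d_ca[post] = np.where(hb, rng.normal(*tr.ca_hbond, n_post),
                          rng.normal(*tr.ca_bridged, n_post))
    d_cg[post] = np.where(hb, rng.normal(*tr.cg_hbond, n_post),
                          rng.normal(*tr.cg_bridged, n_post))
    np.clip(d_ca, 3.0, None, out=d_ca)
    # upper clip keeps the carboxyl gap within dual-proximity reach of a
    # single water (4 Å of both sides); trims <2% of the inactive tail
    np.clip(d_cg, 2.0, 9.4, out=d_cg)
    return d_ca, d_cg, hbond


def simulate_dynamics(
    system: MolecularSystem,
    ref_coords: np.ndarray,
    spec: SyntheticSpec,
    seed: int,
) -> tuple[Trajectory, GroundTruth]:
    """Sampled-fluctuation protein trajectory with planted ground truth.

    Frames are the reference plus planted collective-mode displacements,
    per-residue Gaussian jitter, the two-state repositioning of designated
    helices, the catalytic-pair distance process, tilt wobble of one helix,
    and (optionally) a global rigid tumble that analyses must remove.
    """
    rng = np.random.default_rng(seed)
    n = system.n_atoms
    F = spec.n_frames
    truth = GroundTruth(seed=seed)

    # per-atom jitter sigma (Å per coordinate)
    sigma = np.full(n, spec.jitter_sigma)
    for seg, s in spec.sigma_by_segment.items():
        sigma[_segment_atom_indices(system, seg)] = s
    truth.planted["bfactor_by_atom"] = 8 * np.pi**2 * sigma**2
    truth.planted["sigma_by_atom"] = sigma.copy()

    support = None
    if spec.mode_support == "CA":
        support = np.flatnonzero(system.atom_names.astype(str) == "CA")
    modes = make_random_modes(ref_coords, spec.mode_variances, rng, support) \
        if spec.mode_variances else []
    if modes:
        truth.planted["mode_vectors"] = np.stack([m[0] for m in modes])
        truth.planted["mode_variances"] = [m[1] for m in modes]

    # state shifts
    shift_vectors: dict[str, np.ndarray] = {}
    if spec.transition is not None:
        ps1 = [s for s in spec.subunits if s.label == "PS1"][0]
        center = np.array([*ps1.center_xy, 0.0])
        for seg, mag in spec.transition.shifts.items():
            idx = _segment_atom_indices(system, seg)
            centroid = ref_coords[idx].mean(axis=0)
            inward = center - centroid
            inward[2] = 0.0
            inward /= np.linalg.norm(inward)
            shift_vectors[seg] = mag * inward
        truth.planted["shift_vectors"] = {k: v.tolist() for k, v in shift_vectors.items()}
        truth.planted["transition_frame"] = spec.transition.frame

    # tilt wobble setup: rotate the helix about the y-axis through its centroid
    wobble = spec.tilt_wobble
    if wobble is not None:
        widx = _segment_atom_indices(system, wobble.segment)
        wcentroid = ref_coords[widx].mean(axis=0)
        wangles = rng.normal(wobble.mean_deg, wobble.sigma_deg, F)
        truth.planted["tilt"] = {
            "segment": wobble.segment, "mean_deg": wobble.mean_deg,
            "sigma_deg": wobble.sigma_deg,
        }

    # catalytic distance process
    cat = spec.catalytic
    ica = [_atom_index(system, s, r, "CA") for s, r in cat]
    icg = [_atom_index(system, s, r, "CG") for s, r in cat]
    iod = [[_atom_index(system, s, r, "OD1"), _atom_index(system, s, r, "OD2")]
           for s, r in cat]
    u = ref_coords[ica[1]] - ref_coords[ica[0]]
    u[2] = 0.0
    u /= np.linalg.norm(u)
    w_perp = np.array([0.0, 0.0, 1.0])
    if spec.transition is not None:
        tr = spec.transition
        d_ca, d_cg, hbond = _draw_two_state_series(F, tr.frame, tr, rng)
        truth.planted["catalytic"] = {
            "ca_inactive_mean": tr.ca_inactive[0], "ca_inactive_std": tr.ca_inactive[1],
            "ca_active_mean": tr.ca_active_mean,
            "cg_inactive_mean": tr.cg_inactive[0], "cg_active_mean": tr.cg_active_mean,
            "hbond_fraction_active": tr.hbond_fraction_active,
            "ca_hbond": tr.ca_hbond, "ca_bridged": tr.ca_bridged,
        }
        truth.planted["hbond_frames"] = hbond
    else:
        d_ca = np.full(F, np.linalg.norm(ref_coords[ica[1]] - ref_coords[ica[0]]))
        d_cg = d_ca - 1.0
        hbond = np.zeros(F, dtype=bool)

    coords = np.empty((F, n, 3), dtype=np.float32)
    mid_ca_ref = 0.5 * (ref_coords[ica[0]] + ref_coords[ica[1]])
    for f in range(F):
        frame = ref_coords + rng.standard_normal((n, 3)) * sigma[:, None]
        for vec, var in modes:
            frame += (rng.normal(0.0, np.sqrt(var)) * vec).reshape(n, 3)
        if spec.transition is not None and f >= spec.transition.frame:
            for seg, vec in shift_vectors.items():
                frame[_segment_atom_indices(system, seg)] += vec
        if wobble is not None:
            ang = np.radians(wangles[f])
            c, s = np.cos(ang), np.sin(ang)
            rot = np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])
            frame[widx] = (frame[widx] - wcentroid) @ rot.T + wcentroid
        if spec.transition is not None:
            # plant the catalytic-pair geometry exactly
            mid = mid_ca_ref + rng.standard_normal(3) * 0.2
            frame[ica[0]] = mid - 0.5 * d_ca[f] * u
            frame[ica[1]] = mid + 0.5 * d_ca[f] * u
            mid_cg = mid - np.array([0.0, 0.0, 1.0])
            cg0 = mid_cg - 0.5 * d_cg[f] * u
            cg1 = mid_cg + 0.5 * d_cg[f] * u
            frame[icg[0]] = cg0
            frame[icg[1]] = cg1
            frame[iod[0][0]] = cg0 + 0.8 * u + 0.5 * w_perp
            frame[iod[0][1]] = cg0 + 0.8 * u - 0.5 * w_perp
            frame[iod[1][0]] = cg1 - 0.8 * u + 0.5 * w_perp
            frame[iod[1][1]] = cg1 - 0.8 * u - 0.5 * w_perp
        if spec.tumble_sigma_deg > 0:
            from scipy.spatial.transform import Rotation
            rvec = rng.standard_normal(3)
            rvec *= np.radians(spec.tumble_sigma_deg * rng.standard_normal()) / np.linalg.norm(rvec)
            R = Rotation.from_rotvec(rvec).as_matrix()
            frame = frame @ R.T + rng.standard_normal(3) * 0.5
        coords[f] = frame
    traj = Trajectory(coordinates=coords, frame_period=spec.frame_period)
    truth.planted["catalytic_atoms"] = {
        "ca": ica, "cg": icg, "od": iod,
    }
    return traj, truth


# ---------------------------------------------------------------------------
# Solvent
# ---------------------------------------------------------------------------

def _binding_box_bounds(spec: SyntheticSpec, ref_coords, system):
    """Binding-region and interior-box bounds in the reference frame."""
    ica = [_atom_index(system, s, r, "CA") for s, r in spec.catalytic]
    site = 0.5 * (ref_coords[ica[0]] + ref_coords[ica[1]])
    b_center = np.array([site[0], site[1], site[2]])
    b_edges = np.array([27.0, 18.0, 16.0])
    # the interior box shares the binding-region xy centre so it contains it
    p_center = b_center + np.array([0.0, 0.0, 2.0])
    p_edges = np.array([30.0, 28.0, 36.0])
    return b_center, b_edges, p_center, p_edges


def simulate_solvent(
    system: MolecularSystem,
    ref_coords: np.ndarray,
    spec: SyntheticSpec,
    seed: int,
    dynamics: tuple[Trajectory, GroundTruth] | None = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Per-frame water-oxygen coordinates with planted count distributions.

    Bulk slabs above and below the membrane hold a fixed number of uniformly
    placed waters; the interior binding region and the box above it draw
    per-frame counts from the planted (state-dependent, when *dynamics* is
    given) distributions; dual-proximity and bridging waters are placed
    explicitly from the actual carboxyl positions of each frame.  Inactive
    waters are parked far outside every counting region so the atom count is
    constant.
    """
    sol = spec.solvent or SolventSpec()
    rng = np.random.default_rng(seed)
    F = spec.n_frames
    truth = GroundTruth(seed=seed)
    b_center, b_edges, p_center, p_edges = _binding_box_bounds(spec, ref_coords, system)
    truth.planted["binding_box"] = {"center": b_center, "edges": b_edges}
    truth.planted["ps1_box"] = {"center": p_center, "edges": p_edges}
    truth.planted["binding_counts"] = sol.binding_counts
    truth.planted["dual_water_mean"] = sol.dual_water_mean
    truth.planted["bulk_density"] = sol.bulk_density
    ps1_total = {st: sol.binding_counts[st][0] + sol.upper_counts[st][0]
                 for st in sol.binding_counts}
    truth.planted["ps1_box_mean"] = ps1_total

    z0, z1 = sol.slab_z
    hw = sol.slab_xy_halfwidth
    slab_volume = (2 * hw) ** 2 * (z1 - z0)
    n_bulk = int(round(sol.bulk_density * slab_volume))
    if n_bulk < 1:
        import warnings
        warnings.warn("bulk density * volume < 1 water per slab")

    if dynamics is not None:
        dyn_traj, dyn_truth = dynamics
        t_frame = dyn_truth.planted.get("transition_frame")
        hbond = dyn_truth.planted.get("hbond_frames", np.zeros(F, dtype=bool))
        od_idx = dyn_truth.planted["catalytic_atoms"]["od"]
        side_idx = [np.array(od_idx[0]), np.array(od_idx[1])]
    else:
        dyn_traj, t_frame, hbond = None, None, np.zeros(F, dtype=bool)
        side_idx = None
    state_of = np.array(
        ["inactive" if (t_frame is None or f < t_frame) else "active" for f in range(F)])
    truth.planted["state_of_frame"] = state_of

    cap_binding = int(sol.binding_counts["inactive"][0] + 8 * sol.binding_counts["inactive"][1])
    cap_upper = int(sol.upper_counts["inactive"][0] + 8 * sol.upper_counts["inactive"][1])
    cap_dual = 14
    n_water = 2 * n_bulk + cap_binding + cap_upper + cap_dual
    coords = np.empty((F, n_water, 3), dtype=np.float32)

    b_lo, b_hi = b_center - b_edges / 2, b_center + b_edges / 2
    p_lo, p_hi = p_center - p_edges / 2, p_center + p_edges / 2

    def uniform_in(lo, hi, m):
        return rng.uniform(lo, hi, size=(m, 3))

    park = np.array([0.0, 0.0, 500.0])
    for f in range(F):
        st = state_of[f]
        out = np.full((n_water, 3), park, dtype=float)
        out[:, 0] += np.arange(n_water) * 2.0  # spread the parking rack in x
        k = 0
        # bulk slabs (fixed count, resampled every frame)
        for zs in ((z0, z1), (-z1, -z0)):
            pts = uniform_in((-hw, -hw, zs[0]), (hw, hw, zs[1]), n_bulk)
            out[k:k + n_bulk] = pts
            k += n_bulk
        # explicit dual-proximity / bridging waters around the carboxyls
        n_dual = 0
        if side_idx is not None:
            frame_prot = dyn_traj.coordinates[f].astype(float)
            oa = frame_prot[side_idx[0]]
            ob = frame_prot[side_idx[1]]
            mid = 0.5 * (oa.mean(0) + ob.mean(0))
            gap = np.linalg.norm(oa.mean(0) - ob.mean(0))
            n_dual = min(rng.poisson(sol.dual_water_mean[st]), cap_dual)
            bridged_frame = (st == "active") and (not hbond[f]) and n_dual > 0
            for j in range(n_dual):
                if j == 0 and bridged_frame:
                    pt = mid + rng.standard_normal(3) * 0.1   # within 3.5 Å of both
                else:
                    # proximal shell: nearest-atom distance to each carboxyl in
                    # (3.55, 4.0] — dual-proximal at 4 Å but never bridging at 3.5.
                    # Carboxyl oxygens sit at ±0.5 Å in z about their group centre,
                    # so a point offset by `off` along +z has nearest-atom distance
                    # sqrt((gap/2)^2 + (off-0.5)^2).
                    target = np.clip(rng.uniform(3.65, 3.95), gap / 2 + 0.03, 3.98)
                    off = 0.5 + np.sqrt(max(target**2 - (gap / 2) ** 2, 1e-4))
                    pt = mid + off * np.array([0.0, 0.0, 1.0])
                    pt += rng.standard_normal(3) * 0.03
                out[k] = pt
                k += 1
        # binding region: planted total count, uniform placement away from
        # the catalytic pair so explicit waters stay the only dual-proximal ones
        mean, sd = sol.binding_counts[st]
        n_bind = min(max(int(round(rng.normal(mean, sd))) - n_dual, 0), cap_binding)
        placed = 0
        while placed < n_bind:
            cand = uniform_in(b_lo, b_hi, 4 * (n_bind - placed))
            if side_idx is not None:
                da = np.linalg.norm(cand[:, None] - oa[None], axis=2).min(axis=1)
                db = np.linalg.norm(cand[:, None] - ob[None], axis=2).min(axis=1)
                cand = cand[~((da <= sol.dual_cutoff + 0.3) & (db <= sol.dual_cutoff + 0.3))]
            take = cand[: n_bind - placed]
            out[k:k + len(take)] = take
            k += len(take)
            placed += len(take)
        # interior above the binding region (rest of the PS1 box)
        mean, sd = sol.upper_counts[st]
        n_up = min(max(int(round(rng.normal(mean, sd))), 0), cap_upper)
        placed = 0
        while placed < n_up:
            cand = uniform_in(p_lo, p_hi, 4 * (n_up - placed))
            inside_binding = np.all((cand >= b_lo) & (cand < b_hi), axis=1)
            cand = cand[~inside_binding]
            take = cand[: n_up - placed]
            out[k:k + len(take)] = take
            k += len(take)
            placed += len(take)
        coords[f] = out
    return coords, truth


# ---------------------------------------------------------------------------
# Lipids
# ---------------------------------------------------------------------------

def simulate_lipids(
    system: MolecularSystem,
    ref_coords: np.ndarray,
    spec: SyntheticSpec,
    seed: int,
) -> tuple[np.ndarray, GroundTruth]:
    """Per-frame lipid bead-chain coordinates: trapped vs diffusive.

    Each lipid is a short rigid bead chain normal to the leaflet plane.
    Diffusive lipids perform fixed-step-length 2D random walks with periodic
    wrap in xy; trapped lipids fluctuate harmonically about sites adjacent
    to named PS1 helix pairs.  Ground truth lists the trapped chain ids,
    their sites and the expected B-factors.
    """
    lip = spec.lipids or LipidSpec()
    rng = np.random.default_rng(seed)
    F = spec.n_frames
    truth = GroundTruth(seed=seed)
    n_lip = lip.n_trapped + lip.n_diffusive
    L = lip.box_xy

    ps1 = [s for s in spec.subunits if s.label == "PS1"][0]
    n_hel = len(ps1.segment_names)
    # trap sites: outward of the angular midpoint between two adjacent helices
    sites, site_segments = [], []
    for (i, j) in lip.trap_pairs:
        th_i = 2 * np.pi * (i - 1) / n_hel
        th_j = 2 * np.pi * (j - 1) / n_hel
        mid = (th_i + th_j) / 2.0
        r_site = ps1.ring_radius + 4.5
        sites.append(np.array([ps1.center_xy[0] + r_site * np.cos(mid),
                               ps1.center_xy[1] + r_site * np.sin(mid)]))
        site_segments.append((f"PS1-TMD{i}", f"PS1-TMD{j}"))
    # protein-overlap check for trap sites
    prot_xy = ref_coords[:, :2]
    for s in sites:
        if np.min(np.linalg.norm(prot_xy - s, axis=1)) < 2.0:
            raise ValueError("trapped lipid site overlaps protein atoms")

    bead_z = 4.0 + 1.4 * np.arange(lip.n_beads)
    coords = np.empty((F, n_lip * lip.n_beads, 3), dtype=np.float32)

    trap_assign = [k % len(sites) for k in range(lip.n_trapped)]
    # diffusive starting positions, kept off the protein footprint
    starts = []
    while len(starts) < lip.n_diffusive:
        cand = rng.uniform(-L / 2, L / 2, size=2)
        if np.min(np.linalg.norm(prot_xy - cand, axis=1)) > 6.0:
            starts.append(cand)
    starts = np.asarray(starts)
    angles = rng.uniform(0, 2 * np.pi, size=(F, lip.n_diffusive))
    steps = lip.step_length * np.stack([np.cos(angles), np.sin(angles)], axis=2)
    walk = starts[None] + np.concatenate(
        [np.zeros((1, lip.n_diffusive, 2)), np.cumsum(steps[:-1], axis=0)], axis=0)
    walk = (walk + L / 2) % L - L / 2     # periodic wrap

    for f in range(F):
        xy = np.empty((n_lip, 2))
        for k in range(lip.n_trapped):
            xy[k] = sites[trap_assign[k]] + rng.standard_normal(2) * lip.tether_sigma
        xy[lip.n_trapped:] = walk[f]
        frame = np.repeat(xy, lip.n_beads, axis=0)
        z = np.tile(bead_z, n_lip)
        jitter = rng.standard_normal((n_lip * lip.n_beads, 3)) * 0.05
        coords[f] = np.column_stack([frame, z]) + jitter
    expected_b = (8 * np.pi**2 / 3) * (2 * lip.tether_sigma**2 + 3 * 0.05**2)
    truth.planted["lipids"] = {
        "trapped_lipid_ids": list(range(1, lip.n_trapped + 1)),
        "site_segments": [site_segments[a] for a in trap_assign],
        "expected_trapped_bfactor": expected_b,
        "tether_sigma": lip.tether_sigma,
        "n_diffusive": lip.n_diffusive,
        "box_xy": L,
    }
    return coords, truth


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _append_atoms(system: MolecularSystem, n_new: int, subunit: str, resname: str,
                  atom_name: str, element: str, mass: float,
                  atoms_per_residue: int = 1) -> MolecularSystem:
    start_id = int(system.atom_ids.max()) + 1
    start_res = 1
    new_ids = np.arange(start_id, start_id + n_new)
    resids = start_res + np.arange(n_new) // atoms_per_residue
    return MolecularSystem(
        atom_ids=np.concatenate([system.atom_ids, new_ids]),
        atom_names=np.concatenate([system.atom_names, np.full(n_new, atom_name, dtype=object)]),
        elements=np.concatenate([system.elements, np.full(n_new, element, dtype=object)]),
        masses=np.concatenate([system.masses, np.full(n_new, mass)]),
        residue_ids=np.concatenate([system.residue_ids, resids]),
        residue_names=np.concatenate([system.residue_names, np.full(n_new, resname, dtype=object)]),
        subunit_of=np.concatenate([system.subunit_of, np.full(n_new, subunit, dtype=object)]),
        segments=system.segments,
    )


def generate(spec: SyntheticSpec, seed: int) -> tuple[MolecularSystem, Trajectory, GroundTruth]:
    """Build the full synthetic study system: protein (+solvent) (+lipids).

    A single master seed spawns the per-component streams; identical
    (spec, seed) pairs give byte-identical output.
    """
    system, ref = build_bundle(spec)
    dyn_traj, truth = simulate_dynamics(system, ref, spec, seed)
    parts = [dyn_traj.coordinates]
    full_system = system
    if spec.solvent is not None:
        wcoords, wtruth = simulate_solvent(system, ref, spec, seed + 1,
                                           dynamics=(dyn_traj, truth))
        full_system = _append_atoms(full_system, wcoords.shape[1], "WATER", "HOH",
                                    "O", "O", 15.999)
        parts.append(wcoords)
        truth.planted.update(wtruth.planted)
    if spec.lipids is not None:
        lcoords, ltruth = simulate_lipids(system, ref, spec, seed + 2)
        lip = spec.lipids
        full_system = _append_atoms(full_system, lcoords.shape[1], "LIPID", "POP",
                                    "C", "C", 12.011, atoms_per_residue=lip.n_beads)
        parts.append(lcoords)
        truth.planted.update(ltruth.planted)
    coords = np.concatenate(parts, axis=1)
    box = None
    if spec.lipids is not None:
        L = spec.lipids.box_xy
        box = np.tile(np.array([L, L, 2000.0], dtype=float), (spec.n_frames, 1))
    traj = Trajectory(coordinates=coords, frame_period=spec.frame_period, box=box)
    truth.planted["reference_coords"] = ref
    return full_system, traj, truth
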