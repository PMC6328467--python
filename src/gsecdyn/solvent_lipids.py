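"""Hydration mapping and lipid-immobilization analysis.

Hydration is quantified by counting water oxygens inside protein-anchored
axis-aligned boxes (per-frame counts, per-state statistics, bulk-relative
z-density profiles, and dual-proximity counts near the catalytic pair).
Lipid immobilization is scored by heavy-atom B-factors of lipid chains on
the protein-aligned trajectory; persistently low-B chains are assigned to
binding sites by their protein-segment contact sets.

Waters are represented by their oxygen atom throughout.  Box bounds are
half-open per axis (``[lo, hi)``) so that box counts partition space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import AtomSelection, MolecularSystem, TimeSeries, Trajectory
from .geometry_states import StateSegmentation
from .structural_metrics import B_PREFACTOR, superpose

#: Edge lengths (Å) of the box approximating the presenilin-1 TMD interior
#: (volume ≈ 30 200 ų) and of the putative substrate-binding region
#: (≈ 7 800 ų).  Centers are a convention supplied by the caller, anchored
#: to the PS-1 TMD Cα frame.
PS1_BOX_EDGES = (30.0, 28.0, 36.0)
BINDING_BOX_EDGES = (27.0, 18.0, 16.0)


@dataclass
class BoxSpec:
    """Axis-aligned counting box in the aligned reference frame."""

    center: np.ndarray
    edges: np.ndarray
    anchor: AtomSelection | None = None   # fit selection defining the frame
    name: str = "box"

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.edges = np.asarray(self.edges, dtype=float)
        if np.any(self.edges <= 0):
            raise ValueError("box edges must be positive")

    @property
    def volume(self) -> float:
        return float(np.prod(self.edges))

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        half = self.edges / 2.0
        return self.center - half, self.center + half

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Half-open membership test for (..., 3) points."""
        lo, hi = self.bounds()
        return np.all((points >= lo) & (points < hi), axis=-1)


def ps1_box(center, anchor: AtomSelection | None = None) -> BoxSpec:
    return BoxSpec(center=center, edges=PS1_BOX_EDGES, anchor=anchor, name="PS1-interior")


def binding_box(center, anchor: AtomSelection | None = None) -> BoxSpec:
    return BoxSpec(center=center, edges=BINDING_BOX_EDGES, anchor=anchor, name="binding-region")


@dataclass
class HydrationReport:
    """Per-frame water counts in a box with summary and per-state stats."""

    per_frame_counts: np.ndarray
    box: BoxSpec
    per_state: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(self.per_frame_counts.mean())

    @property
    def std(self) -> float:
        return float(self.per_frame_counts.std(ddof=1))

    @property
    def min(self) -> int:
        return int(self.per_frame_counts.min())

    @property
    def max(self) -> int:
        return int(self.per_frame_counts.max())


def _check_anchor(traj: Trajectory, box: BoxSpec, reference: int, tol: float) -> None:
    if box.anchor is None or tol is None:
        return
    # the check compares the *unaligned* deviation from the reference frame:
    # an aligned trajectory keeps its anchor atoms near the reference, an
    # unaligned one drifts or tumbles far beyond any fluctuation scale
    ref = traj.coordinates[reference][box.anchor.indices]
    dev = np.sqrt(np.mean(np.sum(
        (traj.coordinates[:, box.anchor.indices, :] - ref) ** 2, axis=2), axis=1))
    worst = float(dev.max())
    if worst > tol:
        raise ValueError(
            f"trajectory not aligned on box anchor (max deviation {worst:.2f} Å > {tol} Å)"
        )


def box_water_counts(
    traj: Trajectory,
    waters: AtomSelection,
    box: BoxSpec,
    segmentation: StateSegmentation | None = None,
    anchor_rmsd_tol: float | None = 5.0,
    reference: int = 0,
) -> HydrationReport:
    """Count water oxygens strictly inside *box* per frame.

    The trajectory must already be aligned on the box anchor; when the box
    carries an anchor selection the alignment is verified (max per-frame
    anchor deviation ≤ *anchor_rmsd_tol*).  With a segmentation, per-state
    summary statistics are included (buffer frames excluded).
    """
    _check_anchor(traj, box, reference, anchor_rmsd_tol)
    pts = traj.coordinates[:, waters.indices, :]
    counts = box.contains(pts).sum(axis=1).astype(int)
    report = HydrationReport(per_frame_counts=counts, box=box)
    if segmentation is not None:
        for state in ("inactive", "active"):
            idx = segmentation.frames_of(state)
            if len(idx):
                x = counts[idx]
                report.per_state[state] = {
                    "mean": float(x.mean()),
                    "std": float(x.std(ddof=1)) if len(x) > 1 else 0.0,
                    "min": int(x.min()), "max": int(x.max()), "n": int(len(x)),
                }
    return report


def density_profile(
    traj: Trajectory,
    waters: AtomSelection,
    box: BoxSpec,
    n_bins: int,
    bulk_region: BoxSpec,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean water density per z-bin of *box*, relative to the bulk region.

    Returns ``(bin_centers_z, ratio)`` where ``ratio = rho_bin / rho_bulk``.
    """
    pts = traj.coordinates[:, waters.indices, :]
    lo, hi = box.bounds()
    in_xy = np.all((pts[..., :2] >= lo[:2]) & (pts[..., :2] < hi[:2]), axis=-1)
    z = pts[..., 2]
    edges_z = np.linspace(lo[2], hi[2], n_bins + 1)
    counts = np.zeros(n_bins)
    for b in range(n_bins):
        inside = in_xy & (z >= edges_z[b]) & (z < edges_z[b + 1])
        counts[b] = inside.sum() / traj.n_frames
    bin_volume = box.edges[0] * box.edges[1] * (edges_z[1] - edges_z[0])
    rho_bins = counts / bin_volume

    bulk_counts = bulk_region.contains(pts).sum(axis=1)
    rho_bulk = bulk_counts.mean() / bulk_region.volume
    if rho_bulk == 0:
        raise ValueError("zero bulk density")
    centers = 0.5 * (edges_z[:-1] + edges_z[1:])
    return centers, rho_bins / rho_bulk


def dual_proximity_waters(
    traj: Trajectory,
    res_a: AtomSelection,
    res_b: AtomSelection,
    waters: AtomSelection,
    cutoff: float = 4.0,
    segmentation: StateSegmentation | None = None,
) -> tuple[TimeSeries, dict[str, float]]:
    """Per-frame count of water oxygens within *cutoff* of heavy atoms of
    BOTH residues; per-state mean counts when a segmentation is given."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(res_a) == 0 or len(res_b) == 0:
        raise ValueError("unresolvable residue selections")
    counts = np.zeros(traj.n_frames, dtype=int)
    for f in range(traj.n_frames):
        w = traj.coordinates[f, waters.indices, :].astype(float)
        da = np.linalg.norm(w[:, None, :] - traj.coordinates[f, res_a.indices, :],
                            axis=2).min(axis=1)
        db = np.linalg.norm(w[:, None, :] - traj.coordinates[f, res_b.indices, :],
                            axis=2).min(axis=1)
        counts[f] = int(np.sum((da <= cutoff) & (db <= cutoff)))
    series = TimeSeries(values=counts.astype(float), units="count",
                        label=f"waters within {cutoff:g} Å of both residues")
    per_state: dict[str, float] = {}
    if segmentation is not None:
        for state in ("inactive", "active"):
            idx = segmentation.frames_of(state)
            if len(idx):
                per_state[state] = float(counts[idx].mean())
    return series, per_state


# ---------------------------------------------------------------------------
# Lipid mobility
# ---------------------------------------------------------------------------

@dataclass
class LipidMobilityTable:
    """Per-lipid-chain B-factors with immobilization ranks.

    ``table`` columns: lipid_id, chain_id, bfactor (Å²), rank (1 = most
    immobilized); contact columns are added by :func:`binding_site_contacts`.
    ``chain_atoms`` maps (lipid_id, chain_id) → heavy-atom indices.
    """

    table: pd.DataFrame
    chain_atoms: dict[tuple[int, str], np.ndarray]

    def top_chains(self, n: int) -> list[tuple[int, str]]:
        head = self.table.nsmallest(n, "bfactor")
        return [(int(r.lipid_id), str(r.chain_id)) for r in head.itertuples()]


def unwrap_coordinates(traj: Trajectory, indices: np.ndarray) -> np.ndarray:
    """Unwrap periodic paths of the selected atoms by accumulating
    minimum-image inter-frame displacements."""
    sub = traj.coordinates[:, indices, :].astype(float)
    if traj.box is None:
        return sub
    steps = np.diff(sub, axis=0)
    steps -= traj.box[1:, None, :] * np.round(steps / traj.box[1:, None, :])
    out = np.empty_like(sub)
    out[0] = sub[0]
    out[1:] = sub[0] + np.cumsum(steps, axis=0)
    return out


def default_lipid_chains(system: MolecularSystem) -> dict[tuple[int, str], np.ndarray]:
    """One chain per LIPID residue (chain id "A"), heavy atoms only."""
    lipid = (system.subunit_of.astype(str) == "LIPID") & (system.elements.astype(str) != "H")
    chains: dict[tuple[int, str], np.ndarray] = {}
    for rid in np.unique(system.residue_ids[lipid]):
        chains[(int(rid), "A")] = np.flatnonzero(lipid & (system.residue_ids == rid))
    return chains


def lipid_bfactors(
    traj: Trajectory,
    system: MolecularSystem,
    protein_fit: AtomSelection,
    chains: dict[tuple[int, str], np.ndarray] | None = None,
    reference: int = 0,
) -> LipidMobilityTable:
    """Heavy-atom B-factors of lipid chains on the protein-aligned frame.

    Lipid paths are first unwrapped (a chain hopping the periodic boundary
    must not inflate its B-factor), then carried into the protein frame by
    the per-frame fit transforms; per-chain B is the mean of member
    heavy-atom B-factors about their own time means.  The table is sorted
    ascending by B with ranks (1 = most immobilized).
    """
    if chains is None:
        chains = default_lipid_chains(system)
    if not chains:
        raise ValueError("no lipid chains defined")
    all_idx = np.concatenate(list(chains.values()))
    unwrapped = unwrap_coordinates(traj, all_idx)
    ref_fit = traj.coordinates[reference][protein_fit.indices]
    for f in range(traj.n_frames):
        tr, _ = superpose(traj.coordinates[f][protein_fit.indices], ref_fit)
        unwrapped[f] = tr.apply(unwrapped[f])
    disp2 = np.sum((unwrapped - unwrapped.mean(axis=0)) ** 2, axis=2)
    b_atom = B_PREFACTOR * disp2.mean(axis=0)
    pos = {int(i): p for p, i in enumerate(all_idx)}
    rows = []
    for (lipid_id, chain_id), idx in chains.items():
        member_b = b_atom[[pos[int(i)] for i in idx]]
        rows.append({"lipid_id": lipid_id, "chain_id": chain_id,
                     "bfactor": float(member_b.mean())})
    df = pd.DataFrame(rows).sort_values("bfactor", kind="stable").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return LipidMobilityTable(table=df, chain_atoms=dict(chains))


def binding_site_contacts(
    mobility: LipidMobilityTable,
    traj: Trajectory,
    system: MolecularSystem,
    segments: list[str],
    contact_cutoff: float = 4.5,
    top_n: int = 17,
    persistence: float = 0.5,
) -> pd.DataFrame:
    """Assign the *top_n* most-immobilized chains to protein binding sites.

    A chain contacts a segment when its heavy atoms come within
    *contact_cutoff* Å of the segment's heavy atoms in at least
    *persistence* of frames; chains sharing a contact-segment set form one
    site.  Chains with an empty contact set are flagged unassigned.
    """
    from .core_io import select

    if top_n > len(mobility.table):
        raise ValueError("top_n exceeds table size")
    heavy = system.elements.astype(str) != "H"
    seg_idx = {}
    for name in segments:
        sel = select(system, name)
        seg_idx[name] = sel.indices[heavy[sel.indices]]
    rows = []
    site_of: dict[frozenset, int] = {}
    for lipid_id, chain_id in mobility.top_chains(top_n):
        cidx = mobility.chain_atoms[(lipid_id, chain_id)]
        lip = traj.coordinates[:, cidx, :].astype(float)
        contacts, fractions = [], {}
        for name, sidx in seg_idx.items():
            prot = traj.coordinates[:, sidx, :].astype(float)
            diff = lip[:, :, None, :] - prot[:, None, :, :]
            if traj.box is not None:
                diff -= traj.box[:, None, None, :] * np.round(diff / traj.box[:, None, None, :])
            dmin = np.sqrt(np.sum(diff**2, axis=3).min(axis=(1, 2)))
            frac = float((dmin <= contact_cutoff).mean())
            fractions[name] = frac
            if frac >= persistence:
                contacts.append(name)
        key = frozenset(contacts)
        if contacts and key not in site_of:
            site_of[key] = len(site_of) + 1
        rows.append({
            "lipid_id": lipid_id, "chain_id": chain_id,
            "contact_segments": tuple(sorted(contacts)),
            "contact_fraction": max(fractions.values()) if fractions else 0.0,
            "site": site_of.get(key, 0),
            "unassigned": not contacts,
        })
    return pd.DataFrame(rows)
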