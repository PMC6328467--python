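"""Structures, trajectories, selections and time-series utilities.

This module defines the in-memory containers shared by every analysis stage
(:class:`MolecularSystem`, :class:`Trajectory`, :class:`AtomSelection`,
:class:`TimeSeries`) and the readers/writers that map them onto standard
structural-biology formats.  File parsing and writing are delegated to
MDAnalysis; the containers here are deliberately plain ``numpy``-backed
records so that the numerical stages never depend on a particular I/O
library.

Conventions
-----------
* Coordinates are in Å, frames are 0-based, ``frame_period`` is in ns per
  frame (formats do not reliably carry it, so it comes from configuration;
  default 1 ns).
* The membrane normal is the +z axis of the input frame: structures are
  assumed pre-oriented, as membrane-positioning servers produce them.
* Residue ids follow the input topology (e.g. presenilin-1 numbering 1-467).
* Transmembrane-segment boundaries are configuration input, not derived:
  the shipped ``data/segments_5fn2.yaml`` records a documented convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

logger = logging.getLogger("gsecdyn")

#: Subunit labels treated as non-protein when a selection says "protein".
NON_PROTEIN_SUBUNITS = frozenset({"LIPID", "WATER", "ION", "UNKNOWN"})

DEFAULT_FRAME_PERIOD_NS = 1.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class MolecularSystem:
    """Topology: atoms, residues, subunit labels and segment definitions.

    Residue identity is the pair ``(subunit, residue_id)``; residue ids are
    only required to be unique within a subunit, as in multi-chain PDB files.
    """

    atom_ids: np.ndarray          # (N,) int
    atom_names: np.ndarray        # (N,) str
    elements: np.ndarray          # (N,) str
    masses: np.ndarray            # (N,) float, amu
    residue_ids: np.ndarray       # (N,) int
    residue_names: np.ndarray     # (N,) str
    subunit_of: np.ndarray        # (N,) str label per atom
    subunits: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    segments: dict[str, tuple[str, list[tuple[int, int]]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.atom_ids = np.asarray(self.atom_ids, dtype=np.int64)
        if len(np.unique(self.atom_ids)) != len(self.atom_ids):
            raise ValueError("atom_ids must be unique")
        for name in ("atom_names", "elements", "residue_names", "subunit_of"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=object))
        self.masses = np.asarray(self.masses, dtype=float)
        self.residue_ids = np.asarray(self.residue_ids, dtype=np.int64)
        if not self.subunits:
            self.subunits = self._ranges_from_atoms()
        self._check_segments()

    def _ranges_from_atoms(self) -> dict[str, list[tuple[int, int]]]:
        out: dict[str, list[tuple[int, int]]] = {}
        for label in dict.fromkeys(self.subunit_of):  # preserves order
            rid = self.residue_ids[self.subunit_of == label]
            out[str(label)] = [(int(rid.min()), int(rid.max()))]
        return out

    def _check_segments(self) -> None:
        for seg, (subunit, ranges) in self.segments.items():
            if subunit not in self.subunits:
                raise ValueError(f"segment {seg!r} references unknown subunit {subunit!r}")
            lo = min(a for a, _ in self.subunits[subunit])
            hi = max(b for _, b in self.subunits[subunit])
            for a, b in ranges:
                if a < lo or b > hi:
                    raise ValueError(
                        f"segment {seg!r} range {a}-{b} outside subunit {subunit!r} ({lo}-{hi})"
                    )

    @property
    def n_atoms(self) -> int:
        return len(self.atom_ids)

    def residue_keys(self) -> np.ndarray:
        """Per-atom residue key strings ``"SUBUNIT:resid"``."""
        return np.array(
            [f"{s}:{r}" for s, r in zip(self.subunit_of, self.residue_ids)], dtype=object
        )

    def with_segments(self, segments: Mapping[str, tuple[str, Sequence[tuple[int, int]]]]):
        segs = {k: (v[0], [tuple(r) for r in v[1]]) for k, v in segments.items()}
        return replace(self, segments={**self.segments, **segs})


@dataclass
class Trajectory:
    """Ordered frames of Cartesian coordinates (Å).

    ``box`` holds per-frame orthorhombic box edge lengths (Å) or ``None``
    for non-periodic data.
    """

    coordinates: np.ndarray               # (F, N, 3)
    frame_period: float = DEFAULT_FRAME_PERIOD_NS   # ns per frame
    box: np.ndarray | None = None         # (F, 3) or None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates contain non-finite values")
        if self.frame_period <= 0:
            raise ValueError("frame_period must be positive")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (self.n_frames, 3):
                raise ValueError("box must have shape (n_frames, 3)")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_period


@dataclass(frozen=True)
class AtomSelection:
    """Sorted unique atom indices plus the expression that produced them."""

    indices: np.ndarray
    expression: str = ""

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=np.int64))
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class TimeSeries:
    """Per-frame scalar series with units metadata."""

    values: np.ndarray
    units: str
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.units:
            raise ValueError("units must be non-empty")

    def __len__(self) -> int:
        return len(self.values)


# ---------------------------------------------------------------------------
# Segment / subunit configuration
# ---------------------------------------------------------------------------

@dataclass
class SegmentConfig:
    """Chain→subunit map, segment residue ranges and frame period."""

    chains: dict[str, str] = field(default_factory=dict)
    segments: dict[str, tuple[str, list[tuple[int, int]]]] = field(default_factory=dict)
    frame_period: float = DEFAULT_FRAME_PERIOD_NS


def load_segment_config(path: str | Path) -> SegmentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    segments: dict[str, tuple[str, list[tuple[int, int]]]] = {}
    for name, entry in (raw.get("segments") or {}).items():
        ranges = entry["range"]
        if ranges and not isinstance(ranges[0], (list, tuple)):
            ranges = [ranges]
        segments[name] = (entry["subunit"], [(int(a), int(b)) for a, b in ranges])
    return SegmentConfig(
        chains={str(k): str(v) for k, v in (raw.get("chains") or {}).items()},
        segments=segments,
        frame_period=float(raw.get("frame_period", DEFAULT_FRAME_PERIOD_NS)),
    )


def default_segment_config() -> SegmentConfig:
    """The shipped convention for the 5FN2 chain map and TMD ranges."""
    return load_segment_config(Path(__file__).parent / "data" / "segments_5fn2.yaml")


# ---------------------------------------------------------------------------
# Structure / trajectory reading (MDAnalysis-backed)
# ---------------------------------------------------------------------------

def _universe_to_system(u, config: SegmentConfig | None) -> MolecularSystem:
    import MDAnalysis as mda  # noqa: F401  (parse errors surface on Universe creation)

    atoms = u.atoms
    n = len(atoms)
    chain_map = config.chains if config else {}
    try:
        chain_ids = atoms.chainIDs
    except mda.exceptions.NoDataError:
        chain_ids = atoms.segids
    subunit = np.empty(n, dtype=object)
    unknown: set[str] = set()
    for i, cid in enumerate(chain_ids):
        cid = str(cid).strip()
        if cid in chain_map:
            subunit[i] = chain_map[cid]
        elif not chain_map:
            subunit[i] = cid or "UNKNOWN"
        else:
            subunit[i] = "UNKNOWN"
            unknown.add(cid)
    if unknown:
        warnings.warn(
            f"chains {sorted(unknown)} absent from config chain map; labelled UNKNOWN",
            stacklevel=3,
        )
    try:
        elements = np.asarray(atoms.elements, dtype=object)
    except mda.exceptions.NoDataError:
        elements = np.array([str(nm)[:1] for nm in atoms.names], dtype=object)
    try:
        masses = np.asarray(atoms.masses, dtype=float)
    except mda.exceptions.NoDataError:
        masses = np.ones(n)
    system = MolecularSystem(
        atom_ids=np.arange(n),
        atom_names=np.asarray(atoms.names, dtype=object),
        elements=elements,
        masses=masses,
        residue_ids=np.asarray(atoms.resids, dtype=np.int64),
        residue_names=np.asarray(atoms.resnames, dtype=object),
        subunit_of=subunit,
    )
    if config and config.segments:
        applicable = {
            name: spec for name, spec in config.segments.items() if spec[0] in system.subunits
        }
        system = system.with_segments(applicable)
    return system


def load_structure(
    path: str | Path, config: SegmentConfig | None = None
) -> tuple[MolecularSystem, np.ndarray]:
    """Read a PDB file; return the topology and the first model's coordinates.

    Subunit labels come from the chain→subunit map of *config*; chains absent
    from the map are labelled ``UNKNOWN`` with a warning.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    system = _universe_to_system(u, config)
    coords = u.atoms.positions.astype(float).copy()
    return system, coords


def load_trajectory(
    path: str | Path,
    system: MolecularSystem,
    frame_period: float | None = None,
    topology: str | Path | None = None,
) -> Trajectory:
    """Read a trajectory (multi-model PDB, DCD, XTC, TRR) against *system*.

    ``frame_period`` is configuration, not read from the file.  Binary
    formats need *topology* (any structure file with matching atoms).
    """
    import MDAnalysis as mda

    path = Path(path)
    if topology is None:
        u = mda.Universe(str(path))
    else:
        u = mda.Universe(str(topology), str(path))
    if len(u.atoms) != system.n_atoms:
        raise ValueError(
            f"atom-count mismatch: file has {len(u.atoms)}, system has {system.n_atoms}"
        )
    frames = []
    try:
        for ts in u.trajectory:
            frames.append(u.atoms.positions.astype(float).copy())
    except (OSError, EOFError) as exc:  # truncated file
        raise IOError(f"truncated trajectory after frame {len(frames)}: {exc}") from exc
    coords = np.stack(frames)
    box = None
    dims = u.trajectory.ts.dimensions
    if dims is not None and np.all(dims[:3] > 0):
        box = np.empty((len(frames), 3))
        for i, ts in enumerate(u.trajectory):
            box[i] = ts.dimensions[:3]
    period = frame_period if frame_period is not None else DEFAULT_FRAME_PERIOD_NS
    return Trajectory(coordinates=coords, frame_period=period, box=box)


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

_SUBUNIT_CHAIN_DEFAULT = {
    "NIC": "A", "PS1": "B", "APH1": "C", "PEN2": "D",
    "LIPID": "L", "WATER": "W", "ION": "I",
}


def _system_to_universe(system: MolecularSystem, chain_of: Mapping[str, str] | None = None):
    import MDAnalysis as mda

    chain_of = dict(chain_of or {})
    letters = iter("EFGHJKMNOPQRSTUVXYZ")
    for label in system.subunits:
        if label not in chain_of:
            chain_of[label] = _SUBUNIT_CHAIN_DEFAULT.get(label) or next(letters)

    res_key = system.residue_keys()
    # stable residue grouping in atom order
    seen: dict[str, int] = {}
    atom_resindex = np.empty(system.n_atoms, dtype=int)
    res_ids, res_names, res_chains = [], [], []
    for i, key in enumerate(res_key):
        if key not in seen:
            seen[key] = len(seen)
            res_ids.append(int(system.residue_ids[i]))
            res_names.append(str(system.residue_names[i]))
            res_chains.append(chain_of[str(system.subunit_of[i])])
        atom_resindex[i] = seen[key]
    n_res = len(seen)
    u = mda.Universe.empty(
        n_atoms=system.n_atoms, n_residues=n_res, atom_resindex=atom_resindex,
        n_segments=1, trajectory=True,
    )
    u.add_TopologyAttr("names", [str(x) for x in system.atom_names])
    u.add_TopologyAttr("elements", [str(x) for x in system.elements])
    u.add_TopologyAttr("masses", system.masses)
    u.add_TopologyAttr("resids", res_ids)
    u.add_TopologyAttr("resnames", res_names)
    u.add_TopologyAttr("chainIDs", [res_chains[r] for r in atom_resindex])
    u.add_TopologyAttr("occupancies", np.ones(system.n_atoms))
    u.add_TopologyAttr("tempfactors", np.zeros(system.n_atoms))
    return u


def save_structure(
    system: MolecularSystem,
    coords: np.ndarray,
    path: str | Path,
    chain_of: Mapping[str, str] | None = None,
) -> None:
    """Write one model (or ``(F,N,3)`` stack → multi-model) as PDB."""
    import MDAnalysis as mda

    coords = np.asarray(coords, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    u = _system_to_universe(system, chain_of)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=system.n_atoms, multiframe=coords.shape[0] > 1) as w:
            for frame in coords:
                u.atoms.positions = frame
                w.write(u.atoms)


def save_trajectory(
    system: MolecularSystem,
    traj: Trajectory,
    path: str | Path,
    chain_of: Mapping[str, str] | None = None,
) -> None:
    """Write a trajectory; format chosen by extension (.pdb/.dcd/.xtc/.trr)."""
    import MDAnalysis as mda

    path = Path(path)
    if path.suffix.lower() == ".pdb":
        save_structure(system, traj.coordinates, path, chain_of)
        return
    u = _system_to_universe(system, chain_of)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms=system.n_atoms) as w:
            for f in range(traj.n_frames):
                u.atoms.positions = traj.coordinates[f]
                if traj.box is not None:
                    u.dimensions = [*traj.box[f], 90.0, 90.0, 90.0]
                w.write(u.atoms)


def write_timeseries(series: TimeSeries, path: str | Path, frame_period: float = 1.0) -> None:
    """Write a TimeSeries as a two-column delimited table with a units header."""
    header = f"label: {series.label}\nunits: {series.units}\nframe\tvalue"
    data = np.column_stack([np.arange(len(series)), series.values])
    np.savetxt(path, data, fmt=["%d", "%.6f"], delimiter="\t", header=header)


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def _parse_int_list(token: str) -> list[tuple[int, int]]:
    """``257`` | ``10:20`` | ``1,3,5:9`` → list of inclusive ranges."""
    out = []
    for part in token.split(","):
        if ":" in part:
            a, b = part.split(":")
            out.append((int(a), int(b)))
        else:
            out.append((int(part), int(part)))
    return out


def _term_mask(system: MolecularSystem, term: str) -> np.ndarray:
    words = term.split()
    if not words:
        raise ValueError("empty selection term")
    key = words[0].lower()
    if key == "name" and len(words) == 2:
        names = set(words[1].split(","))
        return np.isin(system.atom_names.astype(str), list(names))
    if key == "resid" and len(words) == 2:
        mask = np.zeros(system.n_atoms, dtype=bool)
        for a, b in _parse_int_list(words[1]):
            mask |= (system.residue_ids >= a) & (system.residue_ids <= b)
        return mask
    if key == "element" and len(words) == 2:
        return np.isin(system.elements.astype(str), words[1].split(","))
    if key == "protein" and len(words) == 1:
        return ~np.isin(system.subunit_of.astype(str), list(NON_PROTEIN_SUBUNITS))
    if len(words) == 1 or (key == "subunit" and len(words) == 2):
        label = words[-1]
        if label in system.subunits:
            return system.subunit_of.astype(str) == label
        if label in system.segments:
            subunit, ranges = system.segments[label]
            mask = system.subunit_of.astype(str) == subunit
            rmask = np.zeros(system.n_atoms, dtype=bool)
            for a, b in ranges:
                rmask |= (system.residue_ids >= a) & (system.residue_ids <= b)
            return mask & rmask
        raise KeyError(f"unknown subunit or segment {label!r}")
    raise ValueError(f"cannot parse selection term {term!r}")


def select(system: MolecularSystem, expression: str) -> AtomSelection:
    """Resolve a selection expression to a sorted atom-index list.

    Grammar: ``or``-separated unions of ``and``-separated terms; a term is a
    subunit label, a segment name, ``protein``, ``name X[,Y]``,
    ``resid A[:B][,C]`` or ``element E``.  Deterministic; an empty result is
    legal but logged.
    """
    union = np.zeros(system.n_atoms, dtype=bool)
    for disjunct in expression.split(" or "):
        mask = np.ones(system.n_atoms, dtype=bool)
        for term in disjunct.split(" and "):
            mask &= _term_mask(system, term.strip())
        union |= mask
    idx = np.flatnonzero(union)
    if len(idx) == 0:
        logger.warning("selection %r matched no atoms", expression)
    return AtomSelection(indices=idx, expression=expression)


# ---------------------------------------------------------------------------
# Time-series utilities
# ---------------------------------------------------------------------------

def running_average(series: TimeSeries | np.ndarray, window: int) -> TimeSeries:
    """Centered moving mean; the window is clamped at the edges.

    For odd ``window`` the interior mean runs over ``window`` points centered
    on each frame; near the edges the window shrinks to what is available.
    Output length equals input length.
    """
    values = series.values if isinstance(series, TimeSeries) else np.asarray(series, float)
    n = len(values)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > n:
        raise ValueError(f"window ({window}) larger than series ({n})")
    left = (window - 1) // 2
    right = window // 2
    csum = np.concatenate([[0.0], np.cumsum(values)])
    lo = np.maximum(np.arange(n) - left, 0)
    hi = np.minimum(np.arange(n) + right + 1, n)
    out = (csum[hi] - csum[lo]) / (hi - lo)
    if isinstance(series, TimeSeries):
        return TimeSeries(values=out, units=series.units,
                          label=f"{series.label} (running mean, w={window})")
    return TimeSeries(values=out, units="a.u.", label=f"running mean, w={window}")
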