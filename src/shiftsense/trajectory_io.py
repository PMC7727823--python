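"""Trajectory and tabular series I/O for chromophore bond/shift analysis.

The in-memory containers are thin dataclasses around numpy arrays:

* :class:`ChromophoreTopology` — the labelled C-C bond chain of the
  chromophore (rings C/D of an open-chain tetrapyrrole by default).
* :class:`FrameSet` — per-frame Cartesian coordinates (Å) with time stamps.
* :class:`BondSeries` / :class:`ShiftSeries` — frames × bonds (Å) and
  frames × atoms (ppm) matrices aligned on a common time grid.

File formats are deliberately plain: multi-frame XYZ for geometries, CSV
with a header row for tabular series, JSON for topologies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ChromophoreTopology",
    "FrameSet",
    "BondSeries",
    "ShiftSeries",
    "bond_label",
    "chain_topology",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "compute_bond_series",
    "read_shift_table",
    "write_shift_table",
    "read_bond_table",
    "write_bond_table",
    "align_series",
]


def bond_label(a: str, b: str) -> str:
    """Canonical label for the bond between atoms *a* and *b*, e.g. ``"C13-C14"``."""
    return f"{a}-{b}"


@dataclass(frozen=True)
class ChromophoreTopology:
    """Labelled atoms, bonds and ring membership of a conjugated chromophore.

    ``ring_membership`` maps atom labels to ring identifiers; for the default
    phycocyanobilin rings-C/D chain these are ``"C"``, ``"bridge"`` (the C15
    methine) and ``"D"``.
    """

    atom_labels: tuple[str, ...]
    bonds: tuple[tuple[str, str], ...]
    ring_membership: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        atoms = set(self.atom_labels)
        if len(atoms) != len(self.atom_labels):
            raise ValueError("duplicate atom labels in topology")
        seen: set[frozenset[str]] = set()
        for a, b in self.bonds:
            if a not in atoms or b not in atoms:
                raise ValueError(f"bond ({a}, {b}) references unknown atom label")
            key = frozenset((a, b))
            if key in seen:
                raise ValueError(f"duplicate bond ({a}, {b})")
            seen.add(key)
        for a in self.ring_membership:
            if a not in atoms:
                raise ValueError(f"ring membership references unknown atom {a!r}")

    @property
    def bond_labels(self) -> tuple[str, ...]:
        return tuple(bond_label(a, b) for a, b in self.bonds)

    @classmethod
    def default(cls) -> "ChromophoreTopology":
        """Rings C/D chain C12–C19 with the seven consecutive C-C bonds."""
        atoms = tuple(f"C{i}" for i in range(12, 20))
        bonds = tuple((f"C{i}", f"C{i + 1}") for i in range(12, 19))
        rings = {"C12": "C", "C13": "C", "C14": "C", "C15": "bridge",
                 "C16": "D", "C17": "D", "C18": "D", "C19": "D"}
        return cls(atoms, bonds, rings)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "atom_labels": list(self.atom_labels),
            "bonds": [list(b) for b in self.bonds],
            "ring_membership": dict(self.ring_membership),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ChromophoreTopology":
        payload = json.loads(Path(path).read_text())
        return cls(
            tuple(payload["atom_labels"]),
            tuple(tuple(b) for b in payload["bonds"]),
            dict(payload.get("ring_membership", {})),
        )


def chain_topology(atom_labels: list[str] | tuple[str, ...],
                   ring_membership: dict[str, str] | None = None) -> ChromophoreTopology:
    """Topology of a linear chain: consecutive atoms bonded pairwise."""
    atoms = tuple(atom_labels)
    bonds = tuple((atoms[i], atoms[i + 1]) for i in range(len(atoms) - 1))
    return ChromophoreTopology(atoms, bonds, ring_membership or {})


@dataclass(frozen=True)
class FrameSet:
    """Cartesian coordinates (Å) per frame for a fixed set of labelled atoms."""

    atom_labels: tuple[str, ...]
    times_fs: np.ndarray  # (n_frames,)
    coordinates: np.ndarray  # (n_frames, n_atoms, 3), Å

    def __post_init__(self) -> None:
        t = np.asarray(self.times_fs, dtype=float)
        c = np.asarray(self.coordinates, dtype=float)
        object.__setattr__(self, "times_fs", t)
        object.__setattr__(self, "coordinates", c)
        if c.ndim != 3 or c.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_atoms, 3)")
        if c.shape[0] != t.shape[0]:
            raise ValueError("frame count mismatch between times and coordinates")
        if c.shape[1] != len(self.atom_labels):
            raise ValueError("atom count mismatch between labels and coordinates")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.times_fs.shape[0])


@dataclass(frozen=True)
class BondSeries:
    """Per-frame bond lengths (Å) for a labelled set of bonds."""

    bond_labels: tuple[str, ...]
    times_fs: np.ndarray
    lengths: np.ndarray  # (n_frames, n_bonds), Å

    def __post_init__(self) -> None:
        t = np.asarray(self.times_fs, dtype=float)
        x = np.asarray(self.lengths, dtype=float)
        object.__setattr__(self, "times_fs", t)
        object.__setattr__(self, "lengths", x)
        if x.shape != (t.shape[0], len(self.bond_labels)):
            raise ValueError("lengths shape inconsistent with times/labels")
        if x.size and not np.all(x > 0):
            raise ValueError("bond lengths must be positive")

    @property
    def n_frames(self) -> int:
        return int(self.times_fs.shape[0])


@dataclass(frozen=True)
class ShiftSeries:
    """Per-frame isotropic chemical shifts (ppm) for labelled atoms."""

    atom_labels: tuple[str, ...]
    times_fs: np.ndarray
    shifts: np.ndarray  # (n_frames, n_atoms), ppm

    def __post_init__(self) -> None:
        t = np.asarray(self.times_fs, dtype=float)
        x = np.asarray(self.shifts, dtype=float)
        object.__setattr__(self, "times_fs", t)
        object.__setattr__(self, "shifts", x)
        if x.shape != (t.shape[0], len(self.atom_labels)):
            raise ValueError("shifts shape inconsistent with times/labels")
        if x.size and not np.all(np.isfinite(x)):
            raise ValueError("shift values must be finite")

    @property
    def n_frames(self) -> int:
        return int(self.times_fs.shape[0])


# ---------------------------------------------------------------------------
# XYZ trajectories


def _parse_comment_time(comment: str) -> float | None:
    txt = comment.strip()
    if not txt:
        return None
    low = txt.lower()
    if "time" in low:
        after = low.split("time", 1)[1].lstrip(" =:")
        token = after.split()[0] if after.split() else ""
        try:
            return float(token.rstrip(","))
        except ValueError:
            return None
    try:
        return float(txt.split()[0])
    except ValueError:
        return None


def read_xyz_trajectory(path: str | Path,
                        label_map: dict[int, str] | None = None,
                        dt_fs: float = 1.0) -> FrameSet:
    """Read a multi-frame XYZ file into a :class:`FrameSet`.

    Frame times are taken from the comment line when it contains
    ``time = <x>`` or a bare number (assumed fs); otherwise frames are
    spaced uniformly by ``dt_fs``. ``label_map`` optionally renames atoms
    by their 0-based index within a frame; by default the element column
    is used, suffixed with the index when elements repeat.
    """
    lines = Path(path).read_text().splitlines()
    pos = 0
    frames: list[np.ndarray] = []
    times: list[float | None] = []
    labels: list[str] | None = None
    n_atoms: int | None = None
    frame_idx = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            count = int(lines[pos].strip())
        except ValueError as exc:
            raise ValueError(f"line {pos + 1}: expected atom count, got {lines[pos]!r}") from exc
        if n_atoms is None:
            n_atoms = count
        elif count != n_atoms:
            raise ValueError(f"frame {frame_idx}: atom count {count} differs from first frame ({n_atoms})")
        if pos + 2 + count > len(lines):
            raise ValueError(f"frame {frame_idx}: truncated (expected {count} atom lines)")
        times.append(_parse_comment_time(lines[pos + 1]))
        syms: list[str] = []
        coords = np.empty((count, 3))
        for i in range(count):
            ln = pos + 2 + i
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ValueError(f"line {ln + 1}: malformed coordinate line {lines[ln]!r}")
            try:
                coords[i] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise ValueError(f"line {ln + 1}: non-numeric coordinate in {lines[ln]!r}") from exc
            syms.append(parts[0])
        if labels is None:
            if label_map is not None:
                labels = [label_map.get(i, syms[i]) for i in range(count)]
            elif len(set(syms)) == len(syms):
                labels = syms
            else:
                labels = [f"{s}{i}" for i, s in enumerate(syms)]
        frames.append(coords)
        pos += 2 + count
        frame_idx += 1
    if not frames:
        raise ValueError("empty XYZ file")
    if any(t is None for t in times):
        t_arr = np.arange(len(frames), dtype=float) * dt_fs
    else:
        t_arr = np.array(times, dtype=float)
    return FrameSet(tuple(labels or ()), t_arr, np.stack(frames))


def write_xyz_trajectory(path: str | Path, frames: FrameSet) -> None:
    """Write a :class:`FrameSet` as multi-frame XYZ (comment line ``time = <fs>``)."""
    out: list[str] = []
    n = len(frames.atom_labels)
    for k in range(frames.n_frames):
        out.append(str(n))
        out.append(f"time = {frames.times_fs[k]:.6f}")
        for lab, xyz in zip(frames.atom_labels, frames.coordinates[k]):
            out.append(f"{lab} {xyz[0]:.9f} {xyz[1]:.9f} {xyz[2]:.9f}")
    Path(path).write_text("\n".join(out) + "\n")


def compute_bond_series(frames: FrameSet, topo: ChromophoreTopology) -> BondSeries:
    """Euclidean bond lengths per frame for every bond in *topo* (Å)."""
    index = {lab: i for i, lab in enumerate(frames.atom_labels)}
    cols = []
    for a, b in topo.bonds:
        if a not in index or b not in index:
            missing = a if a not in index else b
            raise ValueError(f"bond ({a}, {b}): atom {missing!r} not present in frames")
        diff = frames.coordinates[:, index[a], :] - frames.coordinates[:, index[b], :]
        cols.append(np.linalg.norm(diff, axis=1))
    lengths = np.column_stack(cols) if cols else np.empty((frames.n_frames, 0))
    return BondSeries(topo.bond_labels, frames.times_fs.copy(), lengths)


# ---------------------------------------------------------------------------
# Tabular series (CSV with header: time_fs, <label>, <label>, ...)


def _read_table(path: str | Path) -> tuple[tuple[str, ...], np.ndarray, np.ndarray]:
    with open(path) as fh:
        header_line = fh.readline().strip()
    header = [h.strip() for h in header_line.split(",")]
    if len(header) < 1 or not header[0]:
        raise ValueError(f"{path}: missing header row")
    labels = header[1:]
    if len(set(labels)) != len(labels):
        dup = next(l for l in labels if labels.count(l) > 1)
        raise ValueError(f"{path}: duplicate header label {dup!r}")
    raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if raw.empty:
        return tuple(labels), np.empty(0), np.empty((0, len(labels)))
    values = np.empty((len(raw), len(header)))
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & raw[col].notna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ValueError(
                f"{path}: non-numeric value {raw[col].iloc[row]!r} at row {row + 2}, column {col!r}")
        if converted.isna().any():
            row = int(np.argmax(converted.isna().to_numpy()))
            raise ValueError(f"{path}: missing value at row {row + 2}, column {col!r}")
        values[:, j] = converted.to_numpy(dtype=float)
    return tuple(labels), values[:, 0], values[:, 1:]


def read_shift_table(path: str | Path) -> ShiftSeries:
    """Read a shift CSV (columns ``time_fs, C13, C14, ...``) into a ShiftSeries."""
    labels, times, values = _read_table(path)
    return ShiftSeries(labels, times, values)


def write_shift_table(path: str | Path, series: ShiftSeries) -> None:
    df = pd.DataFrame(series.shifts, columns=list(series.atom_labels))
    df.insert(0, "time_fs", series.times_fs)
    df.to_csv(path, index=False, float_format="%.9f")


def read_bond_table(path: str | Path) -> BondSeries:
    """Read a bond-length CSV (columns ``time_fs, C13-C14, ...``) into a BondSeries."""
    labels, times, values = _read_table(path)
    return BondSeries(labels, times, values)


def write_bond_table(path: str | Path, series: BondSeries) -> None:
    df = pd.DataFrame(series.lengths, columns=list(series.bond_labels))
    df.insert(0, "time_fs", series.times_fs)
    df.to_csv(path, index=False, float_format="%.9f")


# ---------------------------------------------------------------------------
# Frame alignment


def align_series(b: BondSeries, s: ShiftSeries, tol_fs: float) -> tuple[BondSeries, ShiftSeries]:
    """Match bond and shift frames by nearest time within ``tol_fs``.

    Unmatched frames are dropped on both sides; each shift frame is used at
    most once. The returned series share the bond series' time stamps.
    """
    if b.n_frames == 0 or s.n_frames == 0:
        raise ValueError("cannot align empty series")
    ts = s.times_fs
    used: set[int] = set()
    keep_b: list[int] = []
    keep_s: list[int] = []
    for i, t in enumerate(b.times_fs):
        j = int(np.searchsorted(ts, t))
        best, best_dt = -1, np.inf
        for cand in (j - 1, j):
            if 0 <= cand < ts.size and cand not in used:
                dt = abs(ts[cand] - t)
                if dt < best_dt:
                    best, best_dt = cand, dt
        if best >= 0 and best_dt <= tol_fs:
            used.add(best)
            keep_b.append(i)
            keep_s.append(best)
    if not keep_b:
        raise ValueError(f"no frames matched within {tol_fs} fs")
    times = b.times_fs[keep_b]
    return (
        BondSeries(b.bond_labels, times, b.lengths[keep_b]),
        ShiftSeries(s.atom_labels, times.copy(), s.shifts[keep_s]),
    )
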