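"""Trajectory dataset I/O and frame/atom bookkeeping.

A :class:`ConfigurationSet` is a labeled molecular trajectory with a fixed
atom list: per-frame positions (Å) and, optionally, per-frame reference
energies (kcal/mol) and per-atom reference forces (kcal/(mol·Å)). These are
the canonical internal units throughout the package; converters are applied
only at the I/O boundary.

Supported on-disk formats are extended XYZ (the community dialect whose
comment line carries ``Properties=...`` column declarations and frame-level
``key=value`` pairs such as ``energy=``) and NPZ array bundles using
MD17/MD22-style key names (``R``, ``z``, ``E``, ``F``).

The atom list is constant across frames: trajectories whose frames disagree
on atom count or order are rejected at load, since every downstream analysis
indexes atoms consistently across frames.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._elements import number_of, symbol_of

logger = logging.getLogger(__name__)

__all__ = [
    "ConfigurationSet",
    "PredictionRecord",
    "SubsetView",
    "AtomSelection",
    "TrajectoryFormatError",
    "read_extxyz",
    "write_extxyz",
    "read_npz_bundle",
    "write_npz_bundle",
    "make_subset",
    "extract_subset",
    "parse_formula",
]


class TrajectoryFormatError(ValueError):
    """Raised for malformed or structurally inconsistent trajectory files."""


@dataclass
class ConfigurationSet:
    """A labeled molecular trajectory with static atom identities.

    Parameters
    ----------
    atomic_numbers : (n_atoms,) int array
        Nuclear charges; fixed across frames, all >= 1.
    positions : (n_frames, n_atoms, 3) float array, Å
    energies : (n_frames,) float array, kcal/mol, optional
    forces : (n_frames, n_atoms, 3) float array, kcal/(mol·Å), optional
    name : str
        Free-text provenance label.
    metadata : dict
        Opaque side information (e.g. preserved comment-line keys, planted
        fixture ground truth). Never interpreted by core analyses.
    """

    atomic_numbers: np.ndarray
    positions: np.ndarray
    energies: np.ndarray | None = None
    forces: np.ndarray | None = None
    name: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=int)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError(
                f"positions must be (n_frames, n_atoms, 3), got {self.positions.shape}"
            )
        if self.atomic_numbers.ndim != 1:
            raise ValueError("atomic_numbers must be 1-D")
        if self.atomic_numbers.shape[0] != self.positions.shape[1]:
            raise ValueError(
                f"atomic_numbers length {self.atomic_numbers.shape[0]} does not match "
                f"per-frame atom count {self.positions.shape[1]}"
            )
        if np.any(self.atomic_numbers < 1):
            raise ValueError("atomic numbers must all be >= 1")
        if self.energies is not None:
            self.energies = np.asarray(self.energies, dtype=float)
            if self.energies.shape != (self.n_frames,):
                raise ValueError(
                    f"energies shape {self.energies.shape} != ({self.n_frames},)"
                )
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)
            if self.forces.shape != self.positions.shape:
                raise ValueError(
                    f"forces shape {self.forces.shape} != positions shape "
                    f"{self.positions.shape}"
                )

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def element_symbols(self) -> list[str]:
        """Per-atom chemical symbols derived from the nuclear charges."""
        return [symbol_of(int(z)) for z in self.atomic_numbers]


@dataclass
class PredictionRecord:
    """Model energies/forces aligned 1:1 with a :class:`ConfigurationSet`."""

    source_id: str
    energies: np.ndarray | None = None
    forces: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.energies is not None:
            self.energies = np.asarray(self.energies, dtype=float)
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)

    def validate_against(self, ds: ConfigurationSet) -> None:
        """Check 1:1 frame/atom alignment with ``ds``; raise on mismatch."""
        n = None
        if self.energies is not None:
            n = self.energies.shape[0]
            if self.energies.shape != (ds.n_frames,):
                raise ValueError(
                    f"prediction has {n} frames of energies, dataset has {ds.n_frames}"
                )
        if self.forces is not None:
            if self.forces.shape != ds.positions.shape:
                raise ValueError(
                    f"prediction forces shape {self.forces.shape} does not match "
                    f"dataset shape {ds.positions.shape}"
                )
        if self.energies is None and self.forces is None:
            raise ValueError("prediction carries neither energies nor forces")


@dataclass(frozen=True)
class SubsetView:
    """A sorted, duplicate-free selection of frames of a parent trajectory."""

    parent: ConfigurationSet
    frame_indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.frame_indices, dtype=int)
        object.__setattr__(self, "frame_indices", idx)
        if idx.size and (idx.min() < 0 or idx.max() >= self.parent.n_frames):
            raise ValueError("frame index out of range")
        if idx.size and (np.any(np.diff(idx) <= 0)):
            raise ValueError("frame_indices must be sorted ascending and unique")

    def __len__(self) -> int:
        return int(self.frame_indices.size)


@dataclass(frozen=True)
class AtomSelection:
    """A sorted, duplicate-free selection of atom indices with a label."""

    atom_indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.atom_indices, dtype=int)
        object.__setattr__(self, "atom_indices", idx)
        if idx.size and idx.min() < 0:
            raise ValueError("atom index out of range")
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("atom_indices must be sorted ascending and unique")

    @classmethod
    def from_indices(cls, indices: Sequence[int], label: str = "") -> "AtomSelection":
        return cls(np.unique(np.asarray(indices, dtype=int)), label)

    @classmethod
    def from_element(cls, ds: ConfigurationSet, symbol: str) -> "AtomSelection":
        """All atoms of one element, labeled by its symbol."""
        z = number_of(symbol)
        return cls(np.flatnonzero(ds.atomic_numbers == z), symbol)

    def __len__(self) -> int:
        return int(self.atom_indices.size)


# ---------------------------------------------------------------------------
# frame subsets

def make_subset(
    ds: ConfigurationSet, indices: Sequence[int], label: str = ""
) -> SubsetView:
    """Create a :class:`SubsetView`; duplicates removed, indices sorted."""
    idx = np.asarray(list(indices), dtype=int)
    for i in idx:
        if i < 0 or i >= ds.n_frames:
            raise IndexError(
                f"frame index {int(i)} out of range for {ds.n_frames}-frame set"
            )
    return SubsetView(ds, np.unique(idx), label)


def extract_subset(view: SubsetView) -> ConfigurationSet:
    """Materialize a :class:`SubsetView` as a standalone ConfigurationSet."""
    ds = view.parent
    idx = view.frame_indices
    return ConfigurationSet(
        atomic_numbers=ds.atomic_numbers.copy(),
        positions=ds.positions[idx],
        energies=None if ds.energies is None else ds.energies[idx],
        forces=None if ds.forces is None else ds.forces[idx],
        name=f"{ds.name}/{view.label}" if view.label else ds.name,
    )


# ---------------------------------------------------------------------------
# molecular formulas

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style molecular formula into element counts.

    >>> parse_formula("C24H42O21")
    {'C': 24, 'H': 42, 'O': 21}
    """
    if not formula:
        raise ValueError("empty formula")
    counts: dict[str, int] = {}
    pos = 0
    while pos < len(formula):
        m = _FORMULA_TOKEN.match(formula, pos)
        if m is None or m.start() != pos or not m.group(1):
            raise ValueError(f"cannot parse formula {formula!r} at position {pos}")
        sym, num = m.group(1), m.group(2)
        number_of(sym)  # raises for unknown symbols
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
        pos = m.end()
    return counts


def formula_atoms(formula: str) -> np.ndarray:
    """Atomic numbers of a formula's atoms, in formula order."""
    counts = parse_formula(formula)
    return np.concatenate(
        [np.full(c, number_of(sym), dtype=int) for sym, c in counts.items()]
    )


# ---------------------------------------------------------------------------
# extended XYZ

_KV_RE = re.compile(r'([A-Za-z_][A-Za-z0-9_]*)=("(?:[^"]*)"|\S+)')


def _parse_comment(comment: str) -> dict[str, str]:
    """key=value pairs from an extended-XYZ comment line (quotes stripped)."""
    out: dict[str, str] = {}
    for m in _KV_RE.finditer(comment):
        val = m.group(2)
        if val.startswith('"') and val.endswith('"'):
            val = val[1:-1]
        out[m.group(1)] = val
    return out


def _parse_properties(spec: str) -> list[tuple[str, str, int]]:
    toks = spec.split(":")
    if len(toks) % 3:
        raise TrajectoryFormatError(f"malformed Properties string {spec!r}")
    return [
        (toks[i], toks[i + 1], int(toks[i + 2])) for i in range(0, len(toks), 3)
    ]


def read_extxyz(path: str | Path) -> ConfigurationSet:
    """Read a (possibly multi-frame) extended-XYZ trajectory.

    The comment line's ``energy=`` key (case-insensitive) is taken as the
    frame energy and a per-atom ``forces`` (or ``force``) property block as
    the reference forces. Plain 4-column XYZ is accepted as a fallback.
    Unknown comment keys are preserved verbatim under
    ``metadata["comment_fields"]``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    pos_frames: list[np.ndarray] = []
    frc_frames: list[np.ndarray] = []
    energies: list[float] = []
    comment_fields: list[dict[str, str]] = []
    symbols_ref: list[str] | None = None
    have_energy = have_forces = True

    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError:
            raise TrajectoryFormatError(
                f"frame {frame}: expected atom count on line {i + 1}, "
                f"got {lines[i]!r}"
            ) from None
        if i + 1 + natoms >= len(lines) + 1 and natoms > 0:
            pass
        if i + 1 >= len(lines) or i + 1 + natoms > len(lines):
            raise TrajectoryFormatError(f"frame {frame}: truncated file")
        comment = lines[i + 1]
        kv = _parse_comment(comment)

        # frame energy: case-insensitive 'energy' key
        e_key = next((k for k in kv if k.lower() == "energy"), None)

        # column layout
        if "Properties" in kv or "properties" in kv:
            spec = kv.get("Properties", kv.get("properties", ""))
            props = _parse_properties(spec)
        else:
            props = [("species", "S", 1), ("pos", "R", 3)]

        symbols: list[str] = []
        frame_pos = np.empty((natoms, 3))
        frame_frc: np.ndarray | None = None
        extra_cols = {n for n, _, _ in props} - {"species", "pos"}
        for a in range(natoms):
            fields_ = lines[i + 2 + a].split()
            col = 0
            for name, _kind, ncol in props:
                vals = fields_[col : col + ncol]
                if len(vals) != ncol:
                    raise TrajectoryFormatError(
                        f"frame {frame}: atom line {a} has too few columns"
                    )
                if name == "species":
                    symbols.append(vals[0])
                elif name == "pos":
                    frame_pos[a] = [float(v) for v in vals]
                elif name in ("forces", "force"):
                    if frame_frc is None:
                        frame_frc = np.empty((natoms, 3))
                    frame_frc[a] = [float(v) for v in vals]
                col += ncol
            # plain-XYZ fallback with trailing force columns
            if not any(n in ("forces", "force") for n, _, _ in props) and len(
                fields_
            ) >= 7 and "Properties" not in kv and "properties" not in kv:
                if frame_frc is None:
                    frame_frc = np.empty((natoms, 3))
                frame_frc[a] = [float(v) for v in fields_[4:7]]

        if symbols_ref is None:
            symbols_ref = symbols
        elif symbols != symbols_ref:
            raise TrajectoryFormatError(
                f"frame {frame}: atom list differs from frame 0 "
                f"({len(symbols)} vs {len(symbols_ref)} atoms or changed order)"
            )

        pos_frames.append(frame_pos)
        if e_key is not None:
            energies.append(float(kv[e_key]))
        else:
            have_energy = False
        if frame_frc is not None:
            frc_frames.append(frame_frc)
        else:
            have_forces = False
        comment_fields.append(
            {
                k: v
                for k, v in kv.items()
                if k.lower() not in ("energy",) and k not in ("Properties", "properties")
            }
        )
        _ = extra_cols  # extra per-atom columns beyond forces are ignored on read
        i += 2 + natoms
        frame += 1

    if symbols_ref is None:
        raise TrajectoryFormatError("file contains no frames")
    z = np.array([number_of(s) for s in symbols_ref], dtype=int)
    meta: dict = {}
    if any(comment_fields):
        meta["comment_fields"] = comment_fields
    return ConfigurationSet(
        atomic_numbers=z,
        positions=np.stack(pos_frames),
        energies=np.array(energies) if have_energy and energies else None,
        forces=np.stack(frc_frames) if have_forces and frc_frames else None,
        name=path.stem,
        metadata=meta,
    )


def write_extxyz(
    ds: ConfigurationSet,
    path: str | Path,
    selection: SubsetView | None = None,
    extra_atom_column: tuple[str, np.ndarray] | None = None,
) -> None:
    """Write a trajectory (or a frame subset of it) as extended XYZ.

    ``extra_atom_column`` attaches one additional scalar per-atom property
    (name, (n_atoms,) values) to every written frame — used for per-atom
    error annotation.
    """
    path = Path(path)
    if selection is not None:
        if selection.parent is not ds:
            raise ValueError("selection does not reference this dataset")
        idx = selection.frame_indices
        if idx.size == 0:
            logger.warning("writing empty subset %r: zero-frame file", selection.label)
    else:
        idx = np.arange(ds.n_frames)

    symbols = ds.element_symbols
    props = "species:S:1:pos:R:3"
    if ds.forces is not None:
        props += ":forces:R:3"
    if extra_atom_column is not None:
        colname, colvals = extra_atom_column
        colvals = np.asarray(colvals, dtype=float)
        if colvals.shape != (ds.n_atoms,):
            raise ValueError("extra column must have one value per atom")
        props += f":{colname}:R:1"

    comment_fields = ds.metadata.get("comment_fields")
    with path.open("w") as fh:
        for f in idx:
            fh.write(f"{ds.n_atoms}\n")
            parts = [f"Properties={props}"]
            if ds.energies is not None:
                parts.append(f"energy={float(ds.energies[f])!r}")
            if comment_fields is not None and f < len(comment_fields):
                for k, v in comment_fields[f].items():
                    vq = f'"{v}"' if " " in v else v
                    parts.append(f"{k}={vq}")
            fh.write(" ".join(parts) + "\n")
            for a in range(ds.n_atoms):
                x, y, zc = ds.positions[f, a]
                line = f"{symbols[a]:<3s} {x:.17g} {y:.17g} {zc:.17g}"
                if ds.forces is not None:
                    fx, fy, fz = ds.forces[f, a]
                    line += f" {fx:.17g} {fy:.17g} {fz:.17g}"
                if extra_atom_column is not None:
                    line += f" {extra_atom_column[1][a]:.17g}"
                fh.write(line + "\n")


# ---------------------------------------------------------------------------
# NPZ bundles

_DEFAULT_KEYS = {"positions": "R", "atomic_numbers": "z", "energies": "E", "forces": "F"}


def read_npz_bundle(
    path: str | Path,
    key_map: Mapping[str, str] | None = None,
    energy_factor: float = 1.0,
    force_factor: float = 1.0,
) -> ConfigurationSet:
    """Read an MD17/MD22-style NPZ array bundle.

    ``key_map`` maps logical names (positions, atomic_numbers, energies,
    forces) to array names in the file; defaults cover the common R/z/E/F
    convention. ``energy_factor``/``force_factor`` convert input units to
    kcal/mol and kcal/(mol·Å).
    """
    path = Path(path)
    keys = dict(_DEFAULT_KEYS)
    if key_map:
        keys.update(key_map)
    with np.load(path, allow_pickle=False) as npz:
        names = set(npz.files)
        missing = [
            keys[k] for k in ("positions", "atomic_numbers") if keys[k] not in names
        ]
        if missing:
            raise TrajectoryFormatError(
                f"bundle {path.name} lacks mandatory arrays {missing}; found {sorted(names)}"
            )
        positions = np.asarray(npz[keys["positions"]], dtype=float)
        z = np.asarray(npz[keys["atomic_numbers"]], dtype=int).ravel()
        energies = (
            np.asarray(npz[keys["energies"]], dtype=float).ravel() * energy_factor
            if keys["energies"] in names
            else None
        )
        forces = (
            np.asarray(npz[keys["forces"]], dtype=float) * force_factor
            if keys["forces"] in names
            else None
        )
    if positions.ndim == 2:  # single frame stored flat
        positions = positions[None]
    if forces is not None and forces.ndim == 2:
        forces = forces[None]
    return ConfigurationSet(
        atomic_numbers=z,
        positions=positions,
        energies=energies,
        forces=forces,
        name=path.stem,
    )


def write_npz_bundle(
    ds: ConfigurationSet, path: str | Path, selection: SubsetView | None = None
) -> None:
    """Write a trajectory (or a frame subset) as an R/z/E/F NPZ bundle."""
    if selection is not None:
        if selection.parent is not ds:
            raise ValueError("selection does not reference this dataset")
        if len(selection) == 0:
            logger.warning("writing empty subset %r", selection.label)
        ds = extract_subset(selection)
    arrays: dict[str, np.ndarray] = {"R": ds.positions, "z": ds.atomic_numbers}
    if ds.energies is not None:
        arrays["E"] = ds.energies
    if ds.forces is not None:
        arrays["F"] = ds.forces
    np.savez(Path(path), **arrays)
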