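"""Geometric observables on trajectory frames.

The central observable is the radius of gyration (gyradius): the
root-mean-square, optionally mass-weighted, distance of the atoms from the
molecular centroid. It is small for folded/compact conformations and large
for extended ones, making its per-frame series a cheap folding/unfolding
monitor that requires no force-field model at all.

Also provided: distances (Å), bond angles (degrees, at the middle atom)
and dihedrals (degrees, IUPAC sign convention) for arbitrary atom tuples.
All observables are invariant under rigid rotation and translation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._elements import mass_of
from .trajio import ConfigurationSet

__all__ = ["GeometrySeries", "radius_of_gyration", "measure"]


@dataclass(frozen=True)
class GeometrySeries:
    """A named per-frame scalar observable (Å or degrees)."""

    name: str
    values: np.ndarray
    units: str

    def __len__(self) -> int:
        return int(self.values.size)


def radius_of_gyration(
    ds: ConfigurationSet, mass_weighted: bool = True
) -> GeometrySeries:
    """Per-frame radius of gyration, Å.

    R_g = sqrt( sum_i m_i |r_i - r_cm|^2 / sum_i m_i ) with r_cm the
    (mass-weighted) centroid; standard atomic masses are looked up from the
    element symbols. ``mass_weighted=False`` sets all m_i = 1.
    """
    if mass_weighted:
        m = np.array([mass_of(s) for s in ds.element_symbols])
    else:
        m = np.ones(ds.n_atoms)
    w = m / m.sum()
    com = np.einsum("a,fax->fx", w, ds.positions)
    delta = ds.positions - com[:, None, :]
    rg2 = np.einsum("a,fa->f", w, (delta**2).sum(axis=2))
    return GeometrySeries(
        name="gyradius" + ("" if mass_weighted else "_unweighted"),
        values=np.sqrt(rg2),
        units="Å",
    )


def measure(ds: ConfigurationSet, atom_indices: tuple[int, ...]) -> GeometrySeries:
    """Distance (2 indices), angle (3) or dihedral (4) series over frames.

    Angles are measured at the middle atom and lie in [0°, 180°];
    dihedrals follow the IUPAC sign convention and lie in (-180°, 180°].
    """
    idx = tuple(int(i) for i in atom_indices)
    if len(set(idx)) != len(idx):
        raise ValueError(f"repeated atom indices {idx}")
    for i in idx:
        if not 0 <= i < ds.n_atoms:
            raise IndexError(f"atom index {i} out of range")
    r = ds.positions[:, idx, :]  # (n_frames, len(idx), 3)

    if len(idx) == 2:
        vals = np.linalg.norm(r[:, 1] - r[:, 0], axis=1)
        return GeometrySeries(name=f"distance{idx}", values=vals, units="Å")

    if len(idx) == 3:
        u = r[:, 0] - r[:, 1]
        v = r[:, 2] - r[:, 1]
        cosang = np.einsum("fx,fx->f", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
        )
        vals = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        return GeometrySeries(name=f"angle{idx}", values=vals, units="deg")

    if len(idx) == 4:
        b1 = r[:, 1] - r[:, 0]
        b2 = r[:, 2] - r[:, 1]
        b3 = r[:, 3] - r[:, 2]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        if np.any(np.linalg.norm(n1, axis=1) < 1e-10) or np.any(
            np.linalg.norm(n2, axis=1) < 1e-10
        ):
            raise ValueError("undefined dihedral: three consecutive atoms collinear")
        b2_hat = b2 / np.linalg.norm(b2, axis=1, keepdims=True)
        x = np.einsum("fx,fx->f", n1, n2)
        y = np.einsum("fx,fx->f", np.cross(n1, n2), b2_hat)
        vals = np.degrees(np.arctan2(y, x))
        vals = np.where(vals <= -180.0, vals + 360.0, vals)
        return GeometrySeries(name=f"dihedral{idx}", values=vals, units="deg")

    raise ValueError("atom_indices must have length 2, 3 or 4")
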