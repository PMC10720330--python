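"""Synthetic trajectories and pseudo-predictions with planted structure.

Every analysis stage in this package is testable without external data:
this module generates multi-frame trajectories of a labeled molecule with
per-frame energies and per-atom forces, plus "prediction" streams whose
error structure is planted and therefore exactly known.

Model
-----
Geometries sit in one of ``n_basins`` harmonic basins: random reference
structures separated by at least ``basin_scale`` (root-mean-square per-atom
displacement, via mutually orthogonal displacement directions), visited in
contiguous blocks, with isotropic Gaussian thermal jitter of scale
``thermal_scale`` per frame. The reference energy is the harmonic-well
energy

    E(r) = k/2 * sum_i |r_i - ref_i|^2 + offset * basin,

and the reference forces are its exact analytic gradient,
``F = -k (r - ref)``. Harmonic energetics keep energies/forces analytic
and cheap — the analyses under test audit error bookkeeping, not dynamics
realism.

If ``fold_cycle`` is set, a global compactness factor oscillates with that
period (scaling the reference geometry), so the radius of gyration
oscillates like a folding/unfolding trajectory.

Predictions perturb the reference with Gaussian noise whose scale is
planted per element, per basin and optionally per atom, plus an optional
constant per-component bias and Gaussian energy noise. The half-normal
expectation E|N(0, σ)| = σ·sqrt(2/π) links a planted σ to its expected
MAE, which is how tests verify recovery quantitatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._elements import symbol_of
from .trajio import ConfigurationSet, PredictionRecord, formula_atoms, parse_formula

__all__ = [
    "FixtureSpec",
    "ErrorModelSpec",
    "generate_trajectory",
    "generate_predictions",
    "fixture_suite",
]

HALF_NORMAL_FACTOR = float(np.sqrt(2.0 / np.pi))  # E|N(0,σ)| = σ * this


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a synthetic trajectory.

    Parameters
    ----------
    formula : str
        Molecular formula, e.g. ``"C24H42O21"``.
    n_frames : int
    n_basins : int
        Number of distinct reference structures.
    basin_scale : float, Å
        RMS per-atom displacement separating basin references; for
        separability fixtures keep ``basin_scale > 3 * thermal_scale``.
    thermal_scale : float, Å
        Per-frame Gaussian jitter around the basin reference.
    fold_cycle : int or None
        Period (frames) of the global compactness oscillation; None
        disables folding.
    fold_amplitude : float
        Fractional compactness drop at the fold minimum (0 < a < 1).
    fold_phase : float
        Frame offset of the compactness cosine.
    spring_constant : float, kcal/(mol·Å²)
        Harmonic well stiffness; sets the force scale (~k * thermal_scale).
    basin_energy_offset : float, kcal/mol
        Constant energy offset between consecutive basins.
    seed : int
    """

    formula: str
    n_frames: int = 200
    n_basins: int = 1
    basin_scale: float = 2.0
    thermal_scale: float = 0.1
    fold_cycle: int | None = None
    fold_amplitude: float = 0.35
    fold_phase: float = 0.0
    spring_constant: float = 50.0
    basin_energy_offset: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1 or self.n_basins < 1:
            raise ValueError("n_frames and n_basins must be >= 1")
        if self.basin_scale <= 0 or self.thermal_scale < 0:
            raise ValueError("basin_scale must be > 0 and thermal_scale >= 0")
        if self.fold_cycle is not None and self.fold_cycle < 2:
            raise ValueError("fold_cycle must be >= 2 frames")
        if not 0 < self.fold_amplitude < 1:
            raise ValueError("fold_amplitude must lie in (0, 1)")


@dataclass(frozen=True)
class ErrorModelSpec:
    """Planted error structure for pseudo-predictions.

    ``element_scale`` maps element symbol to a force-error Gaussian scale
    (kcal/(mol·Å)); every element of the trajectory must be covered.
    ``basin_scale_factor`` and ``atom_scale_factor`` multiply that scale
    per basin / per atom index (default 1). ``bias`` is a constant added
    to every force component; ``energy_noise`` a Gaussian scale on frame
    energies (kcal/mol).
    """

    element_scale: dict[str, float]
    basin_scale_factor: dict[int, float] = field(default_factory=dict)
    atom_scale_factor: dict[int, float] = field(default_factory=dict)
    energy_noise: float = 0.0
    bias: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.element_scale.values()):
            raise ValueError("element scales must be >= 0")
        if self.energy_noise < 0:
            raise ValueError("energy_noise must be >= 0")


def _compactness(spec: FixtureSpec, frames: np.ndarray) -> np.ndarray:
    if spec.fold_cycle is None:
        return np.ones(frames.size)
    phase = 2 * np.pi * (frames - spec.fold_phase) / spec.fold_cycle
    return 1.0 - 0.5 * spec.fold_amplitude * (1.0 - np.cos(phase))


def generate_trajectory(spec: FixtureSpec) -> ConfigurationSet:
    """Generate a reproducible harmonic-basin trajectory from ``spec``.

    The returned set's ``metadata`` records the planted ground truth:
    ``basin_labels`` (per frame), ``compactness`` (per frame) and, when
    folding is on, ``folded_mask`` (compactness below its midpoint).
    """
    z = formula_atoms(spec.formula)
    n_atoms = z.size
    rng = np.random.default_rng(spec.seed)

    # base geometry: compact random cloud with ~molecular density
    extent = 1.2 * n_atoms ** (1.0 / 3.0)
    base = rng.normal(scale=extent, size=(n_atoms, 3))

    # mutually orthogonal displacement directions with unit RMS per atom,
    # so basins b and c sit basin_scale*sqrt(b^2+c^2) >= basin_scale apart
    if spec.n_basins > 1:
        raw = rng.normal(size=(3 * n_atoms, spec.n_basins - 1))
        q, _ = np.linalg.qr(raw)
        directions = q.T.reshape(spec.n_basins - 1, n_atoms, 3) * np.sqrt(n_atoms)
    basin_refs = [base]
    for b in range(1, spec.n_basins):
        basin_refs.append(base + b * spec.basin_scale * directions[b - 1])

    frames = np.arange(spec.n_frames)
    basin_labels = (frames * spec.n_basins) // spec.n_frames
    scale = _compactness(spec, frames)

    refs = np.stack([basin_refs[b] for b in basin_labels]) * scale[:, None, None]
    jitter = rng.normal(scale=spec.thermal_scale, size=refs.shape) \
        if spec.thermal_scale > 0 else np.zeros_like(refs)
    positions = refs + jitter

    k = spec.spring_constant
    disp = positions - refs
    energies = 0.5 * k * (disp**2).sum(axis=(1, 2)) + (
        spec.basin_energy_offset * basin_labels
    )
    forces = -k * disp

    meta: dict = {
        "basin_labels": basin_labels,
        "compactness": scale,
        "fixture_spec": spec,
    }
    if spec.fold_cycle is not None:
        meta["folded_mask"] = scale < (1.0 - 0.5 * spec.fold_amplitude - 1e-12)

    return ConfigurationSet(
        atomic_numbers=z,
        positions=positions,
        energies=energies,
        forces=forces,
        name=f"synthetic:{spec.formula}",
        metadata=meta,
    )


def generate_predictions(
    ds: ConfigurationSet, em: ErrorModelSpec
) -> PredictionRecord:
    """Perturb reference data into a pseudo-prediction with planted errors.

    Predicted force component = reference + bias +
    N(0, element_scale * basin_factor * atom_factor); predicted energy =
    reference + N(0, energy_noise). Fully reproducible from ``em.seed``.
    """
    if ds.forces is None or ds.energies is None:
        raise ValueError("dataset must carry reference energies and forces")
    symbols = [symbol_of(int(zi)) for zi in ds.atomic_numbers]
    missing = sorted(set(symbols) - set(em.element_scale))
    if missing:
        raise ValueError(f"element_scale lacks entries for {missing}")

    rng = np.random.default_rng(em.seed)
    atom_sigma = np.array(
        [
            em.element_scale[s] * em.atom_scale_factor.get(a, 1.0)
            for a, s in enumerate(symbols)
        ]
    )
    basins = np.asarray(ds.metadata.get("basin_labels", np.zeros(ds.n_frames, int)))
    frame_factor = np.array(
        [em.basin_scale_factor.get(int(b), 1.0) for b in basins]
    )
    sigma = frame_factor[:, None] * atom_sigma[None, :]  # (n_frames, n_atoms)

    noise = rng.normal(size=ds.forces.shape) * sigma[:, :, None]
    forces = ds.forces + em.bias + noise
    energies = ds.energies + (
        rng.normal(scale=em.energy_noise, size=ds.n_frames)
        if em.energy_noise > 0
        else 0.0
    )
    return PredictionRecord(
        source_id=f"planted:{em.seed}", energies=energies, forces=forces
    )


# ---------------------------------------------------------------------------
# named fixture suites mirroring the two case-study molecules

def fixture_suite(
    name: str, n_frames: int | None = None, seed: int = 0
) -> tuple[ConfigurationSet, PredictionRecord, dict]:
    """Ready-made (trajectory, prediction, ground truth) fixtures.

    ``stachyose_like`` — a C24H42O21-composition trajectory (87 atoms, three
    structural basins) whose designated "bond" atoms (a handful of carbons
    and oxygens, standing in for glycosidic-linkage atoms) carry an error
    scale inflated by a known factor over their elements' baseline.

    ``dha_like`` — a C22H32O2 trajectory (56 atoms) with an oscillating
    compactness factor; odd basins coincide with the folded phase and
    their error scale is inflated, so error timelines peak on folded
    frames.

    The returned ground-truth dict names the planted contrasts so tests
    can verify their recovery.
    """
    if name == "stachyose_like":
        n = 500 if n_frames is None else n_frames
        spec = FixtureSpec(
            formula="C24H42O21",
            n_frames=n,
            n_basins=3,
            basin_scale=2.0,
            thermal_scale=0.12,
            seed=seed,
        )
        ds = generate_trajectory(spec)
        counts = parse_formula(spec.formula)
        # atom order follows the formula: C block, H block, O block
        o_start = counts["C"] + counts["H"]
        bond_atoms = list(range(0, 6)) + list(range(o_start, o_start + 3))
        bond_factor = 1.5
        element_scale = {"H": 0.1, "C": 0.4, "O": 0.3}
        em = ErrorModelSpec(
            element_scale=element_scale,
            atom_scale_factor={a: bond_factor for a in bond_atoms},
            energy_noise=0.3,
            seed=seed + 1,
        )
        pred = generate_predictions(ds, em)
        truth = {
            "spec": spec,
            "error_model": em,
            "element_scale": element_scale,
            "bond_atoms": bond_atoms,
            "bond_factor": bond_factor,
        }
        return ds, pred, truth

    if name == "dha_like":
        n = 600 if n_frames is None else n_frames
        n_basins = 6
        block = n // n_basins
        spec = FixtureSpec(
            formula="C22H32O2",
            n_frames=n,
            n_basins=n_basins,
            basin_scale=2.0,
            thermal_scale=0.12,
            fold_cycle=2 * block,
            fold_phase=block / 2.0,
            fold_amplitude=0.4,
            seed=seed,
        )
        ds = generate_trajectory(spec)
        folded_basins = [b for b in range(n_basins) if b % 2 == 1]
        fold_factor = 3.0
        element_scale = {"H": 0.1, "C": 0.2, "O": 0.25}
        em = ErrorModelSpec(
            element_scale=element_scale,
            basin_scale_factor={b: fold_factor for b in folded_basins},
            energy_noise=0.3,
            seed=seed + 1,
        )
        pred = generate_predictions(ds, em)
        truth = {
            "spec": spec,
            "error_model": em,
            "element_scale": element_scale,
            "folded_basins": folded_basins,
            "fold_factor": fold_factor,
        }
        return ds, pred, truth

    raise ValueError(f"unknown fixture suite {name!r}")
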