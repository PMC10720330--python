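"""Error quantities: MAE/RMSE, per-element decompositions, densities,
timelines, correlation scatter, and distribution comparison.

Conventions
-----------
Two per-atom scalar conventions are exposed, because both appear in
practice and neither dominates:

``component_mae``
    the mean over the three Cartesian components of ``|F_pred - F_ref|``.
    Under this convention the atom-count-weighted mean of per-element MAEs
    reproduces the all-atom MAE exactly (the partition identity), which is
    how per-element error tables stay internally consistent with overall
    numbers.
``vector_norm``
    the Euclidean norm of the difference vector; natural for per-atom
    visualization and for the dummy (reference-magnitude) mode.

Energy errors are per molecule (kcal/mol), stored signed; consumers take
absolute values where appropriate.

For each convention the squared scalar used by RMSE is the matching one
(mean squared component / squared norm), so ``rmse >= mae`` holds for every
selection by Jensen's inequality, and squared errors recombine across any
disjoint partition of atoms or frames.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats

from .predictors import ErrorSourceMode
from .trajio import AtomSelection, ConfigurationSet, PredictionRecord, SubsetView

__all__ = [
    "ErrorConvention",
    "ErrorTable",
    "SummaryStats",
    "DensityCurve",
    "ScatterResult",
    "compute_error_table",
    "aggregate",
    "per_element_errors",
    "relative_errors",
    "timeline",
    "kde",
    "correlation_scatter",
    "compare_distributions",
]


class ErrorConvention(str, Enum):
    component_mae = "component_mae"
    vector_norm = "vector_norm"


@dataclass
class ErrorTable:
    """Per-frame per-atom scalar force errors and per-frame energy errors.

    ``atom_errors[f, a]`` is the scalar under ``convention`` (kcal/(mol·Å));
    ``atom_sq_errors`` is the matching squared scalar feeding RMSE;
    ``energy_errors`` is the signed per-frame energy difference (kcal/mol),
    or the reference energy itself in reference-magnitude mode.
    """

    atom_errors: np.ndarray
    atom_sq_errors: np.ndarray
    energy_errors: np.ndarray | None
    convention: ErrorConvention
    source_mode: ErrorSourceMode

    def __post_init__(self) -> None:
        if np.any(self.atom_errors < 0):
            raise ValueError("atom_errors must be nonnegative")
        if self.atom_errors.shape != self.atom_sq_errors.shape:
            raise ValueError("atom_errors / atom_sq_errors shape mismatch")

    @property
    def n_frames(self) -> int:
        return self.atom_errors.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.atom_errors.shape[1]


@dataclass(frozen=True)
class SummaryStats:
    """MAE / RMSE over a selection, with the sample count."""

    mae: float
    rmse: float
    n: int

    def __post_init__(self) -> None:
        # Jensen: root-mean-square dominates the mean for any sample
        if self.rmse < self.mae - 1e-12:
            raise ValueError(f"rmse {self.rmse} < mae {self.mae}")


@dataclass(frozen=True)
class DensityCurve:
    """A Gaussian kernel-density estimate evaluated on an even grid."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    label: str = ""

    def __post_init__(self) -> None:
        integral = float(np.trapezoid(self.density, self.grid))
        if not 0.99 <= integral <= 1.01:
            raise ValueError(f"density integrates to {integral:.4f}, not ~1")


@dataclass(frozen=True)
class ScatterResult:
    """Paired (true, predicted) values with robust outlier flags."""

    true: np.ndarray
    predicted: np.ndarray
    flagged: np.ndarray
    k: float

    @property
    def outlier_indices(self) -> np.ndarray:
        return np.flatnonzero(self.flagged)


def compute_error_table(
    ds: ConfigurationSet,
    pred: PredictionRecord,
    mode: ErrorSourceMode = ErrorSourceMode.model_vs_reference,
    convention: ErrorConvention | str = ErrorConvention.component_mae,
) -> ErrorTable:
    """Build the per-frame, per-atom error table for one dataset/model pair.

    In ``model_vs_reference`` mode the scalars summarise
    ``F_pred - F_ref`` per atom and ``E_pred - E_ref`` per frame (signed).
    In ``reference_magnitude`` mode they summarise the reference forces and
    energies themselves (dummy-model dataset auditing).
    """
    convention = ErrorConvention(convention)
    mode = ErrorSourceMode(mode)
    pred.validate_against(ds)

    if mode is ErrorSourceMode.reference_magnitude:
        if ds.forces is None or ds.energies is None:
            raise ValueError("reference_magnitude mode requires reference data")
        dF = ds.forces
        energy_errors = ds.energies.copy()
    else:
        if pred.forces is None:
            raise ValueError("prediction carries no forces")
        if ds.forces is None:
            raise ValueError(
                "model_vs_reference mode requires reference forces in the dataset"
            )
        dF = pred.forces - ds.forces
        if pred.energies is not None and ds.energies is not None:
            energy_errors = pred.energies - ds.energies
        else:
            energy_errors = None

    if convention is ErrorConvention.component_mae:
        atom_errors = np.mean(np.abs(dF), axis=2)
        atom_sq = np.mean(dF**2, axis=2)
    else:
        atom_errors = np.linalg.norm(dF, axis=2)
        atom_sq = atom_errors**2

    return ErrorTable(
        atom_errors=atom_errors,
        atom_sq_errors=atom_sq,
        energy_errors=energy_errors,
        convention=convention,
        source_mode=mode,
    )


def _select(table: ErrorTable, frames: SubsetView | None, atoms: AtomSelection | None):
    f_idx = frames.frame_indices if frames is not None else slice(None)
    a_idx = atoms.atom_indices if atoms is not None else slice(None)
    if frames is not None and frames.parent.n_frames != table.n_frames:
        raise ValueError("frame selection references a different dataset")
    sel = table.atom_errors[f_idx][:, a_idx]
    sel_sq = table.atom_sq_errors[f_idx][:, a_idx]
    return sel, sel_sq


def aggregate(
    table: ErrorTable,
    frames: SubsetView | None = None,
    atoms: AtomSelection | None = None,
) -> SummaryStats:
    """MAE and RMSE of the force errors over a frame/atom selection.

    MAE is the plain mean of the selected per-atom scalars; RMSE the root
    of the mean of the matching squared scalars, so restricting to all
    atoms and frames reproduces the overall numbers exactly and disjoint
    selections recombine by count weighting.
    """
    sel, sel_sq = _select(table, frames, atoms)
    if sel.size == 0:
        raise ValueError("empty selection: no atoms/frames selected")
    return SummaryStats(
        mae=float(sel.mean()), rmse=float(np.sqrt(sel_sq.mean())), n=int(sel.size)
    )


def energy_summary(table: ErrorTable, frames: SubsetView | None = None) -> SummaryStats:
    """MAE and RMSE of the per-frame energy errors (absolute values)."""
    if table.energy_errors is None:
        raise ValueError("error table carries no energy errors")
    e = table.energy_errors
    if frames is not None:
        e = e[frames.frame_indices]
    if e.size == 0:
        raise ValueError("empty frame selection")
    return SummaryStats(
        mae=float(np.abs(e).mean()),
        rmse=float(np.sqrt(np.mean(e**2))),
        n=int(e.size),
    )


def per_element_errors(
    table: ErrorTable, ds: ConfigurationSet
) -> dict[str, np.ndarray]:
    """Split the per-atom error samples by chemical element.

    Every atom contributes all of its frames to exactly one element's
    sample set; sample sizes sum to ``n_frames * n_atoms``.
    """
    if table.n_atoms != ds.n_atoms or table.n_frames != ds.n_frames:
        raise ValueError("error table is not aligned with the dataset")
    out: dict[str, np.ndarray] = {}
    symbols = np.array(ds.element_symbols)
    for sym in dict.fromkeys(ds.element_symbols):  # first-occurrence order
        cols = np.flatnonzero(symbols == sym)
        out[sym] = table.atom_errors[:, cols].ravel()
    return out


def relative_errors(table: ErrorTable, ds: ConfigurationSet) -> dict[str, np.ndarray]:
    """Per-element error samples normalized by that element's mean reference
    force-vector norm (over its atoms and all frames); dimensionless."""
    if ds.forces is None:
        raise ValueError("relative errors require reference forces")
    norms = np.linalg.norm(ds.forces, axis=2)  # (n_frames, n_atoms)
    out: dict[str, np.ndarray] = {}
    symbols = np.array(ds.element_symbols)
    for sym, samples in per_element_errors(table, ds).items():
        cols = np.flatnonzero(symbols == sym)
        mean_norm = float(norms[:, cols].mean())
        if mean_norm == 0.0:
            raise ValueError(f"mean reference force norm for {sym} is zero")
        out[sym] = samples / mean_norm
    return out


def timeline(series: np.ndarray, window: int = 1) -> np.ndarray:
    """Centered moving average of a per-frame scalar series.

    Near the edges the window truncates to the available frames, so the
    output has the input's length and no padding artifacts. ``window=1``
    is the identity.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if window == 1 or x.size == 0:
        return x.copy()
    kernel = np.ones(min(window, 2 * x.size - 1))
    sums = np.convolve(x, kernel, mode="same")
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return sums / counts


def kde(
    samples: np.ndarray,
    bandwidth: float | None = None,
    n_grid: int = 512,
    label: str = "",
) -> DensityCurve:
    """Gaussian kernel-density estimate of a 1-D sample.

    The default bandwidth is Scott's rule, ``h = std * n**(-1/5)``; an
    explicit ``bandwidth`` is the absolute kernel width in data units. The
    grid spans ``[min - 3h, max + 3h]`` so the curve integrates to ~1.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size < 2 or np.ptp(x) == 0.0:
        raise ValueError(
            "kde needs at least two distinct samples; use a histogram for "
            "degenerate data"
        )
    if n_grid < 2:
        raise ValueError("n_grid must be >= 2")
    std = float(np.std(x, ddof=1))
    if bandwidth is None:
        h = std * x.size ** (-1 / 5)
    else:
        if bandwidth <= 0:
            raise ValueError("bandwidth must be positive")
        h = float(bandwidth)
    estimator = stats.gaussian_kde(x, bw_method=h / std)
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, n_grid)
    return DensityCurve(grid=grid, density=estimator(grid), bandwidth=h, label=label)


def correlation_scatter(
    ds: ConfigurationSet,
    pred: PredictionRecord,
    quantity: str = "energy",
    k: float = 4.0,
) -> ScatterResult:
    """Paired (reference, predicted) values with robust outlier flags.

    ``quantity`` is ``"energy"`` (one pair per frame) or
    ``"force_component"`` (one pair per Cartesian force component, in
    dataset order). A point is flagged when its residual deviates from the
    median residual by more than ``k`` times the MAD-based robust scale
    (median absolute deviation x 1.4826); flags are invariant under adding
    a constant to both axes.
    """
    pred.validate_against(ds)
    if quantity == "energy":
        if ds.energies is None or pred.energies is None:
            raise ValueError("energy scatter requires energies on both sides")
        true, predicted = ds.energies, pred.energies
    elif quantity == "force_component":
        if ds.forces is None or pred.forces is None:
            raise ValueError("force scatter requires forces on both sides")
        true, predicted = ds.forces.ravel(), pred.forces.ravel()
    else:
        raise ValueError(f"unknown quantity {quantity!r}")

    residuals = predicted - true
    center = np.median(residuals)
    scale = 1.4826 * np.median(np.abs(residuals - center))
    flagged = np.abs(residuals - center) > k * scale
    return ScatterResult(
        true=np.asarray(true, dtype=float).copy(),
        predicted=np.asarray(predicted, dtype=float).copy(),
        flagged=flagged,
        k=k,
    )


def compare_distributions(
    full_samples: np.ndarray, subset_samples: np.ndarray, n_bins: int = 50
) -> dict[str, float]:
    """Quantify how representative a subset's distribution is of the full set.

    Returns the histogram intersection (sum of per-bin minima of the two
    probability-mass histograms on a shared grid over the pooled range;
    1 = identical, 0 = disjoint) and the two-sample Kolmogorov-Smirnov
    statistic. Applicable to force, energy or gyradius samples.
    """
    full = np.asarray(full_samples, dtype=float).ravel()
    sub = np.asarray(subset_samples, dtype=float).ravel()
    if full.size == 0 or sub.size == 0:
        raise ValueError("both sample sets must be nonempty")
    lo = min(full.min(), sub.min())
    hi = max(full.max(), sub.max())
    if hi == lo:  # all mass in one bin on both sides
        return {"histogram_intersection": 1.0, "ks_statistic": 0.0}
    edges = np.linspace(lo, hi, n_bins + 1)
    p, _ = np.histogram(full, bins=edges)
    q, _ = np.histogram(sub, bins=edges)
    inter = float(np.minimum(p / p.sum(), q / q.sum()).sum())
    ks = float(stats.ks_2samp(full, sub).statistic)
    return {"histogram_intersection": inter, "ks_statistic": ks}
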