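"""Prediction sources: prestored files, pluggable predictors, dummy mode.

Three ways of obtaining the model side of an error analysis:

* load predictions precomputed elsewhere and stored on disk
  (:func:`load_prestored_predictions`);
* evaluate any object satisfying the :class:`Predictor` contract in
  batches, persisting results to a cache so expensive models are run
  once (:func:`precompute_cache`);
* audit the reference data itself via the *dummy model*
  (:func:`reference_as_prediction`): downstream "error" quantities then
  equal the reference force magnitudes and energies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Protocol, runtime_checkable

import numpy as np

from .trajio import (
    ConfigurationSet,
    PredictionRecord,
    read_extxyz,
    read_npz_bundle,
)

__all__ = [
    "Predictor",
    "ErrorSourceMode",
    "StaleCacheError",
    "load_prestored_predictions",
    "precompute_cache",
    "reference_as_prediction",
]


@runtime_checkable
class Predictor(Protocol):
    """Adapter contract for any force-field backend.

    Implementations wrap an external model (an MLFF package, an empirical
    force field, anything callable on coordinates) behind two members:
    a stable ``identifier`` and a batched ``evaluate``.
    """

    identifier: str

    def evaluate(
        self, positions: np.ndarray, atomic_numbers: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """Map (n, n_atoms, 3) positions to ((n,) energies, (n, n_atoms, 3) forces)
        in kcal/mol and kcal/(mol·Å)."""
        ...


class ErrorSourceMode(str, Enum):
    """What the per-atom/per-frame scalars measure.

    ``model_vs_reference`` — prediction-minus-reference errors;
    ``reference_magnitude`` — the reference force norms / energies themselves
    (dummy-model mode, for auditing the dataset rather than a model).
    """

    model_vs_reference = "model_vs_reference"
    reference_magnitude = "reference_magnitude"


class StaleCacheError(RuntimeError):
    """A prediction cache exists but its fingerprint does not match the inputs."""


def load_prestored_predictions(
    path: str | Path, ds: ConfigurationSet, source_id: str | None = None
) -> PredictionRecord:
    """Load model energies/forces from an extXYZ or NPZ file, aligned to ``ds``.

    The file's frame and atom counts must match ``ds`` exactly; mismatches
    raise with both counts in the message.
    """
    path = Path(path)
    if path.suffix == ".npz":
        loaded = read_npz_bundle(path)
    else:
        loaded = read_extxyz(path)
    if loaded.n_frames != ds.n_frames:
        raise ValueError(
            f"prediction file has {loaded.n_frames} frames but dataset "
            f"{ds.name!r} has {ds.n_frames}"
        )
    if loaded.n_atoms != ds.n_atoms:
        raise ValueError(
            f"prediction file has {loaded.n_atoms} atoms but dataset has {ds.n_atoms}"
        )
    rec = PredictionRecord(
        source_id=source_id or path.stem,
        energies=loaded.energies,
        forces=loaded.forces,
    )
    rec.validate_against(ds)
    return rec


def _fingerprint(predictor_id: str, ds: ConfigurationSet) -> dict:
    return {
        "predictor": predictor_id,
        "dataset": ds.name,
        "n_frames": ds.n_frames,
        "n_atoms": ds.n_atoms,
    }


def precompute_cache(
    predictor: Predictor,
    ds: ConfigurationSet,
    cache_path: str | Path,
    batch_size: int = 64,
) -> PredictionRecord:
    """Evaluate ``predictor`` on ``ds`` in batches, caching the result.

    The cache is an NPZ bundle plus a JSON fingerprint
    (``<stem>.pred.npz`` / ``<stem>.pred.json``, keyed by dataset name,
    frame count and predictor identifier). A subsequent call with the same
    inputs loads from the cache without invoking the predictor; a cache
    whose fingerprint disagrees raises :class:`StaleCacheError` rather than
    being silently reused.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    cache_path = Path(cache_path)
    if cache_path.suffixes[-2:] == [".pred", ".npz"]:
        stem = cache_path.name[: -len(".pred.npz")]
        cache_path = cache_path.parent / stem
    npz_path = cache_path.with_name(cache_path.name + ".pred.npz")
    json_path = cache_path.with_name(cache_path.name + ".pred.json")

    fp = _fingerprint(predictor.identifier, ds)
    if npz_path.exists():
        if not json_path.exists():
            raise StaleCacheError(f"cache {npz_path} has no fingerprint file")
        stored = json.loads(json_path.read_text())
        if stored != fp:
            raise StaleCacheError(
                f"cache fingerprint {stored} does not match inputs {fp}"
            )
        with np.load(npz_path) as npz:
            return PredictionRecord(
                source_id=predictor.identifier,
                energies=npz["E"].copy(),
                forces=npz["F"].copy(),
            )

    energies = np.empty(ds.n_frames)
    forces = np.empty_like(ds.positions)
    for start in range(0, ds.n_frames, batch_size):
        stop = min(start + batch_size, ds.n_frames)
        e, f = predictor.evaluate(ds.positions[start:stop], ds.atomic_numbers)
        e = np.asarray(e, dtype=float)
        f = np.asarray(f, dtype=float)
        if e.shape != (stop - start,) or f.shape != (stop - start, ds.n_atoms, 3):
            raise ValueError(
                f"predictor {predictor.identifier!r} returned shapes "
                f"{e.shape}/{f.shape} for a {stop - start}-frame batch"
            )
        energies[start:stop] = e
        forces[start:stop] = f

    npz_path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(npz_path, E=energies, F=forces)
    json_path.write_text(json.dumps(fp, indent=1))
    return PredictionRecord(
        source_id=predictor.identifier, energies=energies, forces=forces
    )


def reference_as_prediction(
    ds: ConfigurationSet,
) -> tuple[PredictionRecord, ErrorSourceMode]:
    """Dummy-model mode: analyze the reference data itself.

    Returns the reference energies/forces repackaged as a prediction
    together with ``ErrorSourceMode.reference_magnitude``, under which the
    downstream per-atom scalar is the reference force-vector norm and the
    per-frame scalar the reference energy.
    """
    if ds.forces is None or ds.energies is None:
        raise ValueError(
            "reference_magnitude mode requires reference energies and forces"
        )
    rec = PredictionRecord(
        source_id=f"reference:{ds.name}",
        energies=ds.energies.copy(),
        forces=ds.forces.copy(),
    )
    return rec, ErrorSourceMode.reference_magnitude
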