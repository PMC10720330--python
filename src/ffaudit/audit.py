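"""Orchestration: the `ForceFieldAudit` model and its `AuditResults`.

`ForceFieldAudit` is built from a trajectory dataset and one or more
aligned prediction streams; ``fit()`` runs the full audit pipeline —
error tables, overall and per-element MAE/RMSE, error densities,
smoothed timelines, two-stage configurational clustering with ascending
error profiles, correlation scatter with robust outlier flags, gyradius
series, and (when a training subset is supplied) training-set
representativeness — and returns an `AuditResults` object carrying every
estimate, a ``summary()`` table, and exporters for JSON/CSV/plot files.

When several models audit one dataset, they share a single clustering so
their cluster error profiles are directly comparable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering as _clustering
from . import geometry as _geometry
from . import metrics as _metrics
from .metrics import ErrorConvention, ErrorTable, SummaryStats
from .predictors import ErrorSourceMode
from .trajio import (
    AtomSelection,
    ConfigurationSet,
    PredictionRecord,
    SubsetView,
    read_extxyz,
    read_npz_bundle,
    write_extxyz,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

__all__ = [
    "AuditConfig",
    "ForceFieldAudit",
    "AuditResults",
    "run_audit",
    "export_annotated_structure",
]


@dataclass
class AuditConfig:
    """File-level audit configuration (the CLI's view of a run)."""

    dataset: str
    predictions: list[str] = field(default_factory=list)
    train_subset: str | None = None
    out_dir: str = "audit_out"
    convention: str = "component_mae"
    window: int = 25
    n_clusters: int = 40
    n_structural: int = 10
    kde_bandwidth: float | None = None
    outlier_k: float = 4.0
    seed: int = 0
    mass_weighted_gyradius: bool = True

    def __post_init__(self) -> None:
        if not self.dataset:
            raise ValueError("at least one dataset is required")


def _load_any(path: str | Path) -> ConfigurationSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npz":
        return read_npz_bundle(path)
    return read_extxyz(path)


@dataclass
class ModelResult:
    """All per-model audit quantities."""

    source_id: str
    error_table: ErrorTable
    force_stats: SummaryStats
    energy_stats: SummaryStats | None
    per_element: dict[str, SummaryStats]
    densities: dict[str, _metrics.DensityCurve]
    force_timeline: np.ndarray
    energy_timeline: np.ndarray | None
    cluster_summaries: list[dict]
    cluster_profile: list[tuple[int, int, float]]
    energy_scatter: _metrics.ScatterResult | None
    force_scatter: _metrics.ScatterResult


class ForceFieldAudit:
    """Audit model: a dataset plus aligned prediction streams.

    Parameters
    ----------
    dataset : ConfigurationSet
        Trajectory with reference energies/forces.
    predictions : PredictionRecord or sequence thereof
        One stream per model under audit. Omit (None) to audit the
        reference data itself in dummy-model mode.
    convention : {"component_mae", "vector_norm"}
        Per-atom force-error scalar convention (see `ffaudit.metrics`).
    """

    def __init__(
        self,
        dataset: ConfigurationSet,
        predictions: PredictionRecord | list[PredictionRecord] | None = None,
        convention: str | ErrorConvention = ErrorConvention.component_mae,
        mode: str | ErrorSourceMode = ErrorSourceMode.model_vs_reference,
    ) -> None:
        self.dataset = dataset
        if predictions is None:
            from .predictors import reference_as_prediction

            rec, mode = reference_as_prediction(dataset)
            predictions = [rec]
        elif isinstance(predictions, PredictionRecord):
            predictions = [predictions]
        if not predictions:
            raise ValueError("at least one prediction stream is required")
        for p in predictions:
            p.validate_against(dataset)
        self.predictions = list(predictions)
        self.convention = ErrorConvention(convention)
        self.mode = ErrorSourceMode(mode)

    @classmethod
    def from_files(
        cls,
        dataset_path: str | Path,
        prediction_paths: list[str | Path],
        **kwargs,
    ) -> "ForceFieldAudit":
        """Build the model from an extXYZ/NPZ dataset and prediction files."""
        from .predictors import load_prestored_predictions

        ds = _load_any(dataset_path)
        preds = [load_prestored_predictions(p, ds) for p in prediction_paths]
        return cls(ds, preds, **kwargs)

    def fit(
        self,
        n_clusters: int = 40,
        n_structural: int = 10,
        window: int = 25,
        kde_bandwidth: float | None = None,
        outlier_k: float = 4.0,
        seed: int = 0,
        train_subset: SubsetView | ConfigurationSet | None = None,
        mass_weighted_gyradius: bool = True,
    ) -> "AuditResults":
        """Run every audit stage and return the results object.

        ``seed`` fixes all stochastic stages (KMeans initialization, any
        clustering subsample), making the report fully regenerable.
        """
        ds = self.dataset
        logger.info("stage=error_table computing error tables")
        tables = [
            _metrics.compute_error_table(ds, p, self.mode, self.convention)
            for p in self.predictions
        ]

        logger.info("stage=clustering two-stage clustering (shared across models)")
        assignment = _clustering.cluster_configurations(
            ds,
            errors=tables[0],
            n_total=n_clusters,
            n_structural=min(n_structural, n_clusters),
            seed=seed,
        )

        logger.info("stage=gyradius computing radius-of-gyration series")
        gyradius = _geometry.radius_of_gyration(
            ds, mass_weighted=mass_weighted_gyradius
        )

        models: list[ModelResult] = []
        for pred, table in zip(self.predictions, tables):
            logger.info("stage=metrics model=%s", pred.source_id)
            force_stats = _metrics.aggregate(table)
            energy_stats = (
                _metrics.energy_summary(table)
                if table.energy_errors is not None
                else None
            )
            per_element: dict[str, SummaryStats] = {}
            densities: dict[str, _metrics.DensityCurve] = {}
            for sym, samples in _metrics.per_element_errors(table, ds).items():
                sel = AtomSelection.from_element(ds, sym)
                per_element[sym] = _metrics.aggregate(table, atoms=sel)
                if np.ptp(samples) > 0:
                    densities[sym] = _metrics.kde(
                        samples, bandwidth=kde_bandwidth, label=sym
                    )
            force_per_frame = table.atom_errors.mean(axis=1)
            force_tl = _metrics.timeline(force_per_frame, window)
            energy_tl = (
                _metrics.timeline(np.abs(table.energy_errors), window)
                if table.energy_errors is not None
                else None
            )

            summaries = _clustering._summarize(
                assignment.labels, assignment.n_total, table
            )
            shared = _clustering.ClusterAssignment(
                labels=assignment.labels,
                structural_labels=assignment.structural_labels,
                n_structural=assignment.n_structural,
                n_total=assignment.n_total,
                summaries=summaries,
                descriptors=assignment.descriptors,
            )
            profile = _clustering.cluster_error_profile(shared, "force_mae")

            logger.info("stage=scatter model=%s", pred.source_id)
            energy_scatter = None
            if table.energy_errors is not None and pred.energies is not None \
                    and ds.energies is not None:
                energy_scatter = _metrics.correlation_scatter(
                    ds, pred, "energy", k=outlier_k
                )
            force_scatter = _metrics.correlation_scatter(
                ds, pred, "force_component", k=outlier_k
            )

            models.append(
                ModelResult(
                    source_id=pred.source_id,
                    error_table=table,
                    force_stats=force_stats,
                    energy_stats=energy_stats,
                    per_element=per_element,
                    densities=densities,
                    force_timeline=force_tl,
                    energy_timeline=energy_tl,
                    cluster_summaries=summaries,
                    cluster_profile=profile,
                    energy_scatter=energy_scatter,
                    force_scatter=force_scatter,
                )
            )

        train_comparison = None
        if train_subset is not None:
            logger.info("stage=train_comparison dataset-vs-training distributions")
            from .trajio import extract_subset

            sub = (
                extract_subset(train_subset)
                if isinstance(train_subset, SubsetView)
                else train_subset
            )
            train_comparison = _compare_training(ds, sub, mass_weighted_gyradius)

        config = {
            "convention": self.convention.value,
            "mode": self.mode.value,
            "n_clusters": n_clusters,
            "n_structural": n_structural,
            "window": window,
            "kde_bandwidth": kde_bandwidth,
            "outlier_k": outlier_k,
            "seed": seed,
            "mass_weighted_gyradius": mass_weighted_gyradius,
        }
        return AuditResults(
            dataset=ds,
            models=models,
            assignment=assignment,
            gyradius=gyradius,
            train_comparison=train_comparison,
            config=config,
        )


def _compare_training(
    ds: ConfigurationSet, train: ConfigurationSet, mass_weighted: bool
) -> dict[str, dict[str, float]]:
    """Training-set representativeness: force / energy / gyradius overlap."""
    out: dict[str, dict[str, float]] = {}
    if ds.forces is not None and train.forces is not None:
        out["forces"] = _metrics.compare_distributions(
            np.linalg.norm(ds.forces, axis=2).ravel(),
            np.linalg.norm(train.forces, axis=2).ravel(),
        )
    if ds.energies is not None and train.energies is not None:
        out["energies"] = _metrics.compare_distributions(ds.energies, train.energies)
    rg_full = _geometry.radius_of_gyration(ds, mass_weighted).values
    rg_train = _geometry.radius_of_gyration(train, mass_weighted).values
    out["gyradius"] = _metrics.compare_distributions(rg_full, rg_train)
    return out


class AuditResults:
    """Estimates and diagnostics from a fitted `ForceFieldAudit`.

    Every number here is regenerable from the inputs plus the recorded
    ``config`` (all stochastic stages are seeded).
    """

    def __init__(
        self,
        dataset: ConfigurationSet,
        models: list[ModelResult],
        assignment: _clustering.ClusterAssignment,
        gyradius: _geometry.GeometrySeries,
        train_comparison: dict | None,
        config: dict,
    ) -> None:
        self.dataset = dataset
        self.models = models
        self.assignment = assignment
        self.gyradius = gyradius
        self.train_comparison = train_comparison
        self.config = config

    # -- tables -------------------------------------------------------------

    def per_element_frame(self) -> pd.DataFrame:
        """Long-form per-element MAE/RMSE table across models."""
        rows = []
        for m in self.models:
            for sym, s in m.per_element.items():
                rows.append(
                    {"model": m.source_id, "element": sym,
                     "n": s.n, "mae": s.mae, "rmse": s.rmse}
                )
            rows.append(
                {"model": m.source_id, "element": "All",
                 "n": m.force_stats.n, "mae": m.force_stats.mae,
                 "rmse": m.force_stats.rmse}
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable audit summary table."""
        lines = [
            "Force-field audit summary",
            "=" * 25,
            f"dataset: {self.dataset.name}  "
            f"({self.dataset.n_frames} frames x {self.dataset.n_atoms} atoms)",
            f"convention: {self.config['convention']}   "
            f"clusters: {self.assignment.n_total} "
            f"({self.assignment.n_structural} structural)",
            "",
        ]
        for m in self.models:
            lines.append(f"model {m.source_id}")
            if m.energy_stats is not None:
                lines.append(
                    f"  energy  MAE {m.energy_stats.mae:8.4f}  "
                    f"RMSE {m.energy_stats.rmse:8.4f}  kcal/mol"
                )
            lines.append(
                f"  forces  MAE {m.force_stats.mae:8.4f}  "
                f"RMSE {m.force_stats.rmse:8.4f}  kcal/(mol·Å)"
            )
            for sym, s in m.per_element.items():
                lines.append(
                    f"    {sym:<2s}    MAE {s.mae:8.4f}  RMSE {s.rmse:8.4f}"
                    f"   (n={s.n})"
                )
            worst = m.cluster_profile[-1]
            best = m.cluster_profile[0]
            lines.append(
                f"  clusters: best {best[0]} (MAE {best[2]:.4f}), "
                f"worst {worst[0]} (MAE {worst[2]:.4f})"
            )
            n_out = int(m.force_scatter.flagged.sum())
            lines.append(f"  flagged force-component outliers: {n_out}")
            lines.append("")
        if self.train_comparison is not None:
            lines.append("training-set representativeness "
                         "(histogram intersection / KS):")
            for key, v in self.train_comparison.items():
                lines.append(
                    f"  {key:<9s} {v['histogram_intersection']:.3f} / "
                    f"{v['ks_statistic']:.3f}"
                )
            lines.append("")
        return "\n".join(lines)

    # -- serialisation ------------------------------------------------------

    def to_report_dict(self) -> dict:
        """JSON-serialisable report (schema-versioned)."""
        def stats(s: SummaryStats | None):
            return None if s is None else {"mae": s.mae, "rmse": s.rmse, "n": s.n}

        report: dict = {
            "schema_version": SCHEMA_VERSION,
            "dataset": {
                "name": self.dataset.name,
                "n_frames": self.dataset.n_frames,
                "n_atoms": self.dataset.n_atoms,
            },
            "config": self.config,
            "clusters": {
                "n_total": self.assignment.n_total,
                "n_structural": self.assignment.n_structural,
                "sizes": [s["size"] for s in self.assignment.summaries],
            },
            "models": [],
        }
        for m in self.models:
            report["models"].append(
                {
                    "source_id": m.source_id,
                    "force": stats(m.force_stats),
                    "energy": stats(m.energy_stats),
                    "per_element": {k: stats(v) for k, v in m.per_element.items()},
                    "cluster_profile": [
                        {"cluster": c, "size": n, "force_mae": v}
                        for c, n, v in m.cluster_profile
                    ],
                    "n_energy_outliers": (
                        None
                        if m.energy_scatter is None
                        else int(m.energy_scatter.flagged.sum())
                    ),
                    "n_force_outliers": int(m.force_scatter.flagged.sum()),
                }
            )
        if self.train_comparison is not None:
            report["train_comparison"] = self.train_comparison
        return report

    def save(self, out_dir: str | Path, plots: bool = True) -> dict:
        """Write the report JSON, CSV tables and (best-effort) plots.

        Returns the file manifest. Any stage failure removes partial
        outputs and re-raises with the stage name; plotting failures only
        degrade the run to CSV output with a warning.
        """
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest: list[str] = []
        try:
            self._write_tables(out, manifest)
            if plots:
                try:
                    self._write_plots(out, manifest)
                except Exception:  # degrade, never abort on plotting
                    logger.warning(
                        "stage=plots plotting failed; report is CSV/JSON only",
                        exc_info=True,
                    )
            report = self.to_report_dict()
            report["manifest"] = sorted(manifest + ["report.json"])
            (out / "report.json").write_text(
                json.dumps(report, indent=1, sort_keys=True)
            )
        except Exception as exc:
            logger.error("stage=save aborting, removing partial outputs: %s", exc)
            for name in manifest:
                (out / name).unlink(missing_ok=True)
            raise
        return report

    def _write_tables(self, out: Path, manifest: list[str]) -> None:
        logger.info("stage=tables writing CSV tables")
        self.per_element_frame().to_csv(out / "per_element.csv", index=False)
        manifest.append("per_element.csv")

        assign = pd.DataFrame(
            {
                "frame_index": np.arange(self.dataset.n_frames),
                "structural_label": self.assignment.structural_labels,
                "cluster_label": self.assignment.labels,
            }
        )
        assign.to_csv(out / "cluster_assignment.csv", index=False)
        manifest.append("cluster_assignment.csv")

        for m in self.models:
            tag = _safe(m.source_id)
            prof = pd.DataFrame(
                m.cluster_profile, columns=["cluster", "size", "force_mae"]
            )
            prof["energy_mae"] = [
                m.cluster_summaries[c]["energy_mae"] for c in prof["cluster"]
            ]
            prof.to_csv(out / f"cluster_profile_{tag}.csv", index=False)
            manifest.append(f"cluster_profile_{tag}.csv")

            tl = pd.DataFrame({"frame": np.arange(len(m.force_timeline)),
                               "force_mae": m.force_timeline})
            if m.energy_timeline is not None:
                tl["energy_abs_error"] = m.energy_timeline
            tl.to_csv(out / f"timeline_{tag}.csv", index=False)
            manifest.append(f"timeline_{tag}.csv")

            for sym, curve in m.densities.items():
                pd.DataFrame({"grid": curve.grid, "density": curve.density}).to_csv(
                    out / f"density_{tag}_{sym}.csv", index=False
                )
                manifest.append(f"density_{tag}_{sym}.csv")

        pd.DataFrame(
            {"frame": np.arange(len(self.gyradius)), "gyradius": self.gyradius.values}
        ).to_csv(out / "gyradius.csv", index=False)
        manifest.append("gyradius.csv")

    def _write_plots(self, out: Path, manifest: list[str]) -> None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        logger.info("stage=plots writing figures")
        # per-element error densities
        fig, ax = plt.subplots(figsize=(6, 4))
        for m in self.models:
            for sym, curve in m.densities.items():
                ax.plot(curve.grid, curve.density, label=f"{m.source_id}:{sym}")
        ax.set_xlabel("force error, kcal/(mol·Å)")
        ax.set_ylabel("density")
        if any(m.densities for m in self.models):
            ax.legend(fontsize=6)
        fig.savefig(out / "densities.png", dpi=120)
        plt.close(fig)
        manifest.append("densities.png")

        # timelines + gyradius overlay
        fig, ax = plt.subplots(figsize=(7, 4))
        for m in self.models:
            ax.plot(m.force_timeline, label=f"{m.source_id} force MAE")
        ax2 = ax.twinx()
        ax2.plot(self.gyradius.values, color="gray", alpha=0.5, label="gyradius")
        ax.set_xlabel("frame")
        ax.set_ylabel("force MAE, kcal/(mol·Å)")
        ax2.set_ylabel("gyradius, Å")
        ax.legend(fontsize=6)
        fig.savefig(out / "timeline.png", dpi=120)
        plt.close(fig)
        manifest.append("timeline.png")

        # ascending cluster error bars
        fig, ax = plt.subplots(figsize=(7, 4))
        width = 0.8 / len(self.models)
        for i, m in enumerate(self.models):
            vals = [v for _, _, v in m.cluster_profile]
            ax.bar(
                np.arange(len(vals)) + i * width, vals, width, label=m.source_id
            )
        ax.set_xlabel("cluster (ascending error)")
        ax.set_ylabel("force MAE, kcal/(mol·Å)")
        ax.legend(fontsize=6)
        fig.savefig(out / "cluster_errors.png", dpi=120)
        plt.close(fig)
        manifest.append("cluster_errors.png")

        # correlation scatter (energies when available)
        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        for m in self.models:
            sc = m.energy_scatter or m.force_scatter
            ax.plot(sc.true, sc.predicted, ".", ms=2, label=m.source_id)
            ax.plot(
                sc.true[sc.flagged], sc.predicted[sc.flagged], "rx", ms=5
            )
        ax.set_xlabel("reference")
        ax.set_ylabel("predicted")
        ax.legend(fontsize=6)
        fig.savefig(out / "scatter.png", dpi=120)
        plt.close(fig)
        manifest.append("scatter.png")


def _safe(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_" for c in name)


def run_audit(config: AuditConfig) -> dict:
    """Execute a full audit from file paths; returns the report dict.

    Thin functional wrapper over ``ForceFieldAudit(...).fit(...).save(...)``.
    """
    logger.info("stage=load dataset=%s", config.dataset)
    model = ForceFieldAudit.from_files(
        config.dataset, config.predictions, convention=config.convention
    )
    train = None
    if config.train_subset:
        train = _load_any(config.train_subset)
        if train.n_atoms != model.dataset.n_atoms:
            raise ValueError(
                "training subset atom count does not match the dataset"
            )
    results = model.fit(
        n_clusters=config.n_clusters,
        n_structural=config.n_structural,
        window=config.window,
        kde_bandwidth=config.kde_bandwidth,
        outlier_k=config.outlier_k,
        seed=config.seed,
        train_subset=train,
    )
    return results.save(config.out_dir)


# ---------------------------------------------------------------------------
# annotated structure export

_PDB_ATOM = (
    "ATOM  {serial:>5d} {name:<4s} MOL A   1    "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {el:>2s}\n"
)


def export_annotated_structure(
    ds: ConfigurationSet,
    table: ErrorTable,
    path: str | Path,
    frames: SubsetView | str = "mean",
    fmt: str = "extxyz_extra_column",
) -> None:
    """Write a structure whose atoms carry their mean force error.

    The per-atom scalar is the mean of ``table.atom_errors`` over the
    selected frames (pass a vector-norm table for the conventional
    per-atom visualization). ``extxyz_extra_column`` appends a scalar
    column to every selected frame; ``pdb_bfactor`` writes a single-frame
    PDB with the scalar in the B-factor field (clamped to the field
    width) for standard structure viewers.
    """
    if table.n_frames != ds.n_frames or table.n_atoms != ds.n_atoms:
        raise ValueError("error table is not aligned with the dataset")
    if isinstance(frames, str):
        if frames != "mean":
            raise ValueError(f"frames must be a SubsetView or 'mean', got {frames!r}")
        idx = np.arange(ds.n_frames)
    else:
        idx = frames.frame_indices
        if idx.size == 0:
            raise ValueError("empty frame selection")
    values = table.atom_errors[idx].mean(axis=0)

    if fmt == "extxyz_extra_column":
        if isinstance(frames, SubsetView):
            write_extxyz(ds, path, selection=frames,
                         extra_atom_column=("error", values))
        else:
            write_extxyz(ds, path, extra_atom_column=("error", values))
    elif fmt == "pdb_bfactor":
        f0 = int(idx[0])
        symbols = ds.element_symbols
        with Path(path).open("w") as fh:
            fh.write("REMARK   per-atom mean force error in B-factor column\n")
            for a in range(ds.n_atoms):
                x, y, z = ds.positions[f0, a]
                b = float(np.clip(values[a], 0.0, 999.99))
                fh.write(
                    _PDB_ATOM.format(
                        serial=a + 1,
                        name=f"{symbols[a]}{a % 100}",
                        x=x, y=y, z=z, occ=1.0, b=b, el=symbols[a],
                    )
                )
            fh.write("END\n")
    else:
        raise ValueError(f"unsupported format {fmt!r}")
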