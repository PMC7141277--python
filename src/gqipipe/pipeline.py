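"""End-to-end orchestration: simulate -> reconstruct -> featurize -> classify.

Every stage writes standard-format artifacts (NIfTI index maps, CSV feature
matrices, CSV metric tables and ROC points) under one output directory, and
a run manifest records files and seeds.  All randomness derives from a
single global seed, so a rerun with the same configuration reproduces the
metric tables byte for byte; the classification stage can be rerun alone
from the saved feature matrices.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .autoencoder import (
    AEConfig,
    PRUNED_SHAPE,
    TEMPLATE_SHAPE,
    build_autoencoder,
    encode_and_flatten,
    normalize_intensity,
    prune_volume,
    train_autoencoder,
    FeatureMatrix,
)
from .gqi import GQIConfig, build_index_maps
from .io import index_map_filename, load_index_map, save_index_map
from .protocol import (
    ClassifierSpec,
    aggregate_iterations,
    imbalance_ratio,
    run_iterations,
    split_nonideation_halves,
)
from .synthetic import CohortSpec, iter_cohort, save_dwi, load_dwi

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "stage_simulate_reconstruct",
    "stage_featurize",
    "stage_classify",
    "small_pipeline_config",
    "recovery_experiment_config",
]

log = logging.getLogger("gqipipe")

GEOMETRIES = ("small", "paper")


@dataclass(frozen=True)
class PipelineConfig:
    """Declarative description of a full run."""

    cohort: CohortSpec
    outdir: Path
    gqi: GQIConfig = field(default_factory=GQIConfig)
    ae: AEConfig | None = None  # input_shape derived from geometry when None
    classifiers: tuple[ClassifierSpec, ...] = (
        ClassifierSpec(kind="xgb"),
        ClassifierSpec(kind="lr"),
    )
    index_types: tuple[str, ...] = ("GFA", "ISO", "NQA")
    random_states: tuple[int, ...] = tuple(range(10))
    halves: tuple[int, ...] = (1, 2)
    seed: int = 0
    geometry: str = "small"
    save_dwi: bool = False

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {GEOMETRIES}")
        expected = PRUNED_SHAPE if self.geometry == "paper" else self.cohort.grid_shape
        if self.geometry == "paper" and tuple(self.cohort.grid_shape) != TEMPLATE_SHAPE:
            raise ValueError(f"paper geometry requires the {TEMPLATE_SHAPE} template grid")
        ae = self.ae
        if ae is None:
            ae = AEConfig(input_shape=expected)
        elif tuple(ae.input_shape) != tuple(expected):
            raise ValueError(
                f"ae.input_shape {ae.input_shape} inconsistent with geometry "
                f"'{self.geometry}' (expected {expected})"
            )
        object.__setattr__(self, "ae", ae)
        object.__setattr__(self, "outdir", Path(self.outdir))
        if not self.index_types or any(t not in ("GFA", "ISO", "NQA") for t in self.index_types):
            raise ValueError("index_types must be a non-empty subset of GFA/ISO/NQA")

    # -- derived seeds -----------------------------------------------------
    def _derived_seeds(self) -> dict[str, int]:
        state = np.random.SeedSequence(self.seed).generate_state(4)
        keys = ("cohort", "ae", "halves", "misc")
        return {k: int(s % (2**31)) for k, s in zip(keys, state)}

    # -- (de)serialization -------------------------------------------------
    @classmethod
    def from_dict(cls, raw: Mapping, outdir: str | Path | None = None) -> "PipelineConfig":
        raw = dict(raw)
        if "cohort" not in raw:
            raise ValueError("configuration must contain a 'cohort' block")
        cohort_kw = dict(raw["cohort"])
        for key in ("grid_shape", "shell_bvalues", "affected_groups"):
            if key in cohort_kw:
                cohort_kw[key] = tuple(cohort_kw[key])
        cohort = CohortSpec(**cohort_kw)
        gqi = GQIConfig(**raw.get("gqi", {}))
        geometry = raw.get("geometry", "small")
        ae_kw = dict(raw.get("ae", {}))
        if "input_shape" in ae_kw:
            ae_kw["input_shape"] = tuple(ae_kw["input_shape"])
        else:
            ae_kw["input_shape"] = (
                PRUNED_SHAPE if geometry == "paper" else cohort.grid_shape
            )
        ae = AEConfig(**ae_kw)
        classifiers = tuple(
            ClassifierSpec(**c) for c in raw.get("classifiers", [{"kind": "xgb"}, {"kind": "lr"}])
        )
        out = outdir or raw.get("outdir")
        if out is None:
            raise ValueError("an output directory is required")
        return cls(
            cohort=cohort,
            gqi=gqi,
            ae=ae,
            classifiers=classifiers,
            index_types=tuple(raw.get("index_types", ("GFA", "ISO", "NQA"))),
            random_states=tuple(raw.get("random_states", range(10))),
            halves=tuple(raw.get("halves", (1, 2))),
            seed=int(raw.get("seed", 0)),
            geometry=geometry,
            save_dwi=bool(raw.get("save_dwi", False)),
            outdir=Path(out),
        )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        return cls.from_dict(raw)


@dataclass
class RunManifest:
    """Files, seeds and versions produced by a run."""

    outdir: Path
    seeds: dict[str, int] = field(default_factory=dict)
    stages: dict[str, dict] = field(default_factory=dict)
    versions: dict[str, str] = field(default_factory=dict)
    timestamps: dict[str, float] = field(default_factory=dict)

    def add_stage(self, name: str, files: dict) -> None:
        self.stages[name] = files
        self.timestamps[name] = time.time()

    def all_files(self) -> list[Path]:
        out: list[Path] = []

        def walk(obj):
            if isinstance(obj, (str, Path)):
                out.append(Path(obj))
            elif isinstance(obj, Mapping):
                for v in obj.values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        for files in self.stages.values():
            walk(files)
        return out

    def save(self) -> Path:
        path = Path(self.outdir) / "manifest.json"
        payload = {
            "outdir": str(self.outdir),
            "seeds": self.seeds,
            "stages": json.loads(json.dumps(self.stages, default=str)),
            "versions": self.versions,
            "timestamps": self.timestamps,
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


def _versions() -> dict[str, str]:
    import importlib.metadata as md

    out = {}
    for pkg in ("gqipipe", "numpy", "scikit-learn", "xgboost", "nibabel"):
        try:
            out[pkg] = md.version(pkg)
        except md.PackageNotFoundError:
            out[pkg] = "unknown"
    return out


# ---------------------------------------------------------------------------
# stages


def stage_simulate_reconstruct(config: PipelineConfig) -> pd.DataFrame:
    """Generate the cohort and write per-subject index maps (streamed, so a
    full cohort never resides in memory at once)."""
    t0 = time.time()
    seeds = config._derived_seeds()
    spec = dataclasses.replace(config.cohort, seed=seeds["cohort"])
    maps_dir = config.outdir / "maps"
    maps_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    n = 0
    for subject in iter_cohort(spec):
        row = {"subject_id": subject.subject_id, "group": subject.group, "seed": seeds["cohort"]}
        if config.save_dwi:
            paths = save_dwi(subject.dwi, config.outdir / "dwi" / subject.subject_id)
            row.update({k: str(v) for k, v in paths.items()})
        gfa, iso, nqa = build_index_maps(subject.dwi, config.gqi)
        for imap in (gfa, iso, nqa):
            path = save_index_map(
                imap, maps_dir / index_map_filename(subject.subject_id, imap.map_type)
            )
            row[f"map_{imap.map_type}"] = str(path)
        rows.append(row)
        n += 1
    manifest = pd.DataFrame(rows)
    manifest.to_csv(config.outdir / "cohort_manifest.csv", index=False)
    log.info(
        "stage=simulate_reconstruct subjects=%d maps=%d seed=%d elapsed=%.1fs",
        n, 3 * n, seeds["cohort"], time.time() - t0,
    )
    return manifest


def stage_reconstruct_from_disk(config: PipelineConfig) -> pd.DataFrame:
    """Rebuild index maps from previously saved DWI files (CLI staged mode)."""
    t0 = time.time()
    manifest = pd.read_csv(config.outdir / "cohort_manifest.csv")
    maps_dir = config.outdir / "maps"
    maps_dir.mkdir(parents=True, exist_ok=True)
    for i, row in manifest.iterrows():
        dwi = load_dwi(row["dwi"], row["bval"], row["bvec"])
        for imap in build_index_maps(dwi, config.gqi):
            path = save_index_map(
                imap, maps_dir / index_map_filename(row["subject_id"], imap.map_type)
            )
            manifest.loc[i, f"map_{imap.map_type}"] = str(path)
    manifest.to_csv(config.outdir / "cohort_manifest.csv", index=False)
    log.info("stage=reconstruct subjects=%d elapsed=%.1fs", len(manifest), time.time() - t0)
    return manifest


def stage_featurize(
    config: PipelineConfig, manifest: pd.DataFrame | None = None
) -> dict[str, dict[str, str]]:
    """Train one autoencoder per index type on every subject's map (all four
    groups) and write flattened bottleneck features as CSV."""
    t0 = time.time()
    if manifest is None:
        manifest = pd.read_csv(config.outdir / "cohort_manifest.csv")
    seeds = config._derived_seeds()
    out: dict[str, dict[str, str]] = {}
    for t_idx, index_type in enumerate(config.index_types):
        vols = []
        for path in manifest[f"map_{index_type}"]:
            vol = load_index_map(path).data
            if config.geometry == "paper":
                vol = prune_volume(vol)
            vols.append(normalize_intensity(vol))
        ae_cfg = dataclasses.replace(config.ae, seed=int((seeds["ae"] + t_idx) % 2**31))
        model = build_autoencoder(ae_cfg)
        model, history = train_autoencoder(model, vols, ae_cfg)
        features = encode_and_flatten(model, vols, subject_ids=list(manifest["subject_id"]))
        feat_path = config.outdir / f"features_{index_type}.csv"
        features.to_csv(feat_path)
        ckpt_path = config.outdir / f"ae_{index_type}.npz"
        model.save(ckpt_path)
        hist_path = config.outdir / f"ae_history_{index_type}.csv"
        pd.DataFrame({"epoch": range(1, len(history) + 1), "loss": history}).to_csv(
            hist_path, index=False
        )
        out[index_type] = {
            "features": str(feat_path),
            "checkpoint": str(ckpt_path),
            "history": str(hist_path),
        }
        log.info(
            "stage=featurize index=%s subjects=%d epochs=%d final_loss=%s",
            index_type, len(vols), len(history), history[-1] if history else "n/a",
        )
    log.info("stage=featurize elapsed=%.1fs", time.time() - t0)
    return out


def _metric_table(reports_rows: list[dict]) -> pd.DataFrame:
    cols = ["model", "index_type", "half_id"]
    metric_cols = [f"{part}_{m}" for part in ("CV", "Test") for m in ("ACC", "SEN", "SPE", "AUC")]
    df = pd.DataFrame(reports_rows)
    extra = [c for c in df.columns if c not in cols + metric_cols]
    return df[cols + metric_cols + extra].round(6)


def stage_classify(
    config: PipelineConfig, manifest: pd.DataFrame | None = None
) -> dict[str, str]:
    """Half-split the non-ideation subjects, run the iterated 4:1:1 protocol
    for every index type x half x classifier, and write metric tables."""
    t0 = time.time()
    if manifest is None:
        manifest = pd.read_csv(config.outdir / "cohort_manifest.csv")
    seeds = config._derived_seeds()
    nonideation = [
        (r.subject_id, r.group)
        for r in manifest.itertuples()
        if r.group in ("HC", "NS")
    ]
    si_ids = [r.subject_id for r in manifest.itertuples() if r.group == "SI"]
    halves = split_nonideation_halves(nonideation, seed=seeds["halves"])

    averaged_rows, best_rows, iter_rows = [], [], []
    roc_paths: dict[str, str] = {}
    for index_type in config.index_types:
        features = FeatureMatrix.from_csv(config.outdir / f"features_{index_type}.csv")
        by_id = {sid: i for i, sid in enumerate(features.subject_ids)}
        for half_id in config.halves:
            half_ids = [sid for sid, _ in halves[half_id - 1]]
            task_ids = half_ids + si_ids
            rows_idx = [by_id[s] for s in task_ids]
            X = features.values[rows_idx]
            y = [1 if s in si_ids else 0 for s in task_ids]
            for spec in config.classifiers:
                reports = run_iterations(
                    X, y, spec,
                    random_states=config.random_states,
                    half_id=half_id,
                    extra_labels={"index_type": index_type},
                )
                averaged, best = aggregate_iterations(reports)
                averaged_rows.append(averaged.row())
                best_rows.append(best.row())
                iter_rows += [r.row() for r in reports]
                roc_path = config.outdir / f"roc_{spec.kind}_{index_type}_{half_id}.csv"
                fpr, tpr = best.test.roc
                pd.DataFrame({"fpr": fpr, "tpr": tpr}).to_csv(roc_path, index=False)
                roc_paths[f"{spec.kind}_{index_type}_{half_id}"] = str(roc_path)
                log.info(
                    "stage=classify model=%s index=%s half=%d mean_test_auc=%.3f",
                    spec.kind, index_type, half_id, averaged.test.auc,
                )
    paths = {
        "table_averaged": str(config.outdir / "table_averaged.csv"),
        "table_best": str(config.outdir / "table_best.csv"),
        "iterations": str(config.outdir / "iterations.csv"),
    }
    _metric_table(averaged_rows).to_csv(paths["table_averaged"], index=False)
    _metric_table(best_rows).to_csv(paths["table_best"], index=False)
    _metric_table(iter_rows).to_csv(paths["iterations"], index=False)
    ratio_all = imbalance_ratio(
        [1 if r.group == "SI" else 0 for r in manifest.itertuples() if r.group != "SA"]
    )
    summary = {
        "imbalance_ratio_full": round(ratio_all, 2),
        "half_seed": seeds["halves"],
        "random_states": list(config.random_states),
    }
    (config.outdir / "classify_summary.json").write_text(json.dumps(summary, indent=2))
    paths["summary"] = str(config.outdir / "classify_summary.json")
    paths.update({f"roc_{k}": v for k, v in roc_paths.items()})
    log.info("stage=classify elapsed=%.1fs", time.time() - t0)
    return paths


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage in order and return the manifest.

    A stage failure aborts the run with the stage name in the error; partial
    outputs are retained next to a ``FAILED_<stage>`` marker file.
    """
    config.outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(outdir=config.outdir, seeds=config._derived_seeds(), versions=_versions())
    manifest.seeds["global"] = config.seed

    def guarded(name, fn, *args):
        try:
            return fn(*args)
        except Exception as exc:
            (config.outdir / f"FAILED_{name}").write_text(f"{type(exc).__name__}: {exc}\n")
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    cohort_df = guarded("simulate_reconstruct", stage_simulate_reconstruct, config)
    map_files = {
        index_type: list(cohort_df[f"map_{index_type}"]) for index_type in config.index_types
    }
    manifest.add_stage(
        "simulate_reconstruct",
        {"cohort_manifest": str(config.outdir / "cohort_manifest.csv"), **map_files},
    )
    feat_files = guarded("featurize", stage_featurize, config, cohort_df)
    manifest.add_stage("featurize", feat_files)
    clf_files = guarded("classify", stage_classify, config, cohort_df)
    manifest.add_stage("classify", clf_files)
    manifest.save()
    return manifest


# ---------------------------------------------------------------------------
# canned configurations


def small_pipeline_config(outdir: str | Path, seed: int = 0, **overrides) -> PipelineConfig:
    """A desk-scale configuration: 16^3 grid, order-2 ODF tessellation and a
    12-epoch autoencoder, with the full reference cohort composition."""
    cohort = CohortSpec(grid_shape=(16, 16, 16), seed=seed, **overrides.pop("cohort_kw", {}))
    ae = AEConfig(input_shape=(16, 16, 16), epochs=12)
    gqi = GQIConfig(odf_direction_order=2)
    return PipelineConfig(
        cohort=cohort, outdir=Path(outdir), gqi=gqi, ae=ae, seed=seed, geometry="small",
        **overrides,
    )


def recovery_experiment_config(
    outdir: str | Path, seed: int, effect_delta: float
) -> PipelineConfig:
    """The signal-recovery experiment: one index type (GFA), half 1, the
    gradient-boosted model only, 10 iterations, at the desk-scale geometry."""
    cohort = CohortSpec(grid_shape=(16, 16, 16), effect_delta=effect_delta, seed=seed)
    return PipelineConfig(
        cohort=cohort,
        outdir=Path(outdir),
        gqi=GQIConfig(odf_direction_order=2),
        ae=AEConfig(input_shape=(16, 16, 16), epochs=12),
        classifiers=(ClassifierSpec(kind="xgb"),),
        index_types=("GFA",),
        halves=(1,),
        random_states=tuple(range(10)),
        seed=seed,
        geometry="small",
    )
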