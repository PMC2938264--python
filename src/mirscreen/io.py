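"""File formats, pipeline configuration and the end-to-end runner.

Formats are plain text throughout: long-format probe-level TSV
(probe_id, spot_index, sample_id, intensity, background), a sample sheet
(sample_id, class_label, subtype), a planted-truth TSV, wide expression
matrices (first column probe_id, one column per sample) with a JSON
sidecar carrying stage and labels, and JSON reports.  All randomness in
:func:`run_pipeline` flows from the single configured seed.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, classify, diffexp, preprocess, roc, screening, simulate
from .errors import ConfigurationError, SchemaError

__all__ = [
    "write_raw_long",
    "read_raw_long",
    "write_sample_sheet",
    "read_sample_sheet",
    "write_truth",
    "write_expression_matrix",
    "read_expression_matrix",
    "PipelineConfig",
    "run_pipeline",
]

log = logging.getLogger("mirscreen")


# ---------------------------------------------------------------- raw data

def write_raw_long(raw: simulate.RawArraySet, path) -> None:
    """Long-format probe-level TSV, one row per (probe, spot, sample)."""
    n_p, n_k, n_s = raw.intensities.shape
    probe_col = np.repeat(raw.probe_ids, n_k * n_s)
    spot_col = np.tile(np.repeat(np.arange(n_k), n_s), n_p)
    sample_col = np.tile(raw.sample_ids, n_p * n_k)
    pd.DataFrame(
        {
            "probe_id": probe_col,
            "spot_index": spot_col,
            "sample_id": sample_col,
            "intensity": raw.intensities.reshape(-1),
            "background": raw.backgrounds.reshape(-1),
        }
    ).to_csv(path, sep="\t", index=False)


def read_raw_long(path, sample_sheet_path) -> simulate.RawArraySet:
    """Rebuild a RawArraySet from the long TSV plus its sample sheet."""
    df = pd.read_csv(path, sep="\t")
    required = {"probe_id", "spot_index", "sample_id", "intensity", "background"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"raw long TSV missing columns: {sorted(missing)}")
    samples = read_sample_sheet(sample_sheet_path)
    sample_ids = [s.sample_id for s in samples]
    probe_ids = list(dict.fromkeys(df["probe_id"]))
    n_k = int(df["spot_index"].max()) + 1

    p_idx = pd.Categorical(df["probe_id"], categories=probe_ids).codes
    s_idx = pd.Categorical(df["sample_id"], categories=sample_ids).codes
    if (s_idx < 0).any():
        raise SchemaError("sample ids in raw TSV not covered by the sample sheet")
    shape = (len(probe_ids), n_k, len(sample_ids))
    intensities = np.full(shape, np.nan)
    backgrounds = np.full(shape, np.nan)
    intensities[p_idx, df["spot_index"], s_idx] = df["intensity"]
    backgrounds[p_idx, df["spot_index"], s_idx] = df["background"]
    if np.isnan(intensities).any():
        raise SchemaError("raw long TSV incomplete: missing (probe, spot, sample) cells")
    return simulate.RawArraySet(probe_ids, samples, intensities, backgrounds)


def write_sample_sheet(samples: list[simulate.SampleSpec], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "class_label": [s.class_label for s in samples],
            "subtype": [s.subtype for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


def read_sample_sheet(path) -> list[simulate.SampleSpec]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "class_label", "subtype"):
        if col not in df.columns:
            raise SchemaError(f"sample sheet missing column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise SchemaError(f"duplicate sample id {dup!r} in sample sheet")
    return [
        simulate.SampleSpec(r.sample_id, r.class_label, r.subtype)
        for r in df.itertuples()
    ]


def write_truth(probe_set: simulate.ProbeSet, path) -> None:
    """Planted ground truth: probe_id and its glog-scale effect."""
    pd.DataFrame(
        {
            "probe_id": probe_set.probe_ids,
            "planted_effect": probe_set.planted_effects,
        }
    ).to_csv(path, sep="\t", index=False)


# -------------------------------------------------------- expression matrix

def write_expression_matrix(
    matrix: preprocess.ExpressionMatrix,
    path,
    model: preprocess.NormalizationModel | None = None,
) -> None:
    """Wide TSV (probe_id + one column per sample) with a JSON sidecar
    recording stage, class labels and, when given, the fitted
    normalization parameters."""
    path = Path(path)
    frame = matrix.to_frame()
    frame.insert(0, "probe_id", matrix.probe_ids)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")
    sidecar: dict = {
        "stage": matrix.stage,
        "labels": {sid: str(lab) for sid, lab in zip(matrix.sample_ids, matrix.labels)},
    }
    if model is not None:
        sidecar["normalization"] = {
            "cofactor": model.cofactor,
            "trim": model.trim,
            "offsets": model.offsets,
            "scales": model.scales,
        }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def read_expression_matrix(
    path, sample_sheet=None, stage: str | None = None
) -> preprocess.ExpressionMatrix:
    """Validated read of a wide matrix TSV.

    Labels come from the JSON sidecar written alongside, or from an
    explicit sample sheet.  Parse errors (ragged rows, non-numeric cells,
    duplicate ids) name the offending line.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows or rows[0][:1] != ["probe_id"]:
        raise SchemaError(f"{path}: first header field must be 'probe_id'")
    header = rows[0]
    sample_ids = header[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise SchemaError(f"{path}: duplicate sample ids in header")

    probe_ids: list[str] = []
    seen: set[str] = set()
    values = np.empty((len(rows) - 1, len(sample_ids)))
    for li, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise SchemaError(
                f"{path}: line {li}: expected {len(header)} fields, got {len(row)}"
            )
        pid = row[0]
        if pid in seen:
            raise SchemaError(f"{path}: line {li}: duplicate probe id {pid!r}")
        seen.add(pid)
        probe_ids.append(pid)
        for ci, cell in enumerate(row[1:]):
            try:
                values[li - 2, ci] = float(cell)
            except ValueError:
                raise SchemaError(
                    f"{path}: line {li}: non-numeric value {cell!r} "
                    f"in column {header[ci + 1]!r}"
                ) from None

    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sample_sheet is not None:
        samples = read_sample_sheet(sample_sheet)
        label_map = {s.sample_id: s.class_label for s in samples}
    elif sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        label_map = sidecar["labels"]
        stage = stage or sidecar.get("stage")
    else:
        raise SchemaError(
            f"{path}: no sample sheet given and no sidecar {sidecar_path.name} found"
        )
    try:
        labels = [label_map[sid] for sid in sample_ids]
    except KeyError as e:
        raise SchemaError(f"{path}: sample {e.args[0]!r} missing from labels") from None

    return preprocess.ExpressionMatrix(
        probe_ids=probe_ids,
        sample_ids=sample_ids,
        values=values,
        labels=np.array(labels),
        stage=stage or preprocess.STAGE_NORMALIZED,
    )


# ------------------------------------------------------------------ config

@dataclass
class PipelineConfig:
    """Nested configuration of the end-to-end run; YAML round-trips
    losslessly.  Scaled-down CV defaults keep the demo desk-scale; the
    full study grid is available by overriding the ``cv`` section."""

    seed: int = 0
    out_dir: str = "mirscreen-run"
    n_case: int = 24
    n_control: int = 15
    generator: dict = field(
        default_factory=lambda: {"n_up": 1, "n_down": 3, "effect_size": 1.0}
    )
    normalization: dict = field(
        default_factory=lambda: {"cofactor": 1.0, "trim": 0.25}
    )
    diffexp: dict = field(
        default_factory=lambda: {"method": "welch", "top_k": 30, "alpha": 0.05}
    )
    cv: dict = field(
        default_factory=lambda: {
            "n_folds": 10,
            "n_repeats": 20,
            "subset_sizes": [10, 60],
            "kernels": ["radial"],
            "cost_grid": [0.1, 1.0, 10.0],
            "stratified": True,
        }
    )
    n_permutation_runs: int = 20
    screening: dict = field(
        default_factory=lambda: {"prevalences": [0.0004, 0.015]}
    )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate -> preprocess -> diffexp -> roc -> classify -> screening.

    Writes every stage artifact under ``config.out_dir`` plus a manifest
    with the seed, the config and a sha256 checksum per file; re-running
    the same config reproduces identical checksums.  Any stage failure
    aborts with the stage name attached.
    """
    if config.n_case <= 0 or config.n_control <= 0:
        raise ConfigurationError("n_case and n_control must be positive")
    gen_cfg = simulate.GeneratorConfig(seed=config.seed, **config.generator)
    cv_cfg = classify.CVConfig(
        seed=config.seed,
        **{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in config.cv.items()
        },
    )

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    stage = "setup"
    try:
        stage = "simulate"
        t0 = time.perf_counter()
        probe_set, raw = simulate.simulate_from_config(
            gen_cfg, config.n_case, config.n_control
        )
        write_raw_long(raw, out / "raw_probe_level.tsv")
        write_sample_sheet(raw.samples, out / "samples.tsv")
        write_truth(probe_set, out / "truth.tsv")
        artifacts |= {
            "raw_probe_level.tsv": out / "raw_probe_level.tsv",
            "samples.tsv": out / "samples.tsv",
            "truth.tsv": out / "truth.tsv",
        }
        log.info("simulate: %d probes x %d samples (%.2fs)",
                 raw.n_probes, len(raw.samples), time.perf_counter() - t0)

        stage = "preprocess"
        t0 = time.perf_counter()
        corrected = preprocess.background_correct(raw)
        summarized = preprocess.summarize_replicates(corrected)
        model = preprocess.fit_normalization(summarized, **config.normalization)
        matrix = model.training_normalized
        write_expression_matrix(matrix, out / "expression_normalized.tsv", model=model)
        artifacts["expression_normalized.tsv"] = out / "expression_normalized.tsv"
        log.info("preprocess: normalized matrix (%.2fs)", time.perf_counter() - t0)

        stage = "diffexp"
        t0 = time.perf_counter()
        de = diffexp.build_de_table(matrix, **config.diffexp)
        de.table.to_csv(out / "de_table.tsv", sep="\t", index=False,
                        float_format="%.8g")
        (out / "de_summary.json").write_text(json.dumps(
            {
                "n_probes": de.n_probes,
                "n_significant_unadjusted": de.n_significant_unadjusted,
                "n_significant_adjusted": de.n_significant_adjusted,
                "alpha": de.alpha,
                "method": de.method,
            },
            indent=2,
        ))
        artifacts |= {"de_table.tsv": out / "de_table.tsv",
                      "de_summary.json": out / "de_summary.json"}
        log.info("diffexp: %d / %d significant (%.2fs)",
                 de.n_significant_unadjusted, de.n_significant_adjusted,
                 time.perf_counter() - t0)

        stage = "roc"
        t0 = time.perf_counter()
        top = de.table.iloc[0]
        i = matrix.probe_ids.index(top["probe_id"])
        orientation = "greater" if top["delta"] >= 0 else "less"
        curve = roc.roc_curve(matrix.values[i], matrix.labels,
                              orientation=orientation)
        pd.DataFrame(
            {"threshold": curve.thresholds, "fpr": curve.fpr, "tpr": curve.tpr}
        ).to_csv(out / "roc_top_probe.tsv", sep="\t", index=False,
                 float_format="%.8g")
        (out / "roc_summary.json").write_text(json.dumps(
            {"probe_id": top["probe_id"], "auc": curve.auc,
             "orientation": orientation,
             "oracle_auc": roc.auc_rank_oracle(matrix.values[i], matrix.labels)},
            indent=2,
        ))
        artifacts |= {"roc_top_probe.tsv": out / "roc_top_probe.tsv",
                      "roc_summary.json": out / "roc_summary.json"}
        log.info("roc: top probe %s AUC %.3f (%.2fs)", top["probe_id"], curve.auc,
                 time.perf_counter() - t0)

        stage = "classify"
        t0 = time.perf_counter()
        report = classify.run_repeated_cv(matrix, config=cv_cfg)
        (out / "cv_report.json").write_text(report.to_json())
        report.per_repeat_frame().to_csv(out / "cv_per_repeat.tsv", sep="\t",
                                         index=False, float_format="%.8g")
        perm = classify.run_permutation(
            matrix, config=cv_cfg, n_permutation_runs=config.n_permutation_runs
        )
        (out / "permutation_report.json").write_text(json.dumps(
            {
                "n_permutation_runs": perm.n_permutation_runs,
                "observed": perm.observed,
                "exceedance": perm.exceedance,
                "permuted_accuracy": perm.permuted_accuracy.tolist(),
                "permuted_sensitivity": perm.permuted_sensitivity.tolist(),
                "permuted_specificity": perm.permuted_specificity.tolist(),
            },
            indent=2,
        ))
        artifacts |= {"cv_report.json": out / "cv_report.json",
                      "cv_per_repeat.tsv": out / "cv_per_repeat.tsv",
                      "permutation_report.json": out / "permutation_report.json"}
        log.info("classify: best acc %.3f (%.2fs)", report.best.mean_accuracy,
                 time.perf_counter() - t0)

        stage = "screening"
        t0 = time.perf_counter()
        metrics = [
            screening.ScreeningMetrics.compute(
                report.best.mean_sensitivity, report.best.mean_specificity, p
            )
            for p in config.screening["prevalences"]
        ]
        (out / "screening.json").write_text(json.dumps(
            [dataclasses.asdict(m) | m.as_percent() for m in metrics], indent=2
        ))
        artifacts["screening.json"] = out / "screening.json"
        log.info("screening: %d prevalence points (%.2fs)", len(metrics),
                 time.perf_counter() - t0)
    except Exception as e:
        raise type(e)(f"pipeline stage {stage!r} failed: {e}") from e

    manifest = {
        "package": "mirscreen",
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "checksums": {name: _sha256(p) for name, p in sorted(artifacts.items())},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
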