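"""On-disk formats, experiment configuration, and the pipeline driver.

A record on disk is a CSV (columns ``t_s``, ``position_deg``,
``evp_dps``) plus a JSON sidecar carrying everything the CSV cannot:
sampling rate, subject class, stimulation angle, seed, noise
configuration, stimulus transition times and exact event indices.
The round trip is lossless to float precision. A dataset is a directory
of such records plus a ``manifest.csv``.

``run_experiment`` drives generate -> differentiate -> detect ->
biomarkers -> statistics and writes every table the analysis produces,
next to the fully resolved configuration, so any output directory is
regenerable from (config, master seed) alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .detection import DetectionConfig, SaccadeEvent
from .evaluation import DifferentiationExperiment, ExperimentResult
from .filters import DEFAULT_METHODS
from .synthetic import (
    ANGLES,
    CLASSES,
    DEFAULT_CLASS_PARAMS,
    ClassParameters,
    DatasetConfig,
    DatasetManifest,
    ManifestEntry,
    NoiseConfig,
    SyntheticRecord,
    generate_dataset,
)

__all__ = [
    "read_record",
    "write_record",
    "write_dataset",
    "read_dataset",
    "ExperimentConfig",
    "run_experiment",
]

log = logging.getLogger("eogdiff")

_FORMAT_VERSION = "1.0"


class RecordFormatError(ValueError):
    """A record file violates the CSV+JSON schema."""


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_record(record: SyntheticRecord, path) -> Path:
    """Write a record as ``<path>.csv`` + ``<path>.json`` sidecar."""
    path = Path(path)
    csv_path = path if path.suffix == ".csv" else path.with_suffix(".csv")
    df = pd.DataFrame(
        {
            "t_s": record.times,
            "position_deg": record.position,
            "evp_dps": record.evp,
        }
    )
    df.to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = {
        "format_version": _FORMAT_VERSION,
        "fs": record.fs,
        "n_samples": record.n_samples,
        "subject_class": record.subject_class,
        "stimulation_angle": record.stimulation_angle,
        "seed": record.seed,
        "noise": record.noise.to_dict() if record.noise is not None else None,
        "stimulus_transitions": record.stimulus_transitions.tolist(),
        "exact_events": [
            [ev.onset_index, ev.offset_index] for ev in record.exact_events
        ],
    }
    _sidecar_path(csv_path).write_text(json.dumps(sidecar, indent=1))
    return csv_path


def read_record(path) -> SyntheticRecord:
    """Read a record written by :func:`write_record`, validating the schema."""
    csv_path = Path(path)
    if csv_path.suffix != ".csv":
        csv_path = csv_path.with_suffix(".csv")
    side_path = _sidecar_path(csv_path)
    if not csv_path.exists():
        raise RecordFormatError(f"record CSV not found: {csv_path}")
    if not side_path.exists():
        raise RecordFormatError(f"missing JSON sidecar: {side_path}")

    df = pd.read_csv(csv_path, float_precision="round_trip")
    for col in ("t_s", "position_deg", "evp_dps"):
        if col not in df.columns:
            raise RecordFormatError(f"{csv_path}: missing column {col!r}")
        bad = df.index[~np.isfinite(df[col].to_numpy(dtype=float))]
        if len(bad):
            raise RecordFormatError(
                f"{csv_path}: non-finite value in {col!r} at row {int(bad[0])}"
            )
    meta = json.loads(side_path.read_text())
    for key in ("fs", "n_samples", "subject_class", "stimulation_angle"):
        if key not in meta:
            raise RecordFormatError(f"{side_path}: missing field {key!r}")

    fs = float(meta["fs"])
    t = df["t_s"].to_numpy(dtype=float)
    if len(df) != int(meta["n_samples"]):
        raise RecordFormatError(
            f"{csv_path}: {len(df)} rows but sidecar says {meta['n_samples']} "
            "(truncated file?)"
        )
    dt = np.diff(t)
    if len(dt) and (dt.min() <= 0):
        row = int(np.argmax(dt <= 0)) + 1
        raise RecordFormatError(f"{csv_path}: non-monotone time at row {row}")
    if len(dt) and abs(dt.mean() - 1.0 / fs) > 1e-9 / fs + 1e-12:
        raise RecordFormatError(
            f"{csv_path}: CSV time step {dt.mean():.6g}s does not match "
            f"sidecar fs={fs} Hz"
        )

    noise = meta.get("noise")
    return SyntheticRecord(
        fs=fs,
        position=df["position_deg"].to_numpy(dtype=float),
        evp=df["evp_dps"].to_numpy(dtype=float),
        stimulus_transitions=np.asarray(meta.get("stimulus_transitions", []), float),
        exact_events=tuple(
            SaccadeEvent(int(a), int(b)) for a, b in meta.get("exact_events", [])
        ),
        subject_class=meta["subject_class"],
        stimulation_angle=float(meta["stimulation_angle"]),
        seed=meta.get("seed"),
        noise=NoiseConfig.from_dict(noise) if noise else None,
    )


def write_dataset(manifest: DatasetManifest, out_dir) -> Path:
    """Write all records plus ``manifest.csv`` into ``out_dir``."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc
    if manifest.records is None:
        raise ValueError("manifest has no in-memory records to write")
    rows = []
    for entry, rec in zip(manifest.entries, manifest.records):
        csv_path = write_record(rec, out_dir / f"{entry.record_id}.csv")
        entry.path = str(csv_path)
        rows.append(
            {
                "record_id": entry.record_id,
                "subject_class": entry.subject_class,
                "angle": entry.angle,
                "seed": entry.seed,
                "path": csv_path.name,
            }
        )
    mpath = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(mpath, index=False)
    return mpath


def read_dataset(directory) -> DatasetManifest:
    """Load a dataset directory written by :func:`write_dataset`."""
    directory = Path(directory)
    mpath = directory / "manifest.csv"
    if not mpath.exists():
        raise RecordFormatError(f"no manifest.csv in {directory}")
    df = pd.read_csv(mpath)
    entries, records = [], []
    for _, row in df.iterrows():
        path = directory / row["path"]
        entries.append(
            ManifestEntry(
                record_id=row["record_id"],
                subject_class=row["subject_class"],
                angle=float(row["angle"]),
                seed=int(row["seed"]),
                path=str(path),
            )
        )
        records.append(read_record(path))
    return DatasetManifest(entries=entries, records=records)


@dataclasses.dataclass
class ExperimentConfig:
    """Fully resolved configuration of one experiment run."""

    dataset: DatasetConfig = dataclasses.field(default_factory=DatasetConfig)
    detection: DetectionConfig = dataclasses.field(default_factory=DetectionConfig)
    methods: tuple[str, ...] = DEFAULT_METHODS
    alpha: float = 0.05
    drop_factor: float | None = 100.0
    master_seed: int = 0

    def to_dict(self) -> dict:
        ds = self.dataset
        return {
            "master_seed": self.master_seed,
            "methods": list(self.methods),
            "alpha": self.alpha,
            "drop_factor": self.drop_factor,
            "dataset": {
                "records_per_cell": ds.records_per_cell,
                "n_saccades": ds.n_saccades,
                "classes": list(ds.classes),
                "angles": list(ds.angles),
                "fs": ds.fs,
                "target_fs": ds.target_fs,
                "noiseless": ds.noiseless,
                "noise": {
                    c: ds.noise_for(c).to_dict() for c in ds.classes
                },
                "class_params": {
                    c: dataclasses.asdict(
                        (ds.class_params or DEFAULT_CLASS_PARAMS)[c]
                    )
                    for c in ds.classes
                },
            },
            "detection": dataclasses.asdict(self.detection),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d or {})
        det = DetectionConfig(**d.get("detection", {}))
        ds_d = dict(d.get("dataset", {}))
        noise = ds_d.pop("noise", None)
        class_params = ds_d.pop("class_params", None)
        ds = DatasetConfig(
            **{
                **ds_d,
                "classes": tuple(ds_d.get("classes", CLASSES)),
                "angles": tuple(ds_d.get("angles", ANGLES)),
                "noise": (
                    {c: NoiseConfig.from_dict(v) for c, v in noise.items()}
                    if noise
                    else None
                ),
                "class_params": (
                    {c: ClassParameters(**v) for c, v in class_params.items()}
                    if class_params
                    else None
                ),
                "detection": det,
            }
        )
        return cls(
            dataset=ds,
            detection=det,
            methods=tuple(d.get("methods", DEFAULT_METHODS)),
            alpha=float(d.get("alpha", 0.05)),
            drop_factor=d.get("drop_factor", 100.0),
            master_seed=int(d.get("master_seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def run_experiment(
    config: ExperimentConfig | None = None,
    out_dir=None,
    write_records: bool = False,
) -> ExperimentResult:
    """Execute the full pipeline and (optionally) persist every output.

    Stages: generate the dataset, differentiate with every configured
    method, detect and match saccades, extract biomarker errors, and
    run the ranking statistics. With ``out_dir`` the resolved config,
    manifest, per-method MSE table, identification scores, biomarker
    error tables and ranking tables (CSV + Markdown) are written.
    """
    config = config or ExperimentConfig()
    t0 = time.time()
    log.info(
        "run_experiment: seed=%d, h=%g s (fs=%g Hz), Pt=%g, Ot=%g, methods=%s",
        config.master_seed,
        1.0 / config.dataset.target_fs,
        config.dataset.target_fs,
        config.detection.pt,
        config.detection.ot,
        ",".join(config.methods),
    )
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out / "config.yaml")

    try:
        manifest = generate_dataset(
            config.dataset,
            config.master_seed,
            out_dir=(out / "records") if (out is not None and write_records) else None,
        )
    except Exception as exc:
        raise RuntimeError(f"[generate] stage failed: {exc}") from exc

    try:
        experiment = DifferentiationExperiment(
            manifest,
            methods=config.methods,
            detection=config.detection,
            alpha=config.alpha,
            drop_factor=config.drop_factor,
        )
        result = experiment.run()
    except Exception as exc:
        raise RuntimeError(f"[evaluate] stage failed: {exc}") from exc

    if out is not None:
        try:
            _write_results(result, manifest, out)
        except Exception as exc:
            raise RuntimeError(f"[report] stage failed: {exc}") from exc
    log.info("run_experiment finished in %.1f s", time.time() - t0)
    return result


def _write_results(result: ExperimentResult, manifest, out: Path) -> None:
    pd.DataFrame(
        [
            {
                "record_id": e.record_id,
                "subject_class": e.subject_class,
                "angle": e.angle,
                "seed": e.seed,
            }
            for e in manifest.entries
        ]
    ).to_csv(out / "manifest.csv", index=False)
    result.mse_table.rename_axis("record_id").to_csv(out / "mse.csv")
    result.identification.to_csv(out / "identification.csv")
    errors = pd.concat(
        [ev.pair_errors.assign(method=ev.method) for ev in result.evaluations],
        ignore_index=True,
    )
    errors.to_csv(out / "biomarker_errors.csv", index=False)
    for biomarker, table in result.ranking.tables.items():
        table.to_csv(out / f"ranking_{biomarker}.csv", index=False)
    (out / "ranking.md").write_text(result.ranking.to_markdown())
    (out / "summary.txt").write_text(result.summary() + "\n")
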