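"""Readers, writers and run configuration.

Recordings travel as NPZ archives (samples + rate + subject id) or EDF
(read via ``mne``, single channel selected by name or index).  Learned
dictionaries and bags persist as NPZ with their provenance; cohort
tables and seizure-event lists as CSV; run configuration as YAML.

Every persisted artifact embeds the hash of the run configuration and
the seed that produced it, so downstream stages can refuse to mix
artifacts from different runs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import ClassifierModel, CohortTable
from .dictionary import WaveformDictionary
from .features import BagOfWaves, TfidfWeights
from .signal import Recording, SeizureEvent

__all__ = [
    "RunConfig",
    "read_recording",
    "write_recording_npz",
    "read_seizure_events",
    "read_cohort_csv",
    "write_cohort_csv",
    "save_dictionary",
    "load_dictionary",
    "save_bags",
    "load_bags",
    "save_model",
    "load_model",
]


@dataclass
class RunConfig:
    """Hyperparameters of a full study run.

    The "published" profile holds the published configuration (K=200 waveforms
    of P=256 samples matched inside L=512-sample windows; 40 000 training
    windows and 480 one-hour segments per genotype; 15-point C grid over
    [1e-1, 1e4]; 3 internal CV folds; 5 repeated splits).  The "desk"
    profile scales the same pipeline to minutes on a laptop.
    """

    K: int = 200
    P: int = 256
    L: int = 512
    rate_hz: float = 256.0
    windows_per_dict: int = 40_000
    segments_per_dict: int = 480
    seg_len_s: float = 3600.0
    K_CV: int = 3
    grid_low: float = 1e-1
    grid_high: float = 1e4
    grid_size: int = 15
    n_splits: int = 5
    seed: int = 0
    task: str = "strain"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.P >= self.L:
            raise ValueError("P must be smaller than L")
        if self.grid_low >= self.grid_high:
            raise ValueError("grid bounds must satisfy low < high")

    def grid(self) -> np.ndarray:
        return np.logspace(np.log10(self.grid_low), np.log10(self.grid_high), self.grid_size)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def published(cls, **overrides) -> "RunConfig":
        return cls(**overrides)

    @classmethod
    def desk(cls, **overrides) -> "RunConfig":
        defaults = dict(
            K=6,
            P=64,
            L=128,
            rate_hz=64.0,
            windows_per_dict=1500,
            segments_per_dict=48,
            seg_len_s=60.0,
            grid_size=5,
            n_splits=1,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        profile = data.pop("profile", None)
        if profile == "desk":
            return cls.desk(**data)
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def read_recording(
    path: str | Path, channel: int | str = 0, expected_rate: float | None = None
) -> Recording:
    """Load a single-channel recording from NPZ or EDF.

    NPZ archives carry ``samples``, ``rate`` and optional ``subject_id``;
    EDF files are read through ``mne`` with the channel selected by index
    or name.  A rate mismatch against ``expected_rate`` raises.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".npz":
        with np.load(path, allow_pickle=False) as data:
            samples = data["samples"]
            rate = float(data["rate"])
            subject_id = str(data["subject_id"]) if "subject_id" in data else path.stem
    elif path.suffix.lower() == ".edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        names = raw.ch_names
        if isinstance(channel, int):
            if not 0 <= channel < len(names):
                raise ValueError(f"channel index {channel} not available; channels: {names}")
            name = names[channel]
        else:
            if channel not in names:
                raise ValueError(f"channel {channel!r} not found; available channels: {names}")
            name = channel
        samples = raw.get_data(picks=[name])[0]
        rate = float(raw.info["sfreq"])
        subject_id = path.stem
    else:
        raise ValueError(f"unsupported recording format {path.suffix!r} (use .npz or .edf)")
    if expected_rate is not None and abs(rate - expected_rate) > 1e-9:
        raise ValueError(f"rate mismatch: file has {rate} Hz, config expects {expected_rate} Hz")
    return Recording(np.asarray(samples, dtype=float), rate, subject_id=subject_id)


def write_recording_npz(rec: Recording, path: str | Path) -> None:
    np.savez_compressed(
        path, samples=rec.samples, rate=rec.rate, subject_id=np.str_(rec.subject_id)
    )


def read_seizure_events(path: str | Path) -> dict[str, list[SeizureEvent]]:
    """CSV with columns subject_id, start_s, end_s -> events per subject."""
    df = pd.read_csv(path)
    out: dict[str, list[SeizureEvent]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["subject_id"]), []).append(
            SeizureEvent(float(row["start_s"]), float(row["end_s"]))
        )
    return out


def read_cohort_csv(path: str | Path) -> CohortTable:
    return CohortTable(pd.read_csv(path))


def write_cohort_csv(cohort: CohortTable, path: str | Path) -> None:
    cohort.table.to_csv(path, index=False)


def save_dictionary(d: WaveformDictionary, path: str | Path, config_hash: str = "") -> None:
    np.savez_compressed(
        path,
        centroids=d.centroids,
        class_label=np.str_(d.class_label),
        fold=-1 if d.fold is None else int(d.fold),
        meta=np.str_(json.dumps(d.train_meta)),
        config_hash=np.str_(config_hash),
    )


def load_dictionary(path: str | Path, expect_hash: str | None = None) -> WaveformDictionary:
    with np.load(path, allow_pickle=False) as data:
        if expect_hash is not None and str(data["config_hash"]) != expect_hash:
            raise ValueError(
                f"artifact {path} was produced under config {data['config_hash']}, "
                f"expected {expect_hash}"
            )
        fold = int(data["fold"])
        return WaveformDictionary(
            data["centroids"],
            class_label=str(data["class_label"]),
            fold=None if fold < 0 else fold,
            train_meta=json.loads(str(data["meta"])),
        )


def save_model(model: ClassifierModel, path_prefix: str | Path) -> None:
    """Persist a classifier as JSON (classes, biases, C, task) + NPZ (arrays)."""
    prefix = Path(path_prefix)
    meta = {
        "classes": model.classes,
        "intercepts": model.intercepts.tolist(),
        "reg_C": model.reg_C,
        "task": model.task,
        "transform": "tfidf" if model.tfidf is not None else ("scaler" if model.scaler else "none"),
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    arrays = {"coefficients": model.coefficients}
    if model.feature_means is not None:
        arrays["feature_means"] = model.feature_means
    if model.tfidf is not None:
        arrays.update(tfidf_w=model.tfidf.w, tfidf_N_k=model.tfidf.N_k,
                      tfidf_N_train=np.array(model.tfidf.N_train))
    if model.scaler is not None:
        arrays.update(scaler_mean=model.scaler[0], scaler_scale=model.scaler[1])
    np.savez_compressed(prefix.with_suffix(".npz"), **arrays)


def load_model(path_prefix: str | Path) -> ClassifierModel:
    prefix = Path(path_prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    with np.load(prefix.with_suffix(".npz"), allow_pickle=False) as data:
        tfidf = None
        scaler = None
        if meta["transform"] == "tfidf":
            tfidf = TfidfWeights(
                w=data["tfidf_w"], N_train=int(data["tfidf_N_train"]), N_k=data["tfidf_N_k"]
            )
        elif meta["transform"] == "scaler":
            scaler = (data["scaler_mean"], data["scaler_scale"])
        return ClassifierModel(
            classes=list(meta["classes"]),
            intercepts=np.array(meta["intercepts"]),
            coefficients=data["coefficients"],
            reg_C=float(meta["reg_C"]),
            tfidf=tfidf,
            scaler=scaler,
            task=meta["task"],
            feature_means=data["feature_means"] if "feature_means" in data else None,
        )


def save_bags(bags_by_subject: dict[str, list[BagOfWaves]], path: str | Path, config_hash: str = "") -> None:
    """Persist per-subject segment bags as a flat NPZ."""
    subjects, counts, meta = [], [], []
    block_index = None
    for s, bags in bags_by_subject.items():
        for b in bags:
            subjects.append(s)
            counts.append(b.counts)
            meta.append((b.start, b.duration_s))
            block_index = b.block_index
    np.savez_compressed(
        path,
        counts=np.array(counts),
        subjects=np.array(subjects),
        meta=np.array(meta, dtype=float),
        block_index=np.array(block_index, dtype=int),
        config_hash=np.str_(config_hash),
    )


def load_bags(path: str | Path, expect_hash: str | None = None) -> dict[str, list[BagOfWaves]]:
    with np.load(path, allow_pickle=False) as data:
        if expect_hash is not None and str(data["config_hash"]) != expect_hash:
            raise ValueError(
                f"artifact {path} was produced under config {data['config_hash']}, "
                f"expected {expect_hash}"
            )
        block_index = [tuple(map(int, r)) for r in data["block_index"]]
        out: dict[str, list[BagOfWaves]] = {}
        for s, z, (start, dur) in zip(data["subjects"], data["counts"], data["meta"]):
            out.setdefault(str(s), []).append(
                BagOfWaves(z, block_index, subject_id=str(s), start=int(start), duration_s=float(dur))
            )
    return out
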