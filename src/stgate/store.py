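"""Feature store, run configuration and checkpoint input/output.

The feature store is a directory with one ``.npy`` array per trial and a
tab-separated ``manifest.tsv`` (subject_id, trial_id, label, path,
feature_kind, bands, window_seconds).  Round-trips are bitwise exact.

Run configuration is a YAML file over the published defaults (learning rate
1e-5, batch 16, dropout 0.3, Top-K 10, loss stop 0.15); unknown keys are
rejected.  Checkpoints are an ``.npz`` parameter store plus a JSON sidecar
describing the architecture and training setup.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, DataError
from .features import FeatureTensor
from .model import STGATE, GATParams, ModelConfig, TLBParams
from .training import TrainConfig

MANIFEST_NAME = "manifest.tsv"
MANIFEST_COLUMNS = ["subject_id", "trial_id", "label", "path", "feature_kind",
                    "bands", "window_seconds"]


# ---------------------------------------------------------------------------
# feature store
# ---------------------------------------------------------------------------


def write_feature_store(tensors: list[FeatureTensor], directory: str | Path) -> Path:
    """Write one array file per trial plus the manifest; returns its path."""
    if not tensors:
        raise DataError("no feature tensors to write")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    kinds = {t.feature_kind for t in tensors}
    bands = {tuple(t.band_names) for t in tensors}
    if len(kinds) > 1 or len(bands) > 1:
        raise DataError(f"inconsistent feature kinds {kinds} or bands {bands}")
    rows = []
    for t in tensors:
        fname = f"{t.subject_id}__{t.trial_id}.npy"
        np.save(directory / fname, t.values)
        rows.append({
            "subject_id": t.subject_id,
            "trial_id": t.trial_id,
            "label": t.label,
            "path": fname,
            "feature_kind": t.feature_kind,
            "bands": ",".join(t.band_names),
            "window_seconds": t.window_seconds,
        })
    manifest = directory / MANIFEST_NAME
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, sep="\t", index=False)
    return manifest


def read_feature_store(directory: str | Path):
    """Read back ``(tensors, manifest_dataframe)``; errors name the trial."""
    directory = Path(directory)
    manifest_path = directory / MANIFEST_NAME
    if not manifest_path.exists():
        raise DataError(f"no manifest at {manifest_path}")
    manifest = pd.read_csv(manifest_path, sep="\t")
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise DataError(f"manifest {manifest_path} is missing columns {missing}")
    tensors = []
    shape_tail = None
    for row in manifest.itertuples():
        fpath = directory / row.path
        if not fpath.exists():
            raise DataError(f"array file missing for trial {row.trial_id}: {fpath}")
        try:
            values = np.load(fpath)
        except Exception as exc:
            raise DataError(f"corrupt array file for trial {row.trial_id}: {fpath}") from exc
        if values.ndim != 3:
            raise DataError(
                f"trial {row.trial_id}: expected T x N x F array, got {values.shape}"
            )
        if shape_tail is None:
            shape_tail = values.shape[1:]
        elif values.shape[1:] != shape_tail:
            raise DataError(
                f"trial {row.trial_id}: shape {values.shape[1:]} drifts from {shape_tail}"
            )
        tensors.append(FeatureTensor(
            values=values,
            band_names=str(row.bands).split(","),
            window_seconds=float(row.window_seconds),
            subject_id=str(row.subject_id),
            trial_id=str(row.trial_id),
            label=int(row.label),
            feature_kind=str(row.feature_kind),
        ))
    return tensors, manifest


# ---------------------------------------------------------------------------
# raw recording store (synth output / extract-features input)
# ---------------------------------------------------------------------------

RAW_MANIFEST_COLUMNS = ["subject_id", "trial_id", "label", "path", "rate"]


def write_raw_store(recordings, directory: str | Path) -> Path:
    """Write raw recordings (one ``.npy`` per trial) plus a manifest."""
    from .features import RawRecording  # noqa: F401 - type of the elements

    if not recordings:
        raise DataError("no recordings to write")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    labels0 = recordings[0].channel_labels
    for rec in recordings:
        if rec.channel_labels != labels0:
            raise DataError(f"trial {rec.trial_id}: channel labels drift")
        fname = f"{rec.trial_id}.npy"
        np.save(directory / fname, rec.data)
        rows.append({
            "subject_id": rec.subject_id,
            "trial_id": rec.trial_id,
            "label": rec.label,
            "path": fname,
            "rate": rec.rate,
        })
    (directory / "channels.txt").write_text("\n".join(labels0) + "\n")
    manifest = directory / MANIFEST_NAME
    pd.DataFrame(rows, columns=RAW_MANIFEST_COLUMNS).to_csv(manifest, sep="\t",
                                                            index=False)
    return manifest


def read_raw_store(directory: str | Path):
    """Read back the raw recordings written by :func:`write_raw_store`."""
    from .features import RawRecording

    directory = Path(directory)
    manifest_path = directory / MANIFEST_NAME
    if not manifest_path.exists():
        raise DataError(f"no manifest at {manifest_path}")
    manifest = pd.read_csv(manifest_path, sep="\t")
    labels = (directory / "channels.txt").read_text().splitlines()
    recordings = []
    for row in manifest.itertuples():
        fpath = directory / row.path
        if not fpath.exists():
            raise DataError(f"array file missing for trial {row.trial_id}: {fpath}")
        recordings.append(RawRecording(
            data=np.load(fpath), rate=float(row.rate), channel_labels=list(labels),
            subject_id=str(row.subject_id), trial_id=str(row.trial_id),
            label=int(row.label),
        ))
    return recordings, manifest


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

CONFIG_DEFAULTS = {
    "variant": "stgate",
    "n_classes": 3,
    "k_top": 10,
    "k_nn": 10,
    "dropout": 0.3,
    "seq_len": 10,
    "conv_channels": 32,
    "transformer_depth": 2,
    "transformer_heads": 4,
    "gat_heads": 4,
    "gat_out_features": 32,
    "learning_rate": 1e-5,
    "batch_size": 16,
    "loss_stop_threshold": 0.15,
    "max_epochs": 200,
    "seed": 0,
}

_RANGES = {
    "dropout": (0.0, 0.999),
    "learning_rate": (1e-12, 1.0),
    "loss_stop_threshold": (1e-9, float("inf")),
}


def read_config_file(path: str | Path) -> dict:
    """Read only the keys explicitly set in a YAML config file (validated)."""
    with open(path) as fh:
        loaded = yaml.safe_load(fh) or {}
    if not isinstance(loaded, dict):
        raise ConfigurationError(f"config {path} must be a key-value mapping")
    out = {}
    for key, value in loaded.items():
        if key not in CONFIG_DEFAULTS:
            raise ConfigurationError(
                f"unknown config key {key!r}; valid keys: {sorted(CONFIG_DEFAULTS)}"
            )
        expected = type(CONFIG_DEFAULTS[key])
        if expected is float and isinstance(value, int):
            value = float(value)
        if not isinstance(value, expected):
            raise ConfigurationError(
                f"config key {key!r} expects {expected.__name__}, got {value!r}"
            )
        out[key] = value
    return out


def validate_config(cfg: dict) -> dict:
    for key, (lo, hi) in _RANGES.items():
        if not lo <= cfg[key] <= hi:
            raise ConfigurationError(
                f"config key {key!r}={cfg[key]} out of range [{lo}, {hi}]"
            )
    return cfg


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML run configuration over the published defaults.

    An empty (or absent) file yields the full default configuration;
    unknown keys and out-of-range values are configuration errors naming
    the key.
    """
    cfg = dict(CONFIG_DEFAULTS)
    if path is not None and Path(path).exists():
        cfg.update(read_config_file(path))
    return validate_config(cfg)


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def model_config_from_dict(cfg: dict) -> ModelConfig:
    return ModelConfig(
        variant=cfg["variant"],
        n_classes=cfg["n_classes"],
        k_top=cfg["k_top"],
        k_nn=cfg["k_nn"],
        dropout=cfg["dropout"],
        seq_len=cfg["seq_len"],
        tlb=TLBParams(conv_channels=cfg["conv_channels"], depth=cfg["transformer_depth"],
                      heads=cfg["transformer_heads"]),
        gat=GATParams(heads=cfg["gat_heads"], out_features=cfg["gat_out_features"]),
    )


def train_config_from_dict(cfg: dict) -> TrainConfig:
    return TrainConfig(
        learning_rate=cfg["learning_rate"],
        batch_size=cfg["batch_size"],
        loss_stop_threshold=cfg["loss_stop_threshold"],
        max_epochs=cfg["max_epochs"],
        seed=cfg["seed"],
    )


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: STGATE, path: str | Path, *,
                    tcfg: TrainConfig | None = None, seed: int | None = None,
                    extra: dict | None = None) -> Path:
    """Serialize parameters (``.npz``) plus a JSON sidecar describing the run."""
    path = Path(path)
    params = {name: p.data for name, p in model.named_parameters()}
    np.savez(path, **params)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")
    sidecar = {
        "variant": model.cfg.variant,
        "n_classes": model.cfg.n_classes,
        "n_channels": model.n_channels,
        "seq_len": model.cfg.seq_len,
        "conv_channels": model.cfg.tlb.conv_channels,
        "n_bands": 5,
        "k_top": model.cfg.k_top,
        "k_nn": model.cfg.k_nn,
        "model_config": asdict(model.cfg),
        "train_config": asdict(tcfg) if tcfg else None,
        "seed": seed,
        "static_adjacency": (
            model.static_mask.astype(int).tolist() if model.static_mask is not None else None
        ),
    }
    if extra:
        sidecar.update(extra)
    sidecar_path = npz_path.with_suffix(".json")
    with open(sidecar_path, "w") as fh:
        json.dump(sidecar, fh, indent=2)
    return npz_path


def load_checkpoint(path: str | Path) -> STGATE:
    """Rebuild a model from an ``.npz`` + JSON sidecar checkpoint."""
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise DataError(f"checkpoint sidecar missing: {sidecar_path}")
    with open(sidecar_path) as fh:
        sidecar = json.load(fh)
    mc = dict(sidecar["model_config"])
    cfg = ModelConfig(
        variant=mc["variant"], n_classes=mc["n_classes"], k_top=mc["k_top"],
        k_nn=mc["k_nn"], dropout=mc["dropout"], seq_len=mc["seq_len"],
        tlb=TLBParams(**mc["tlb"]), gat=GATParams(**mc["gat"]),
        knn_warm_start=mc.get("knn_warm_start", False),
    )
    static = sidecar.get("static_adjacency")
    model = STGATE(cfg, n_channels=sidecar["n_channels"],
                   static_adjacency=np.array(static) if static is not None else None,
                   rng=np.random.default_rng(0))
    stored = np.load(path)
    for name, p in model.named_parameters():
        if name not in stored:
            raise DataError(f"checkpoint {path} is missing parameter {name!r}")
        if stored[name].shape != p.data.shape:
            raise DataError(
                f"checkpoint parameter {name!r} has shape {stored[name].shape}, "
                f"model expects {p.data.shape}"
            )
        p.data = stored[name].astype(float)
    model.eval()
    return model
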