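"""File formats: trial-table CSV, epoch and GAT HDF5 containers, run
manifests.

Conventions: times are seconds inside HDF5 containers and milliseconds in
trial tables; epochs are float32 on disk.  Every container carries a
``schema_version`` attribute.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .erp import EpochSet

SCHEMA_VERSION = "1"

TRIAL_COLUMNS = [
    "subject", "session", "drug", "block", "trial_index", "stimulus",
    "response", "confidence", "rt_ms", "pupil_baseline_pct", "fixation_lost",
]

_VOCAB = {
    "drug": {"PLC", "DNP", "ATX"},
    "stimulus": {"cw", "ccw"},
    "response": {"cw", "ccw", "none"},
    "confidence": {"high", "low", "none"},
}


class ValidationError(ValueError):
    pass


def validate_trial_table(df: pd.DataFrame) -> None:
    """Schema validation; errors name the offending row and column."""
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing column(s): {missing}")
    for col, vocab in _VOCAB.items():
        bad = ~df[col].astype(str).isin(vocab)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"row {row}, column {col!r}: value {df[col].iloc[row]!r} "
                f"not in {sorted(vocab)}"
            )
    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    none_resp = df["response"].eq("none")
    bad = none_resp & rt.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(f"row {row}: rt_ms set although response is 'none'")
    bad = ~none_resp & rt.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(f"row {row}: rt_ms missing for an answered trial")
    bad = ~df["fixation_lost"].isin([0, 1])
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(f"row {row}, column 'fixation_lost': must be 0 or 1")


def write_trial_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in TRIAL_COLUMNS:
        if col not in out.columns:
            if col in ("subject", "session"):
                out[col] = 0
            else:
                raise ValidationError(f"missing column {col!r}")
    out = out[TRIAL_COLUMNS + [c for c in out.columns if c not in TRIAL_COLUMNS]]
    validate_trial_table(out)
    out.to_csv(path, index=False)


def read_trial_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    validate_trial_table(df)
    df["rt_ms"] = pd.to_numeric(df["rt_ms"], errors="coerce")
    return df


def write_epochs(epochs: EpochSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32))
        f.create_dataset("times", data=epochs.times.astype(np.float64))
        f.create_dataset(
            "channels", data=np.array(epochs.channels, dtype=h5py.string_dtype())
        )
        f.create_dataset(
            "trials",
            data=epochs.metadata.to_csv(index=False),
            dtype=h5py.string_dtype(),
        )
        f.attrs["sfreq"] = float(epochs.sfreq)
        f.attrs["lock"] = epochs.lock
        f.attrs["schema_version"] = SCHEMA_VERSION


def read_epochs(path: str | Path) -> EpochSet:
    import io as _io

    with h5py.File(path, "r") as f:
        for key in ("data", "times", "channels", "trials"):
            if key not in f:
                raise ValidationError(f"epoch container missing /{key}")
        for attr in ("sfreq", "lock", "schema_version"):
            if attr not in f.attrs:
                raise ValidationError(f"epoch container missing attribute {attr!r}")
        data = f["data"][...]
        times = f["times"][...]
        channels = [c.decode() if isinstance(c, bytes) else c for c in f["channels"][...]]
        raw = f["trials"][()]
        meta = pd.read_csv(_io.StringIO(raw.decode() if isinstance(raw, bytes) else raw))
        if data.shape[2] != len(times):
            raise ValidationError("times length does not match data")
        return EpochSet(
            data=data, times=times, sfreq=float(f.attrs["sfreq"]),
            lock=str(f.attrs["lock"]), channels=channels, metadata=meta,
        )


def write_gat(matrices: dict, times_train, times_test, path: str | Path) -> None:
    """Store GAT AUC matrices (one dataset per subcondition label)."""
    with h5py.File(path, "w") as f:
        g = f.create_group("gat")
        g.create_dataset("train_times", data=np.asarray(times_train, dtype=float))
        g.create_dataset("test_times", data=np.asarray(times_test, dtype=float))
        for key, mat in matrices.items():
            name = key if isinstance(key, str) else "|".join(map(str, key))
            g.create_dataset(f"auc/{name}", data=np.asarray(mat, dtype=np.float32))
        f.attrs["schema_version"] = SCHEMA_VERSION


def read_gat(path: str | Path) -> tuple[dict, np.ndarray, np.ndarray]:
    with h5py.File(path, "r") as f:
        g = f["gat"]
        mats = {k: g[f"auc/{k}"][...] for k in g["auc"]}
        return mats, g["train_times"][...], g["test_times"][...]


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def write_manifest(path: str | Path, *, seed: int, config: dict,
                   stage: str, outputs: list[str]) -> dict:
    """JSON run manifest: seed, config hash, versions, outputs."""
    import metarousal

    manifest = {
        "stage": stage,
        "seed": seed,
        "config_hash": config_hash(config),
        "config": config,
        "outputs": outputs,
        "versions": {
            "metarousal": metarousal.__version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "schema_version": SCHEMA_VERSION,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
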