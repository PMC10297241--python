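"""Reading and writing of channel recordings, cohort manifests and result tables.

The canonical on-disk format is plain CSV: a channel file has two columns
``timestamp_s,value_pct``; a uniformised signal adds a ``valid`` 0/1 column.
A cohort lives in a directory with one ``manifest.csv`` row per infant
(channel paths, outcome label, clinical covariates) and a ``truth.csv``
listing every injected desaturation event when the cohort is synthetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: channel identifiers used throughout the package
CHANNELS = ("rcSO2", "SpO2")
#: sampling dialects of the oximetry hardware (nominal period ranges, seconds)
DIALECTS = ("external", "internal")

CLINICAL_COLUMNS = [
    "sex",
    "hypotension",
    "inotrope",
    "chorioamnionitis",
    "gestational_age",
    "birth_weight",
    "apgar_5min",
    "head_circumference",
]


@dataclass
class RawChannel:
    """One channel of one infant, as the device stored it.

    Timestamps are seconds since recording start and need not be uniform;
    the INVOS oximeter samples at roughly 1/5-1/6 Hz with external storage
    ("external" dialect) and roughly 1/34-1/35 Hz on internal memory
    ("internal"); pulse oximeters record at 1 or 0.5 Hz.

    Attributes
    ----------
    infant_id : str
    channel : {"rcSO2", "SpO2"}
    timestamps : ndarray, seconds, strictly increasing
    values : ndarray, % saturation in [0, 100]
    start_postnatal_age : float, hours of life at ``timestamps[0] == t=0``
    dialect : {"external", "internal"}
    """

    infant_id: str
    channel: str
    timestamps: np.ndarray
    values: np.ndarray
    start_postnatal_age: float = 0.0
    dialect: str = "external"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}")
        if self.dialect not in DIALECTS:
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if self.timestamps.shape != self.values.shape:
            raise ValueError("timestamps and values differ in length")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")
        bad = np.flatnonzero((self.values < 0) | (self.values > 100))
        if bad.size:
            raise ValueError(
                f"value outside [0, 100] at row {bad[0]} "
                f"(t={self.timestamps[bad[0]]:g}s, value={self.values[bad[0]]:g})"
            )

    def __len__(self) -> int:
        return len(self.timestamps)

    def replace_samples(self, timestamps: np.ndarray, values: np.ndarray) -> "RawChannel":
        """Return a copy with a new sample set (metadata unchanged)."""
        return RawChannel(
            infant_id=self.infant_id,
            channel=self.channel,
            timestamps=timestamps,
            values=values,
            start_postnatal_age=self.start_postnatal_age,
            dialect=self.dialect,
        )


def read_channel(
    path: str | Path,
    infant_id: str = "",
    channel: str = "rcSO2",
    start_postnatal_age: float = 0.0,
    dialect: str = "external",
) -> RawChannel:
    """Read a two-column channel CSV into a :class:`RawChannel`.

    Duplicate timestamps are collapsed by averaging their values, with a
    logged warning. Timestamps that remain non-monotone after
    de-duplication, or values outside [0, 100], raise ``ValueError``.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if not {"timestamp_s", "value_pct"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns timestamp_s,value_pct")
    t = df["timestamp_s"].to_numpy(dtype=float)
    v = df["value_pct"].to_numpy(dtype=float)
    if len(t) == 0:
        raise ValueError(f"{path}: empty channel file")
    # collapse exact duplicate timestamps by averaging
    if len(np.unique(t)) != len(t):
        n_dup = len(t) - len(np.unique(t))
        logger.warning("%s: %d duplicated timestamp(s) collapsed by averaging", path, n_dup)
        order = np.argsort(t, kind="stable")
        t, v = t[order], v[order]
        uniq, inv = np.unique(t, return_inverse=True)
        sums = np.bincount(inv, weights=v)
        counts = np.bincount(inv)
        t, v = uniq, sums / counts
    if len(t) > 1 and not np.all(np.diff(t) > 0):
        raise ValueError(f"{path}: timestamps not strictly increasing after de-duplication")
    return RawChannel(
        infant_id=infant_id or path.stem,
        channel=channel,
        timestamps=t,
        values=v,
        start_postnatal_age=start_postnatal_age,
        dialect=dialect,
    )


def write_channel(ch: RawChannel, path: str | Path) -> None:
    """Write a channel as CSV; numeric precision preserves a round trip to 1e-9."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"timestamp_s": ch.timestamps, "value_pct": ch.values})
    df.to_csv(path, index=False, float_format="%.12g")


def write_uniform(sig, path: str | Path) -> None:
    """Write a preprocessed uniform signal (mask as a 0/1 column)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    t = np.arange(len(sig.values)) / sig.fs
    df = pd.DataFrame(
        {
            "timestamp_s": t,
            "value_pct": sig.values,
            "valid": sig.valid_mask.astype(int),
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def read_uniform(path: str | Path, infant_id: str = "", channel: str = "rcSO2",
                 fs: float = 1.0 / 6.0, start_postnatal_age: float = 0.0):
    """Read a uniform-signal CSV written by :func:`write_uniform`."""
    from .preprocess import UniformSignal

    df = pd.read_csv(path)
    return UniformSignal(
        infant_id=infant_id or Path(path).stem,
        channel=channel,
        fs=fs,
        values=df["value_pct"].to_numpy(dtype=float),
        valid_mask=df["valid"].to_numpy(dtype=bool),
        start_postnatal_age=start_postnatal_age,
    )


def write_cohort(cohort, out_dir: str | Path) -> Path:
    """Write a synthetic cohort to ``out_dir``: channel CSVs, manifest, truth.

    Returns the path to the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    truth_rows = []
    for infant_id, channels in cohort.recordings.items():
        row: dict = {"infant_id": infant_id, "label": int(cohort.labels[infant_id])}
        for channel, raw in channels.items():
            rel = f"{infant_id}_{channel.lower()}.csv"
            write_channel(raw, out_dir / rel)
            key = channel.lower()
            row[f"{key}_path"] = rel
            row[f"{key}_start_postnatal_age_h"] = raw.start_postnatal_age
            row[f"{key}_dialect"] = raw.dialect
        clin = cohort.clinical.loc[infant_id]
        for c in CLINICAL_COLUMNS:
            row[c] = clin[c]
        rows.append(row)
        for channel, events in cohort.truth.get(infant_id, {}).items():
            for ev in events:
                truth_rows.append(
                    {
                        "infant_id": infant_id,
                        "channel": channel,
                        "onset_s": ev.onset_time,
                        "duration_s": ev.duration,
                        "nadir_depth_pct": ev.nadir_depth,
                        "shape": ev.shape,
                        "asymmetry": ev.asymmetry,
                    }
                )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False, float_format="%.12g")
    pd.DataFrame(
        truth_rows,
        columns=["infant_id", "channel", "onset_s", "duration_s",
                 "nadir_depth_pct", "shape", "asymmetry"],
    ).to_csv(out_dir / "truth.csv", index=False, float_format="%.12g")
    return manifest


def read_cohort(manifest_path: str | Path):
    """Load a cohort directory written by :func:`write_cohort`."""
    from .synthetic import PRDSpec, SyntheticCohort

    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    df = pd.read_csv(manifest_path, dtype={"infant_id": str})
    recordings: dict = {}
    labels = {}
    for _, row in df.iterrows():
        iid = str(row["infant_id"])
        labels[iid] = int(row["label"])
        chans = {}
        for channel in CHANNELS:
            key = channel.lower()
            p = row.get(f"{key}_path")
            if isinstance(p, str) and p:
                chans[channel] = read_channel(
                    base / p,
                    infant_id=iid,
                    channel=channel,
                    start_postnatal_age=float(row.get(f"{key}_start_postnatal_age_h", 0.0)),
                    dialect=str(row.get(f"{key}_dialect", "external")),
                )
        recordings[iid] = chans
    clinical = df.set_index(df["infant_id"].astype(str))[CLINICAL_COLUMNS]
    truth: dict = {}
    truth_path = base / "truth.csv"
    if truth_path.exists():
        tdf = pd.read_csv(truth_path, dtype={"infant_id": str})
        for _, r in tdf.iterrows():
            truth.setdefault(str(r["infant_id"]), {}).setdefault(r["channel"], []).append(
                PRDSpec(
                    onset_time=float(r["onset_s"]),
                    duration=float(r["duration_s"]),
                    nadir_depth=float(r["nadir_depth_pct"]),
                    shape=str(r["shape"]),
                    asymmetry=float(r["asymmetry"]),
                )
            )
    return SyntheticCohort(
        recordings=recordings,
        clinical=clinical,
        labels=pd.Series(labels, name="label"),
        truth=truth,
    )
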