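"""Plain-text readers and writers for recordings, events and trial logs.

Native dialect is TSV with a one-line ``# key: value`` header for
metadata.  ``samples.tsv`` carries (t_ms, pupil, gaze_x, gaze_y) with a
missing-sample sentinel (blank cell or pupil == 0, as produced by EyeLink
parsers); ``events.tsv`` carries (kind, start_ms, end_ms); ``trials.tsv``
carries the trial-log schema.  An ``asc-like`` adapter reads
whitespace-separated sample lines (t_ms gaze_x gaze_y pupil) preceded by a
``RATE <hz>`` line, with pupil 0 or '.' as the missing sentinel.

All writers round-trip losslessly through the matching reader.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (PupilRecording, TRIAL_COLUMNS, make_event_table,
                        validate_trial_table)

_SENTINEL = 0.0


def write_samples(rec: PupilRecording, path: str | Path) -> None:
    path = Path(path)
    t_ms = np.rint(rec.t * 1000.0).astype(np.int64)
    pupil = np.where(rec.valid, rec.pupil, np.nan)
    df = pd.DataFrame({"t_ms": t_ms, "pupil": pupil})
    df["gaze_x"] = rec.gaze_x if rec.gaze_x is not None else np.nan
    df["gaze_y"] = rec.gaze_y if rec.gaze_y is not None else np.nan
    with path.open("w") as fh:
        fh.write(f"# rate_hz: {rec.rate:g}\tunits: {rec.units}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f", na_rep="")


def read_samples(path: str | Path, dialect: str = "tsv-samples") -> PupilRecording:
    """Read a continuous pupil recording.

    Invalid samples (blank/NaN or sentinel-zero pupil) are kept in the
    array with pupil value 0 and ``valid=False``.
    """
    path = Path(path)
    if dialect == "tsv-samples":
        with path.open() as fh:
            header = fh.readline()
            if not header.startswith("#"):
                raise ValueError("tsv-samples file must start with a '# rate_hz:' header")
            meta = dict(
                kv.split(":", 1) for kv in header.lstrip("#").strip().split("\t"))
            rate = float(meta["rate_hz"])
            units = meta.get("units", "au").strip()
            df = pd.read_csv(fh, sep="\t")
        t_ms = df["t_ms"].to_numpy(dtype=np.int64)
        pupil = df["pupil"].to_numpy(dtype=float)
        gaze_x = df["gaze_x"].to_numpy(dtype=float) if "gaze_x" in df else None
        gaze_y = df["gaze_y"].to_numpy(dtype=float) if "gaze_y" in df else None
    elif dialect == "asc-like":
        rate = None
        rows = []
        units = "au"
        for line in path.read_text().splitlines():
            parts = line.split()
            if not parts:
                continue
            if parts[0].upper() == "RATE":
                rate = float(parts[1])
                continue
            if not parts[0].lstrip("-").replace(".", "", 1).isdigit():
                continue  # MSG / event lines from the tracker
            t, gx, gy, pu = parts[:4]
            rows.append((int(float(t)),
                         np.nan if gx == "." else float(gx),
                         np.nan if gy == "." else float(gy),
                         np.nan if pu == "." else float(pu)))
        if rate is None:
            raise ValueError("asc-like file must declare RATE")
        arr = np.asarray(rows, dtype=float)
        t_ms = arr[:, 0].astype(np.int64)
        gaze_x, gaze_y, pupil = arr[:, 1], arr[:, 2], arr[:, 3]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if np.any(np.diff(t_ms) <= 0):
        raise ValueError("non-monotone time")
    valid = np.isfinite(pupil) & (pupil != _SENTINEL)
    pupil = np.where(valid, pupil, 0.0)
    return PupilRecording(t=t_ms / 1000.0, pupil=pupil, rate=rate, valid=valid,
                          gaze_x=gaze_x, gaze_y=gaze_y, units=units)


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t",
                     dtype={"kind": str, "start_ms": np.int64, "end_ms": np.int64})
    if len(df) == 0:
        return make_event_table([], [], [])
    return make_event_table(df["kind"], df["start_ms"], df["end_ms"])


def write_subject_dir(subject: str, rec: PupilRecording, events: pd.DataFrame,
                      trials: pd.DataFrame, out_dir: str | Path) -> Path:
    """Write one subject's session as samples/events/trials TSVs."""
    d = Path(out_dir) / subject
    d.mkdir(parents=True, exist_ok=True)
    write_samples(rec, d / "samples.tsv")
    write_events(events, d / "events.tsv")
    write_trial_log(trials, d / "trials.tsv")
    return d


def read_subject_dir(subject_dir: str | Path, config=None):
    """Read back a subject directory; returns (recording, events, trials)."""
    d = Path(subject_dir)
    return (read_samples(d / "samples.tsv"),
            read_events(d / "events.tsv"),
            read_trial_log(d / "trials.tsv", config))


def write_trial_log(trials: pd.DataFrame, path: str | Path) -> None:
    trials[list(TRIAL_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_trial_log(path: str | Path, config=None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["retrospective_flag"] = df["retrospective_flag"].astype(bool)
    df["retro_false_positive_flag"] = df["retro_false_positive_flag"].astype(bool)
    if config is not None:
        validate_trial_table(df, config)
    return df
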