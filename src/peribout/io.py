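"""Read/write session bundles, trial tables, and analysis products.

All formats are plain text: a JSON manifest plus CSVs with header rows,
'.' decimals, UTF-8, times in seconds as floats.  Every writer produces
files its paired reader accepts.

Bundle layout (one directory per session)::

    manifest.json    mouse_id, region, condition, session_duration_s, fs_hz
    licks.csv        time_s
    photometry.csv   time_s,ch465,ch405
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    BootstrapWaveform,
    CONDITIONS,
    EpochAUC,
    LickSession,
    MultispoutSession,
    PeriEventSnip,
    PhotometryRecording,
    REGIONS,
    ROITrace,
    SessionSummary,
    SignificanceWindows,
    Window,
    BIN_S,
    PRE_S,
)
from .errors import FormatError, PeriboutIOError

__all__ = [
    "read_session",
    "write_session",
    "write_results",
    "read_waveform",
    "read_windows",
    "write_multispout",
    "read_multispout",
    "write_roi_trace",
    "read_roi_trace",
    "write_snips",
    "read_snips",
]

log = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


# --- session bundles -----------------------------------------------------


def write_session(
    path: str | Path,
    session: LickSession,
    rec: PhotometryRecording | None = None,
) -> Path:
    """Write a session bundle directory; returns its path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "mouse_id": session.mouse_id,
        "region": session.region,
        "condition": session.condition,
        "session_duration_s": session.session_duration_s,
        "fs_hz": rec.fs_hz if rec is not None else None,
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=1))
    pd.DataFrame({"time_s": session.lick_times_s}).to_csv(
        path / "licks.csv", index=False, float_format=_FLOAT_FMT
    )
    if rec is not None:
        pd.DataFrame(
            {"time_s": rec.times(), "ch465": rec.ch_signal, "ch405": rec.ch_control}
        ).to_csv(path / "photometry.csv", index=False, float_format=_FLOAT_FMT)
    return path


def read_session(path: str | Path) -> tuple[LickSession, PhotometryRecording | None]:
    """Read a session bundle written by :func:`write_session`.

    Lick times are sorted and de-duplicated (with a logged warning when a
    repair was needed).  A photometry stream whose length disagrees with
    ``session_duration_s * fs_hz`` by more than one second raises a
    :class:`FormatError`.
    """
    path = Path(path)
    mf = path / "manifest.json"
    if not mf.exists():
        raise PeriboutIOError(f"missing file: {mf}")
    manifest = json.loads(mf.read_text())
    if manifest["condition"] not in CONDITIONS:
        raise FormatError(
            f"condition {manifest['condition']!r} not in allowed labels {CONDITIONS}"
        )
    if manifest["region"] not in REGIONS:
        raise FormatError(f"region {manifest['region']!r} not in allowed labels {REGIONS}")

    lick_path = path / "licks.csv"
    if not lick_path.exists():
        raise PeriboutIOError(f"missing file: {lick_path}")
    licks = pd.read_csv(lick_path)["time_s"].to_numpy(dtype=float)
    if licks.size and np.any(np.diff(licks) < 0):
        log.warning("read_session: lick times were unsorted, repairing (%s)", lick_path)
        licks = np.sort(licks)
    if licks.size:
        dedup = np.unique(licks)
        if dedup.size != licks.size:
            log.warning(
                "read_session: removed %d duplicate lick timestamps (%s)",
                licks.size - dedup.size,
                lick_path,
            )
        licks = dedup
    session = LickSession(
        mouse_id=str(manifest["mouse_id"]),
        region=manifest["region"],
        condition=manifest["condition"],
        session_duration_s=float(manifest["session_duration_s"]),
        lick_times_s=licks,
    )

    rec = None
    fs = manifest.get("fs_hz")
    phot_path = path / "photometry.csv"
    if fs is not None:
        if not phot_path.exists():
            raise PeriboutIOError(f"missing file: {phot_path}")
        streams = pd.read_csv(phot_path)
        n = len(streams)
        expected = session.session_duration_s * fs
        if abs(n - expected) > fs:  # disagreement beyond one second
            raise FormatError(
                f"photometry stream length {n} vs duration*fs {expected:.0f} "
                f"differs by more than 1 s"
            )
        rec = PhotometryRecording(
            fs_hz=float(fs),
            ch_signal=streams["ch465"].to_numpy(dtype=float),
            ch_control=streams["ch405"].to_numpy(dtype=float),
            t0_s=float(streams["time_s"].iloc[0]) if n else 0.0,
        )
    return session, rec


# --- analysis products ---------------------------------------------------


def _bin_time_s(bin_index: np.ndarray) -> np.ndarray:
    """Nominal time of a bin's left edge on the flat -5 .. +18 s axis."""
    return -PRE_S + BIN_S * np.asarray(bin_index, dtype=float)


def write_results(results, path: str | Path, windows: SignificanceWindows | None = None) -> Path:
    """Serialize an analysis product to CSV (waveforms/windows/AUC) or JSON.

    Waveforms go to long-format CSV
    ``bin_index,time_s,mean,ci_lo,ci_hi,significant_flag`` (the flag filled
    from ``windows`` when given); windows to ``start_s,end_s,direction``
    pairs; epoch AUCs to one row per snip; summaries and ANOVA results to
    JSON.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    try:
        if isinstance(results, BootstrapWaveform):
            nb = results.mean.size
            flag = np.zeros(nb, dtype=int)
            if windows is not None:
                for w in windows:
                    flag[w.start_bin : w.end_bin] = 1
            pd.DataFrame(
                {
                    "bin_index": np.arange(nb),
                    "time_s": _bin_time_s(np.arange(nb)),
                    "mean": results.mean,
                    "ci_lo": results.ci_lo,
                    "ci_hi": results.ci_hi,
                    "significant_flag": flag,
                }
            ).to_csv(path, index=False, float_format=_FLOAT_FMT)
        elif isinstance(results, SignificanceWindows):
            pd.DataFrame(
                {
                    "start_s": [_bin_time_s(w.start_bin) for w in results],
                    "end_s": [_bin_time_s(w.end_bin) for w in results],
                    "start_bin": [w.start_bin for w in results],
                    "end_bin": [w.end_bin for w in results],
                    "direction": [w.direction for w in results],
                }
            ).to_csv(path, index=False, float_format=_FLOAT_FMT)
        elif isinstance(results, EpochAUC):
            pd.DataFrame([dataclasses.asdict(results)]).to_csv(
                path, index=False, float_format=_FLOAT_FMT
            )
        elif isinstance(results, (SessionSummary,)):
            path.write_text(json.dumps(dataclasses.asdict(results), indent=1))
        elif isinstance(results, list) and all(dataclasses.is_dataclass(r) for r in results):
            path.write_text(json.dumps([dataclasses.asdict(r) for r in results], indent=1))
        elif isinstance(results, dict):
            path.write_text(json.dumps(results, indent=1, default=float))
        else:
            raise FormatError(f"no serializer for {type(results).__name__}")
    except OSError as exc:
        raise PeriboutIOError(f"cannot write {path}: {exc}") from exc
    return path


def read_waveform(path: str | Path) -> BootstrapWaveform:
    df = pd.read_csv(path)
    return BootstrapWaveform(
        mean=df["mean"].to_numpy(),
        ci_lo=df["ci_lo"].to_numpy(),
        ci_hi=df["ci_hi"].to_numpy(),
        n_bouts=0,
        n_boot=0,
        alpha=float("nan"),
        seed=0,
    )


def read_windows(path: str | Path) -> SignificanceWindows:
    df = pd.read_csv(path)
    return SignificanceWindows(
        windows=[
            Window(int(r.start_bin), int(r.end_bin), str(r.direction))
            for r in df.itertuples()
        ]
    )


# --- snip matrices -------------------------------------------------------


def write_snips(snips: list[PeriEventSnip], path: str | Path) -> Path:
    """Snip matrix CSV: one row per bout, 230 z columns plus metadata."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in snips:
        row = {
            "mouse_id": s.mouse_id,
            "bout_start_s": s.bout.start_s,
            "bout_end_s": s.bout.end_s,
            "n_licks": s.bout.n_licks,
            "artifact": int(s.artifact),
        }
        z = s.z if s.z is not None else np.full(s.values.size, np.nan)
        row.update({f"z{i}": z[i] for i in range(z.size)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_snips(path: str | Path) -> list[PeriEventSnip]:
    from .datatypes import Bout, N_SNIP_BINS

    df = pd.read_csv(path)
    zcols = [f"z{i}" for i in range(N_SNIP_BINS)]
    snips = []
    for r in df.itertuples():
        z = np.array([getattr(r, c) for c in zcols])
        s = PeriEventSnip(
            bout=Bout(r.bout_start_s, r.bout_end_s, int(r.n_licks)),
            values=z,  # raw values are not round-tripped; z carries the analysis
            z=z,
            artifact=bool(r.artifact),
            mouse_id=str(r.mouse_id),
        )
        snips.append(s)
    return snips


# --- multispout & in vitro ----------------------------------------------


def write_multispout(sessions: list[MultispoutSession], path: str | Path) -> Path:
    """Trial table CSV: ``mouse,treatment,trial,concentration_pct,licks``."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frames = []
    for s in sessions:
        frames.append(
            pd.DataFrame(
                {
                    "mouse": s.mouse_id,
                    "treatment": s.treatment,
                    "trial": np.arange(s.licks.size),
                    "concentration_pct": s.concentration_pct,
                    "licks": s.licks,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_multispout(path: str | Path) -> list[MultispoutSession]:
    path = Path(path)
    if not path.exists():
        raise PeriboutIOError(f"missing file: {path}")
    df = pd.read_csv(path)
    required = {"mouse", "treatment", "trial", "concentration_pct", "licks"}
    if not required.issubset(df.columns):
        raise FormatError(f"multispout CSV must have columns {sorted(required)}")
    out = []
    for (mouse, treatment), g in df.groupby(["mouse", "treatment"], sort=True):
        g = g.sort_values("trial")
        out.append(
            MultispoutSession(
                mouse_id=str(mouse),
                treatment=str(treatment),
                concentration_pct=g["concentration_pct"].to_numpy(),
                licks=g["licks"].to_numpy(),
            )
        )
    return out


def write_roi_trace(trace: ROITrace, path: str | Path) -> Path:
    """In vitro trace CSV ``frame,mean_gray`` with the ligand frame as a column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "frame": np.arange(trace.frames.size),
            "mean_gray": trace.frames,
            "ligand_frame": trace.ligand_frame,
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)
    return path


def read_roi_trace(path: str | Path, ligand_frame: int | None = None) -> ROITrace:
    path = Path(path)
    if not path.exists():
        raise PeriboutIOError(f"missing file: {path}")
    df = pd.read_csv(path)
    if ligand_frame is None:
        if "ligand_frame" not in df.columns:
            raise FormatError("ligand_frame not stored in file and not provided")
        ligand_frame = int(df["ligand_frame"].iloc[0])
    return ROITrace(frames=df["mean_gray"].to_numpy(), ligand_frame=ligand_frame)
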