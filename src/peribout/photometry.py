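"""From raw two-channel streams to z-scored peri-bout snips.

Stages: (1) frequency-domain subtraction of the 405 nm isosbestic channel
from the 465 nm sensor channel, removing bleaching and shared motion
artifacts while preserving sensor-specific transients; (2) extraction of
fixed-length peri-bout snips (5 s baseline, first 6 s + last 2 s of
licking, 10 s post) binned at 0.1 s; (3) per-snip baseline z-scoring;
(4) rejection of snips with large consecutive-bin jumps.
"""

from __future__ import annotations

import logging

import numpy as np

from .datatypes import (
    BASELINE,
    BIN_S,
    Bout,
    CorrectedTrace,
    LICK_EARLY_S,
    LICK_LATE_S,
    N_BASELINE_BINS,
    N_EARLY_BINS,
    N_LATE_BINS,
    N_POST_BINS,
    PeriEventSnip,
    PhotometryRecording,
    POST_S,
    PRE_S,
)
from .errors import DegenerateDataError, InsufficientDataError, InvalidParameterError

__all__ = [
    "correct_isosbestic",
    "extract_snips",
    "zscore_snip",
    "artifact_filter",
    "preprocess_session",
]

log = logging.getLogger(__name__)

LOWPASS_HZ = 0.05  # band used to fit the control channel onto the signal


def correct_isosbestic(rec: PhotometryRecording) -> CorrectedTrace:
    """Subtract the fitted 405 nm channel from the 465 nm channel.

    Both channels are transformed with an FFT; the control spectrum is fit
    to the signal spectrum by least squares over the sub-0.05 Hz band
    (where bleaching dominates), scaled, subtracted in the frequency
    domain, and the residual is inverted and divided by the fitted slow
    baseline to give fractional (dF/F-like) units.

    Components common to both channels — bleaching and shared artifacts —
    cancel; transients present only in the signal channel survive.
    """
    if rec.duration_s < 60:
        raise InsufficientDataError(
            f"need >= 60 s of data for a stable low-frequency fit, got {rec.duration_s:.1f} s"
        )
    n = rec.n_samples
    sig_f = np.fft.rfft(rec.ch_signal)
    ctl_f = np.fft.rfft(rec.ch_control)
    freqs = np.fft.rfftfreq(n, d=1.0 / rec.fs_hz)

    band = (freqs > 0) & (freqs <= LOWPASS_HZ)
    denom = np.sum(np.abs(ctl_f[band]) ** 2)
    scale_ref = np.sum(np.abs(sig_f[band]) ** 2)
    if denom <= 1e-12 * max(scale_ref, 1.0):
        raise DegenerateDataError(
            "control channel has no low-frequency structure (constant stream?)"
        )
    # real least-squares scale mapping control onto signal in the slow band
    a = float(np.real(np.sum(sig_f[band] * np.conj(ctl_f[band]))) / denom)

    resid_f = sig_f - a * ctl_f
    resid_f[0] = 0.0  # remove DC offset (the affine intercept)
    resid = np.fft.irfft(resid_f, n=n)

    baseline_f = np.zeros_like(sig_f)
    keep = freqs <= LOWPASS_HZ
    baseline_f[keep] = a * ctl_f[keep]
    baseline = np.fft.irfft(baseline_f, n=n)
    floor = 1e-6 * np.max(np.abs(baseline)) if np.max(np.abs(baseline)) > 0 else 1.0
    baseline = np.where(np.abs(baseline) < floor, floor, baseline)

    return CorrectedTrace(fs_hz=rec.fs_hz, values=resid / baseline, t0_s=rec.t0_s)


def extract_snips(
    trace: CorrectedTrace,
    bouts: list[Bout],
    min_bout_s: float = 4.0,
    pre_s: float = PRE_S,
    post_s: float = POST_S,
    bin_s: float = BIN_S,
) -> list[PeriEventSnip]:
    """Cut one fixed-length snip per sufficiently long bout.

    Only bouts with duration >= ``min_bout_s`` and full pre/post windows
    inside the recording are kept.  Layout per snip: 50 baseline bins
    (5 s before bout start), 60 early-lick bins, 20 late-lick bins (the
    final 2 s of licking), 100 post bins (10 s after bout end).  Bouts of
    at least 8 s use the literal first 6 s for the early grid; bouts of
    4-8 s have their licking period minus the final 2 s linearly
    time-rescaled onto the 60-bin early grid.  Each bin is the mean of the
    samples it covers.
    """
    for name, span in (("pre", pre_s), ("post", post_s)):
        nbins = span / bin_s
        if abs(nbins - round(nbins)) > 1e-9:
            raise InvalidParameterError(f"bin_s must divide the {name} window evenly")
    t0 = trace.t0_s
    fs = trace.fs_hz
    n = trace.values.size
    duration = n / fs
    snips: list[PeriEventSnip] = []
    n_skipped = 0
    for bout in bouts:
        if bout.duration_s < min_bout_s:
            continue
        if bout.start_s - pre_s < t0 or bout.end_s + post_s > t0 + duration:
            n_skipped += 1
            continue
        vals = np.concatenate(
            [
                _bin_means(trace.values, t0, fs, edges)
                for edges in _snip_segment_edges(bout, bin_s)
            ]
        )
        snips.append(PeriEventSnip(bout=bout, values=vals))
    if n_skipped:
        log.info("extract_snips: skipped %d bouts too close to recording edges", n_skipped)
    return snips


def _snip_segment_edges(bout: Bout, bin_s: float) -> list[np.ndarray]:
    """Per-segment absolute-time bin edges for one bout's snip.

    Separate edge chains keep the excluded middle of long bouts (between
    the first 6 s and the last 2 s of licking) out of every bin.
    """
    s, e = bout.start_s, bout.end_s
    late_start = e - LICK_LATE_S
    baseline = s - PRE_S + bin_s * np.arange(N_BASELINE_BINS + 1)
    if bout.duration_s >= LICK_EARLY_S + LICK_LATE_S:
        early = s + bin_s * np.arange(N_EARLY_BINS + 1)
    else:
        # stretch [start, end - 2 s] linearly onto the 60-bin early grid
        early = s + (late_start - s) * np.arange(N_EARLY_BINS + 1) / N_EARLY_BINS
    late = late_start + bin_s * np.arange(N_LATE_BINS + 1)
    post = e + bin_s * np.arange(N_POST_BINS + 1)
    return [baseline, early, late, post]


def _bin_means(values: np.ndarray, t0: float, fs: float, edges: np.ndarray) -> np.ndarray:
    """Mean of samples within each [edge_i, edge_{i+1}) bin.

    Stretched early-grid bins narrower than one sample fall back to linear
    interpolation at the bin centre.
    """
    idx = np.round((edges - t0) * fs).astype(int)
    idx = np.clip(idx, 0, values.size)
    csum = np.concatenate([[0.0], np.cumsum(values)])
    counts = np.diff(idx).astype(float)
    sums = csum[idx[1:]] - csum[idx[:-1]]
    out = np.empty(counts.size)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz]
    if not nz.all():
        centers = (edges[:-1] + edges[1:]) / 2.0
        tgrid = t0 + np.arange(values.size) / fs
        out[~nz] = np.interp(centers[~nz], tgrid, values)
    return out


def zscore_snip(snip: PeriEventSnip) -> PeriEventSnip:
    """Z-score a snip against its own 5-s pre-bout baseline.

    Baseline statistics use the 50 baseline bins (sample SD, n-1).  A
    zero-variance baseline flags the snip as artifact instead of dividing
    by zero.
    """
    base = snip.values[BASELINE]
    mu = float(np.mean(base))
    sd = float(np.std(base, ddof=1))
    snip.baseline_mean = mu
    snip.baseline_sd = sd
    if sd == 0:
        snip.artifact = True
        snip.z = np.zeros_like(snip.values)
        log.info("zscore_snip: zero baseline variance, snip flagged as artifact")
    else:
        snip.z = (snip.values - mu) / sd
    return snip


def artifact_filter(
    snips: list[PeriEventSnip], threshold: float = 12.0
) -> list[PeriEventSnip]:
    """Drop snips whose max |consecutive-bin difference| exceeds the threshold.

    The comparison is strict (``> threshold``) and runs on the corrected,
    binned, pre-z-score values.  Flagged snips are removed from the
    returned list; the removal count is logged.
    """
    kept = []
    n_removed = 0
    for s in snips:
        jumps = np.abs(np.diff(s.values))
        if jumps.size and float(np.max(jumps)) > threshold:
            s.artifact = True
            n_removed += 1
        elif s.artifact:
            n_removed += 1
        else:
            kept.append(s)
    if n_removed:
        log.info("artifact_filter: removed %d of %d snips", n_removed, len(snips))
    return kept


def preprocess_session(
    rec: PhotometryRecording,
    bouts: list[Bout],
    min_bout_s: float = 4.0,
    artifact_threshold: float = 12.0,
    mouse_id: str = "",
) -> list[PeriEventSnip]:
    """Full preprocessing chain: correct, snip, artifact-screen, z-score."""
    trace = correct_isosbestic(rec)
    snips = extract_snips(trace, bouts, min_bout_s=min_bout_s)
    snips = artifact_filter(snips, threshold=artifact_threshold)
    out = []
    for s in snips:
        s.mouse_id = mouse_id
        s = zscore_snip(s)
        if not s.artifact:
            out.append(s)
    return out
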