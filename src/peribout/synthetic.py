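"""Synthetic sessions with known ground truth.

The generator emulates the statistical structure the analysis assumes:

* lick trains organised into bouts (>= 3 licks, > 10 s apart) whose count,
  duration and intra-bout rate are condition parameters;
* two-channel photometry where bleaching and brief motion artifacts enter
  both channels multiplicatively (so they are common-mode up to channel
  gain) while the bout-locked transient enters the 465 nm channel only;
* the transient kernel is piecewise linear in fractional (dF/F) units:
  it ramps down to ``-transient_amplitude`` starting
  ``suppression_onset_s`` after bout start, holds through the bout, and
  after bout end either stays suppressed for ``suppression_offset_s``
  before recovering (VMH-like) or overshoots above baseline from
  ``rebound_onset_s`` onward (PVH-like);
* multispout sessions of 100 trials (5 sucrose concentrations x 20) with
  negative-binomial lick counts whose mean scales with concentration and a
  multiplicative treatment effect.

Every function takes an explicit integer seed and is reproducible
bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .datatypes import (
    Bout,
    LickSession,
    MultispoutSession,
    PhotometryRecording,
    ROITrace,
    SUCROSE_CONCENTRATIONS,
    TRIALS_PER_CONCENTRATION,
)
from .errors import InvalidParameterError

__all__ = [
    "BoutModel",
    "GroundTruth",
    "gen_lick_session",
    "gen_photometry",
    "gen_multispout_session",
    "gen_multispout_cohort",
    "gen_roi_trace",
    "pvh_like_truth",
    "vmh_like_truth",
    "expected_binned_noise_sd",
    "DEFAULT_MULTISPOUT_RATES_HZ",
    "LHISTIDINE_EFFECT",
]


@dataclass(frozen=True)
class BoutModel:
    """Condition-level parameters of the bout-structured lick train.

    ``bout_duration_mean_s`` / ``bout_duration_sd_s`` are the natural-scale
    mean and SD of a log-normal bout-duration distribution.  The inter-bout
    gap is ``inter_bout_gap_min_s`` plus an exponential excess so generated
    bouts are always separable under the 10-s rule.
    """

    bouts_per_session: float = 20.0
    bout_duration_mean_s: float = 12.0
    bout_duration_sd_s: float = 6.0
    intra_bout_lick_rate_hz: float = 8.0
    inter_bout_gap_min_s: float = 15.0
    inter_bout_gap_excess_mean_s: float = 25.0
    session_duration_s: float = 1800.0

    def __post_init__(self) -> None:
        if self.session_duration_s <= 0:
            raise InvalidParameterError("session_duration_s must be positive")
        if not (0 < self.intra_bout_lick_rate_hz <= 12):
            raise InvalidParameterError("intra_bout_lick_rate_hz must be in (0, 12]")
        if self.inter_bout_gap_min_s <= 10:
            raise InvalidParameterError(
                "inter_bout_gap_min_s must exceed 10 s so bouts stay separable"
            )
        if self.bouts_per_session < 0 or self.bout_duration_mean_s <= 0:
            raise InvalidParameterError("bout count and duration must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """Parameters of the injected photometry signal, in fractional units.

    ``transient_amplitude`` is the depth of the licking-evoked suppression
    as a fraction of the fluorescence baseline.  Timing fields are seconds
    relative to bout start (onset) or bout end (offset / rebound).
    """

    transient_amplitude: float = 0.02
    suppression_onset_s: float = 0.3
    suppression_offset_s: float = 10.0
    rebound: bool = False
    rebound_onset_s: float = 4.0
    rebound_amplitude: float | None = None  # defaults to half the suppression
    bleach_tau_s: float = 900.0
    artifact_times_s: tuple[float, ...] = ()
    noise_sd: float = 0.004
    seed: int = 0
    # secondary shape/channel parameters
    ramp_s: float = 1.0
    recovery_s: float = 2.0
    bleach_frac_inf: float = 0.25
    control_level: float = 120.0
    signal_gain: float = 1.8
    artifact_amplitude: float = 0.2
    artifact_width_s: float = 0.1

    def __post_init__(self) -> None:
        if not math.isfinite(self.transient_amplitude):
            raise InvalidParameterError("transient_amplitude must be finite")
        if self.suppression_onset_s < 0 or self.suppression_offset_s < 0:
            raise InvalidParameterError("onset/offset must be >= 0")
        if self.noise_sd < 0 or self.bleach_tau_s <= 0:
            raise InvalidParameterError("noise_sd >= 0 and bleach_tau_s > 0 required")

    @property
    def rebound_amp(self) -> float:
        if self.rebound_amplitude is not None:
            return self.rebound_amplitude
        return 0.5 * self.transient_amplitude


def pvh_like_truth(**overrides) -> GroundTruth:
    """Ground truth mimicking PVH dynamics: post-bout rebound above baseline."""
    kw = dict(rebound=True, rebound_onset_s=4.0)
    kw.update(overrides)
    return GroundTruth(**kw)


def vmh_like_truth(**overrides) -> GroundTruth:
    """Ground truth mimicking VMH dynamics: suppression sustained >= 10 s post-bout."""
    kw = dict(rebound=False, suppression_offset_s=10.0)
    kw.update(overrides)
    return GroundTruth(**kw)


# --- lick trains ---------------------------------------------------------


def gen_lick_session(
    model: BoutModel,
    condition: str = "Restricted",
    seed: int = 0,
    mouse_id: str = "sim",
    region: str = "none",
) -> tuple[LickSession, list[Bout]]:
    """Draw one bout-structured lick session plus its ground-truth bouts.

    The bout count is Poisson around ``model.bouts_per_session``; bouts are
    placed sequentially with gaps ``gap_min + Exp(excess)`` and truncated at
    the session end.  Within a bout, inter-lick intervals are gamma-jittered
    and rescaled so the last lick lands exactly at start + duration; every
    bout has >= 3 licks and internal intervals far below 10 s.
    """
    rng = np.random.default_rng(seed)
    n_target = int(rng.poisson(model.bouts_per_session))
    licks: list[np.ndarray] = []
    bouts: list[Bout] = []
    t = float(rng.uniform(2.0, model.inter_bout_gap_min_s + model.inter_bout_gap_excess_mean_s))
    for _ in range(n_target):
        dur = _lognormal(rng, model.bout_duration_mean_s, model.bout_duration_sd_s)
        if t + dur > model.session_duration_s - 1.0:
            break
        n_licks = max(3, int(round(dur * model.intra_bout_lick_rate_hz)) + 1)
        ili = rng.gamma(shape=5.0, scale=1.0, size=n_licks - 1)
        times = t + np.concatenate([[0.0], np.cumsum(ili / ili.sum() * dur)])
        times[-1] = t + dur  # exact endpoint despite float accumulation
        licks.append(times)
        bouts.append(Bout(start_s=t, end_s=t + dur, n_licks=n_licks))
        t += dur + model.inter_bout_gap_min_s + rng.exponential(model.inter_bout_gap_excess_mean_s)
    all_licks = np.concatenate(licks) if licks else np.empty(0)
    session = LickSession(
        mouse_id=mouse_id,
        region=region,
        condition=condition,
        session_duration_s=model.session_duration_s,
        lick_times_s=all_licks,
    )
    return session, bouts


def _lognormal(rng: np.random.Generator, mean: float, sd: float) -> float:
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


# --- photometry ----------------------------------------------------------


def gen_photometry(
    session: LickSession,
    truth: GroundTruth,
    fs_hz: float = 100.0,
    bouts: list[Bout] | None = None,
) -> PhotometryRecording:
    """Simulate paired 465/405 streams for a lick session.

    Both channels share a single-exponential bleach and multiplicative
    motion artifacts; the bout-locked transient kernel multiplies the
    465 nm channel only.  With zero amplitude, zero noise and no artifacts
    the signal channel is an exact scalar multiple of the control channel.
    """
    if fs_hz < 20:
        raise InvalidParameterError("fs_hz must be >= 20 to support 0.1-s bins")
    if session is None:
        raise InvalidParameterError("session must not be None")
    rng = np.random.default_rng(truth.seed)
    n = int(round(session.session_duration_s * fs_hz))
    t = np.arange(n) / fs_hz

    bleach = truth.bleach_frac_inf + (1 - truth.bleach_frac_inf) * np.exp(
        -t / truth.bleach_tau_s
    )
    art = np.zeros(n)
    for t0 in truth.artifact_times_s:
        lo = max(0, int((t0 - 5 * truth.artifact_width_s) * fs_hz))
        hi = min(n, int((t0 + 5 * truth.artifact_width_s) * fs_hz) + 1)
        art[lo:hi] += truth.artifact_amplitude * np.exp(
            -0.5 * ((t[lo:hi] - t0) / truth.artifact_width_s) ** 2
        )

    if bouts is None:
        from .licks import detect_bouts

        bouts = detect_bouts(session)
    kernel = transient_kernel(t, bouts, truth)

    base_c = truth.control_level
    base_s = truth.control_level * truth.signal_gain
    noise_c = rng.normal(0.0, truth.noise_sd * base_c, size=n) if truth.noise_sd else 0.0
    noise_s = rng.normal(0.0, truth.noise_sd * base_s, size=n) if truth.noise_sd else 0.0
    ch_control = base_c * bleach * (1 + art) + noise_c
    ch_signal = base_s * bleach * (1 + kernel) * (1 + art) + noise_s
    return PhotometryRecording(fs_hz=fs_hz, ch_signal=ch_signal, ch_control=ch_control)


def transient_kernel(t: np.ndarray, bouts: list[Bout], truth: GroundTruth) -> np.ndarray:
    """Sum of per-bout piecewise-linear transients, in fractional units."""
    out = np.zeros_like(t)
    amp = truth.transient_amplitude
    for b in bouts:
        s, e = b.start_s, b.end_s
        on = s + truth.suppression_onset_s
        knots = [(on, 0.0), (on + truth.ramp_s, -amp)]
        if e > on + truth.ramp_s:
            knots.append((e, -amp))
        if truth.rebound:
            # overshoot above baseline after the bout, then settle back
            knots += [
                (e + truth.rebound_onset_s, truth.rebound_amp),
                (e + 10.0, truth.rebound_amp),
                (e + 10.0 + truth.recovery_s, 0.0),
            ]
        else:
            knots += [
                (e + truth.suppression_offset_s, -amp),
                (e + truth.suppression_offset_s + truth.recovery_s, 0.0),
            ]
        kt = np.array([k[0] for k in knots])
        kv = np.array([k[1] for k in knots])
        lo, hi = np.searchsorted(t, [kt[0], kt[-1]])
        if lo < hi:
            out[lo:hi] += np.interp(t[lo:hi], kt, kv)
    return out


def expected_binned_noise_sd(
    truth: GroundTruth, fs_hz: float, bin_s: float = 0.1, bleach: float = 1.0
) -> float:
    """Approximate SD of one 0.1-s bin of the corrected trace, noise only.

    The isosbestic correction subtracts ``gain * control`` from the signal
    and divides by the fitted slow baseline.  With both channels carrying
    independent noise proportional to their own level (fractional SD
    ``sigma``), the numerator noise SD is ``sigma * gain * level * sqrt(2)``
    and the baseline is ``gain * level * bleach``, giving a per-sample
    corrected SD of ``sigma * sqrt(2) / bleach``, reduced by
    ``sqrt(fs * bin_s)`` on binning.  Used to convert fractional amplitudes
    to z units when designing simulations.
    """
    per_sample = truth.noise_sd * math.sqrt(2.0) / bleach
    return per_sample / math.sqrt(fs_hz * bin_s)


# --- multispout ----------------------------------------------------------

#: Vehicle-condition lick rates (Hz during the 3-s access window) rising
#: monotonically with sucrose concentration; session totals land near the
#: grouped means these defaults are calibrated to.
DEFAULT_MULTISPOUT_RATES_HZ = {0: 0.65, 5: 1.5, 10: 2.0, 20: 2.4, 30: 3.0}

#: Multiplicative effect of L-histidine on lick rate (244.88 / 572.38).
LHISTIDINE_EFFECT = 244.88 / 572.38

ACCESS_S = 3.0


def gen_multispout_session(
    mouse: str,
    treatment: str,
    rates: dict[int | float, float],
    effect: float = 1.0,
    seed: int = 0,
    dispersion: float = 8.0,
    mouse_factor: float = 1.0,
) -> MultispoutSession:
    """One 100-trial multispout session (5 concentrations x 20 trials).

    Concentration order is a seeded pseudorandom permutation.  Per-trial
    lick counts are negative binomial with mean
    ``rate * 3 s * mouse_factor * (effect if treatment != "vehicle")``;
    ``dispersion`` is the NB size parameter (larger = closer to Poisson).
    """
    missing = [c for c in SUCROSE_CONCENTRATIONS if c not in rates]
    if missing:
        raise InvalidParameterError(f"rates table missing concentrations: {missing}")
    if any(rates[c] < 0 for c in SUCROSE_CONCENTRATIONS):
        raise InvalidParameterError("rates must be >= 0")
    rng = np.random.default_rng(seed)
    concs = np.repeat(SUCROSE_CONCENTRATIONS, TRIALS_PER_CONCENTRATION)
    concs = rng.permutation(concs)
    treated = treatment.lower() not in ("vehicle", "saline")
    mult = mouse_factor * (effect if treated else 1.0)
    means = np.array([rates[c] * ACCESS_S * mult for c in concs])
    p = dispersion / (dispersion + means)
    licks = rng.negative_binomial(dispersion, p)
    return MultispoutSession(
        mouse_id=mouse, treatment=treatment, concentration_pct=concs, licks=licks
    )


def gen_multispout_cohort(
    n_mice: int = 8,
    rates: dict | None = None,
    effect: float = LHISTIDINE_EFFECT,
    dispersion: float = 8.0,
    mouse_cv: float = 0.25,
    seed: int = 0,
) -> list[MultispoutSession]:
    """Vehicle + L-histidine sessions for a cohort with mouse-level scaling.

    Each mouse carries a log-normal multiplicative factor (CV ``mouse_cv``)
    shared across its two sessions, giving realistic between-subject spread
    while keeping the treatment contrast within-subject.
    """
    if rates is None:
        rates = DEFAULT_MULTISPOUT_RATES_HZ
    rng = np.random.default_rng(seed)
    sessions = []
    for i in range(n_mice):
        mf = _lognormal(rng, 1.0, mouse_cv) if mouse_cv > 0 else 1.0
        for treatment in ("vehicle", "L-histidine"):
            sessions.append(
                gen_multispout_session(
                    mouse=f"m{i}",
                    treatment=treatment,
                    rates=rates,
                    effect=effect,
                    seed=int(rng.integers(2**31)),
                    dispersion=dispersion,
                    mouse_factor=mf,
                )
            )
    return sessions


# --- in vitro ------------------------------------------------------------


def gen_roi_trace(
    baseline_f: float = 100.0,
    peak_dff: float = 1.5,
    ligand_frame: int = 15,
    n_frames: int = 60,
    rise_frames: int = 3,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> ROITrace:
    """Timelapse of one ROI: flat baseline, sigmoid-free linear rise to a plateau."""
    rng = np.random.default_rng(seed)
    f = np.full(n_frames, baseline_f, dtype=float)
    plateau = baseline_f * (1 + peak_dff)
    rise_end = min(n_frames, ligand_frame + rise_frames)
    f[ligand_frame:rise_end] = np.linspace(baseline_f, plateau, rise_end - ligand_frame)
    f[rise_end:] = plateau
    if noise_sd:
        f = f + rng.normal(0, noise_sd, size=n_frames)
    return ROITrace(frames=np.clip(f, 0, None), ligand_frame=ligand_frame)
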