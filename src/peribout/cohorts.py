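"""Reference synthetic cohorts for end-to-end evaluation of the pipeline.

These helpers bundle the generator and the preprocessing chain into the
study-level units the waveform statistics operate on: a region cohort is a
pool of z-scored peri-bout snips from several sessions sharing one ground
truth profile (PVH-like rebound or VMH-like sustained suppression).
"""

from __future__ import annotations

import math

import numpy as np

from .datatypes import BASELINE, PeriEventSnip
from .photometry import preprocess_session
from .synthetic import (
    BoutModel,
    GroundTruth,
    expected_binned_noise_sd,
    gen_lick_session,
    gen_photometry,
    pvh_like_truth,
    vmh_like_truth,
)

__all__ = ["build_region_cohort", "null_snip_matrix", "amplitude_for_z"]

#: Session model used by the reference cohorts: 30-min sessions with ~25
#: bouts long enough (mostly >= 8 s) to enter the strict snip analysis.
COHORT_MODEL = BoutModel(
    bouts_per_session=25.0,
    bout_duration_mean_s=12.0,
    bout_duration_sd_s=4.0,
)


def amplitude_for_z(z_units: float, noise_sd: float, fs_hz: float) -> float:
    """Fractional transient amplitude whose depth is ~``z_units`` after z-scoring.

    Uses the corrected-trace noise model at mid-session bleach, so the
    realised per-snip amplitude varies with the bleach level around this
    target.
    """
    proto = GroundTruth(noise_sd=noise_sd)
    mid_t = COHORT_MODEL.session_duration_s / 2
    bleach_mid = proto.bleach_frac_inf + (1 - proto.bleach_frac_inf) * math.exp(
        -mid_t / proto.bleach_tau_s
    )
    return z_units * expected_binned_noise_sd(proto, fs_hz, bleach=bleach_mid)


def build_region_cohort(
    profile: str,
    n_sessions: int = 10,
    amplitude_z: float = 2.0,
    noise_sd: float = 0.01,
    fs_hz: float = 100.0,
    min_bout_s: float = 8.0,
    seed: int = 0,
    model: BoutModel | None = None,
) -> list[PeriEventSnip]:
    """Pooled z-scored snips from ``n_sessions`` sessions of one profile.

    ``profile`` is ``"pvh"`` (post-bout rebound above baseline) or
    ``"vmh"`` (suppression sustained through the post window).
    """
    if profile not in ("pvh", "vmh"):
        raise ValueError("profile must be 'pvh' or 'vmh'")
    factory = pvh_like_truth if profile == "pvh" else vmh_like_truth
    model = model or COHORT_MODEL
    amp = amplitude_for_z(amplitude_z, noise_sd, fs_hz)
    snips: list[PeriEventSnip] = []
    for i in range(n_sessions):
        s_seed = seed + 7919 * (i + 1)
        session, bouts = gen_lick_session(model, seed=s_seed, mouse_id=f"{profile}{i:02d}")
        truth = factory(
            transient_amplitude=amp, noise_sd=noise_sd, seed=s_seed + 1
        )
        rec = gen_photometry(session, truth, fs_hz=fs_hz, bouts=bouts)
        snips.extend(
            preprocess_session(rec, bouts, min_bout_s=min_bout_s, mouse_id=session.mouse_id)
        )
    return snips


def null_snip_matrix(n_snips: int, n_bins: int = 230, seed: int = 0) -> np.ndarray:
    """Baseline-z-scored white-noise snips: the pipeline's null condition."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n_snips, n_bins))
    base = x[:, BASELINE]
    return (x - base.mean(axis=1, keepdims=True)) / base.std(axis=1, ddof=1, keepdims=True)
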