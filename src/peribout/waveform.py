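"""Bootstrapped waveform inference on peri-bout snips.

The bootstrapped mean trace and its 95% percentile confidence interval are
computed per 0.1-s bin by resampling bout snips with replacement.  A
deflection is declared a true fluctuation when the CI excludes the
reference (zero) for at least six consecutive bins (0.6 s, matching the
low-pass bandwidth of the photometry signal); two waveforms are declared
different where their CIs fail to overlap for at least six consecutive
bins.
"""

from __future__ import annotations

import numpy as np

from .datatypes import (
    BASELINE,
    BIN_S,
    BootstrapWaveform,
    EPOCHS,
    EpochAUC,
    N_SNIP_BINS,
    PeriEventSnip,
    SignificanceWindows,
    Window,
)
from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "bootstrap_waveform",
    "significant_windows",
    "compare_waveforms",
    "epoch_auc",
    "snip_matrix",
]


def snip_matrix(snips: list[PeriEventSnip]) -> np.ndarray:
    """Stack non-artifact z-scored snips into an (n_bouts, 230) matrix."""
    rows = [s.z for s in snips if not s.artifact and s.z is not None]
    if not rows:
        return np.empty((0, N_SNIP_BINS))
    return np.vstack(rows)


def bootstrap_waveform(
    snips: list[PeriEventSnip] | np.ndarray,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    stratify_by_mouse: bool = False,
) -> BootstrapWaveform:
    """Bootstrapped per-bin mean and percentile CI over bout snips.

    Each replicate resamples ``n_bouts`` snips with replacement (pooled
    across mice by default; ``stratify_by_mouse`` resamples within mouse,
    preserving each mouse's bout count) and averages per bin.  ``ci_lo`` /
    ``ci_hi`` are the alpha/2 and 1-alpha/2 percentiles of the replicate
    means; ``mean`` is the plug-in sample mean.  Deterministic given seed.
    """
    if isinstance(snips, np.ndarray):
        z = np.asarray(snips, dtype=float)
        groups = None
    else:
        z = snip_matrix(snips)
        groups = [s.mouse_id for s in snips if not s.artifact and s.z is not None]
    n = z.shape[0]
    if n < 2:
        raise InsufficientDataError(f"need >= 2 non-artifact snips, got {n}")
    rng = np.random.default_rng(seed)
    if stratify_by_mouse and groups is not None:
        idx_by_mouse = {}
        for i, m in enumerate(groups):
            idx_by_mouse.setdefault(m, []).append(i)
        reps = np.zeros((n_boot, z.shape[1]))
        for members in idx_by_mouse.values():
            members = np.asarray(members)
            pick = members[rng.integers(0, members.size, size=(n_boot, members.size))]
            reps += z[pick].sum(axis=1)
        reps /= n
    else:
        pick = rng.integers(0, n, size=(n_boot, n))
        reps = z[pick].mean(axis=1)
    lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
    return BootstrapWaveform(
        mean=z.mean(axis=0),
        ci_lo=lo,
        ci_hi=hi,
        n_bouts=n,
        n_boot=n_boot,
        alpha=alpha,
        seed=seed,
    )


def _runs(mask: np.ndarray, min_consecutive: int, direction: str) -> list[Window]:
    windows = []
    start = None
    for i, m in enumerate(mask):
        if m and start is None:
            start = i
        elif not m and start is not None:
            if i - start >= min_consecutive:
                windows.append(Window(start, i, direction))
            start = None
    if start is not None and mask.size - start >= min_consecutive:
        windows.append(Window(start, mask.size, direction))
    return windows


def significant_windows(
    bw: BootstrapWaveform,
    min_consecutive: int = 6,
    reference: float = 0.0,
    exclude_baseline: bool = True,
) -> SignificanceWindows:
    """Maximal runs of bins whose CI excludes the reference.

    ``direction="above"`` where ``ci_lo > reference`` and ``"below"`` where
    ``ci_hi < reference``; runs shorter than ``min_consecutive`` bins are
    dropped.  Baseline bins are excluded by default (they define zero).
    """
    above = bw.ci_lo > reference
    below = bw.ci_hi < reference
    if exclude_baseline:
        above = above.copy()
        below = below.copy()
        above[BASELINE] = False
        below[BASELINE] = False
    windows = _runs(above, min_consecutive, "above") + _runs(below, min_consecutive, "below")
    windows.sort(key=lambda w: w.start_bin)
    return SignificanceWindows(windows=windows)


def compare_waveforms(
    a: BootstrapWaveform,
    b: BootstrapWaveform,
    min_consecutive: int = 6,
    exclude_baseline: bool = True,
) -> SignificanceWindows:
    """Bins where the two waveforms' CIs fail to overlap for >= min_consecutive.

    Intervals touching at exactly one endpoint count as overlapping
    (conservative).  Direction is "above" where ``a``'s mean exceeds
    ``b``'s in the disjoint run, "below" otherwise.
    """
    if a.mean.shape != b.mean.shape:
        raise InvalidInputError("waveforms are on different bin grids")
    a_above = a.ci_lo > b.ci_hi
    b_above = b.ci_lo > a.ci_hi
    if exclude_baseline:
        a_above = a_above.copy()
        b_above = b_above.copy()
        a_above[BASELINE] = False
        b_above[BASELINE] = False
    windows = _runs(a_above, min_consecutive, "above") + _runs(
        b_above, min_consecutive, "below"
    )
    windows.sort(key=lambda w: w.start_bin)
    return SignificanceWindows(windows=windows)


def epoch_auc(z: np.ndarray | PeriEventSnip) -> EpochAUC:
    """Signed area (z * s) of the snip within each behavioral epoch.

    Epochs: early licking (first 6 s of the bout), late licking (final
    2 s), and the 10 s post-bout split into two 5-s bins.  Each 0.1-s bin
    contributes ``z * 0.1`` (area of the binned step function), so a snip
    at z = 1 across a 5-s epoch scores exactly 5 z*s.
    """
    if isinstance(z, PeriEventSnip):
        if z.artifact or z.z is None:
            raise InvalidInputError("epoch_auc requires a z-scored, non-artifact snip")
        z = z.z
    z = np.asarray(z, dtype=float)
    if z.shape != (N_SNIP_BINS,):
        raise InvalidInputError(f"expected a {N_SNIP_BINS}-bin snip")
    vals = {name: float(np.sum(z[sl]) * BIN_S) for name, sl in EPOCHS.items()}
    return EpochAUC(**vals)
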