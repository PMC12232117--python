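"""Lick-bout detection and session-level microstructure summaries.

A bout is a cluster of at least ``min_licks`` licks whose internal
inter-lick intervals are all shorter than ``gap_s``; clusters are split
wherever an interval is >= ``gap_s`` ("at least 10 s separating one bout
from another"), and sub-threshold clusters are discarded rather than merged
into neighbours.  This is deliberately not the classical burst/cluster
microstructure hierarchy.
"""

from __future__ import annotations

import numpy as np

from .datatypes import Bout, LickSession, SessionSummary

__all__ = ["detect_bouts", "summarize_session"]


def detect_bouts(
    session: LickSession, min_licks: int = 3, gap_s: float = 10.0
) -> list[Bout]:
    """Partition licks into maximal clusters and keep those with enough licks.

    An inter-lick interval exactly equal to ``gap_s`` splits clusters.
    Returns bouts in time order; empty input yields an empty list.
    """
    t = session.lick_times_s
    if t.size == 0:
        return []
    # split indices where the gap to the previous lick is >= gap_s
    breaks = np.nonzero(np.diff(t) >= gap_s)[0] + 1
    bouts: list[Bout] = []
    for cluster in np.split(t, breaks):
        if cluster.size >= min_licks:
            bouts.append(
                Bout(start_s=float(cluster[0]), end_s=float(cluster[-1]), n_licks=int(cluster.size))
            )
    return bouts


def summarize_session(session: LickSession, bouts: list[Bout]) -> SessionSummary:
    """Session totals: licks, bouts, mean bout length, intra-bout lick rate.

    Lick frequency is estimated from within-bout inter-lick intervals:
    ``sum(n_licks - 1) / sum(duration)`` over bouts, i.e. the reciprocal of
    the mean intra-bout ILI.  With no bouts both means are 0.
    """
    n_bouts = len(bouts)
    if n_bouts == 0:
        return SessionSummary(
            total_licks=int(session.lick_times_s.size),
            n_bouts=0,
            mean_bout_duration_s=0.0,
            lick_frequency_hz=0.0,
        )
    durations = np.array([b.duration_s for b in bouts])
    intervals = np.array([b.n_licks - 1 for b in bouts], dtype=float)
    total_dur = float(durations.sum())
    freq = float(intervals.sum() / total_dur) if total_dur > 0 else 0.0
    return SessionSummary(
        total_licks=int(session.lick_times_s.size),
        n_bouts=n_bouts,
        mean_bout_duration_s=float(durations.mean()),
        lick_frequency_hz=freq,
    )
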