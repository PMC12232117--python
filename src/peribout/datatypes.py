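"""Core containers shared by all analysis stages.

The peri-event grid is fixed across the pipeline: snips are 230 bins of
0.1 s, covering 5 s of pre-bout baseline, a 6 s + 2 s bout-aligned licking
period, and 10 s post-bout.  Segment boundaries live here so that every
module indexes the same layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError

# --- fixed analysis grid -------------------------------------------------

BIN_S = 0.1
PRE_S = 5.0
POST_S = 10.0
LICK_EARLY_S = 6.0
LICK_LATE_S = 2.0

N_BASELINE_BINS = int(round(PRE_S / BIN_S))          # 50
N_EARLY_BINS = int(round(LICK_EARLY_S / BIN_S))      # 60
N_LATE_BINS = int(round(LICK_LATE_S / BIN_S))        # 20
N_POST_BINS = int(round(POST_S / BIN_S))             # 100
N_SNIP_BINS = N_BASELINE_BINS + N_EARLY_BINS + N_LATE_BINS + N_POST_BINS  # 230

BASELINE = slice(0, 50)
LICK_EARLY = slice(50, 110)
LICK_LATE = slice(110, 130)
POST = slice(130, 230)
EARLY_POST = slice(130, 180)
LATE_POST = slice(180, 230)

#: Epoch name -> bin slice used by the AUC analysis.
EPOCHS = {
    "early_lick": LICK_EARLY,
    "late_lick": LICK_LATE,
    "early_post": EARLY_POST,
    "late_post": LATE_POST,
}

CONDITIONS = ("Restricted", "Light", "Dark", "Sucralose")
REGIONS = ("PVH", "VMH", "none")


# --- behavior ------------------------------------------------------------


@dataclass(frozen=True)
class Bout:
    """A cluster of >= 3 licks separated from neighbours by > 10 s."""

    start_s: float
    end_s: float
    n_licks: int

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class LickSession:
    """Timestamped licks from one recording session.

    lick_times_s must be strictly increasing and lie in
    ``[0, session_duration_s]``.
    """

    mouse_id: str
    region: str
    condition: str
    session_duration_s: float
    lick_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.lick_times_s = np.asarray(self.lick_times_s, dtype=float)
        if self.lick_times_s.ndim != 1:
            raise InvalidInputError("lick_times_s must be a 1-D array")
        if self.lick_times_s.size and (
            np.any(np.diff(self.lick_times_s) <= 0)
            or self.lick_times_s[0] < 0
            or self.lick_times_s[-1] > self.session_duration_s
        ):
            raise InvalidInputError(
                "lick times must be strictly increasing within "
                f"[0, {self.session_duration_s}]"
            )


@dataclass(frozen=True)
class SessionSummary:
    total_licks: int
    n_bouts: int
    mean_bout_duration_s: float
    lick_frequency_hz: float


# --- photometry ----------------------------------------------------------


@dataclass
class PhotometryRecording:
    """Paired 465 nm (sensor) and 405 nm (isosbestic control) streams."""

    fs_hz: float
    ch_signal: np.ndarray
    ch_control: np.ndarray
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.ch_signal = np.asarray(self.ch_signal, dtype=float)
        self.ch_control = np.asarray(self.ch_control, dtype=float)
        if self.ch_signal.shape != self.ch_control.shape:
            raise InvalidInputError("signal and control streams differ in length")
        if self.fs_hz <= 0:
            raise InvalidInputError("fs_hz must be positive")
        if not (np.all(np.isfinite(self.ch_signal)) and np.all(np.isfinite(self.ch_control))):
            raise InvalidInputError("photometry streams must be finite")

    @property
    def n_samples(self) -> int:
        return self.ch_signal.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.fs_hz


@dataclass
class CorrectedTrace:
    """Isosbestic-corrected signal in fractional (dF/F-like) units."""

    fs_hz: float
    values: np.ndarray
    t0_s: float = 0.0

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.values.size) / self.fs_hz


@dataclass
class PeriEventSnip:
    """One bout-locked excerpt on the fixed 230-bin grid.

    ``values`` holds corrected (pre-z-score) binned amplitudes; ``z`` is
    filled in by baseline z-scoring.  ``artifact`` marks snips excluded
    downstream (threshold crossing or zero baseline variance).
    """

    bout: Bout
    values: np.ndarray
    z: np.ndarray | None = None
    artifact: bool = False
    baseline_mean: float = float("nan")
    baseline_sd: float = float("nan")
    mouse_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_SNIP_BINS,):
            raise InvalidInputError(
                f"snip must have exactly {N_SNIP_BINS} bins, got {self.values.shape}"
            )


def snip_bin_times() -> np.ndarray:
    """Nominal time (s, relative to bout start) of each bin's left edge.

    Baseline and early-lick bins are anchored to bout start; late-lick and
    post bins are anchored to bout end (the grid is piecewise because the
    middle of long bouts is excluded).  Post-bin i maps to ``i * 0.1`` s
    after bout end.
    """
    t = np.empty(N_SNIP_BINS)
    t[BASELINE] = -PRE_S + BIN_S * np.arange(N_BASELINE_BINS)
    t[LICK_EARLY] = BIN_S * np.arange(N_EARLY_BINS)
    # late-lick and post bins: time relative to bout end
    t[LICK_LATE] = -LICK_LATE_S + BIN_S * np.arange(N_LATE_BINS)
    t[POST] = BIN_S * np.arange(N_POST_BINS)
    return t


# --- waveform inference --------------------------------------------------


@dataclass
class BootstrapWaveform:
    """Per-bin bootstrapped mean with a percentile confidence interval."""

    mean: np.ndarray
    ci_lo: np.ndarray
    ci_hi: np.ndarray
    n_bouts: int
    n_boot: int
    alpha: float
    seed: int


@dataclass(frozen=True)
class Window:
    """Half-open run of bins where the inference rule fired."""

    start_bin: int
    end_bin: int
    direction: str  # "above" | "below"

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin


@dataclass
class SignificanceWindows:
    windows: list[Window] = field(default_factory=list)

    def __iter__(self):
        return iter(self.windows)

    def __len__(self) -> int:
        return len(self.windows)


@dataclass(frozen=True)
class EpochAUC:
    """Signed area (z * s) of a snip within each behavioral epoch."""

    early_lick: float
    late_lick: float
    early_post: float
    late_post: float


# --- multispout & in vitro ----------------------------------------------

SUCROSE_CONCENTRATIONS = (0, 5, 10, 20, 30)
TRIALS_PER_CONCENTRATION = 20


@dataclass
class MultispoutSession:
    """Per-trial lick counts from one head-fixed multispout session."""

    mouse_id: str
    treatment: str
    concentration_pct: np.ndarray  # per trial
    licks: np.ndarray              # per trial

    def __post_init__(self) -> None:
        self.concentration_pct = np.asarray(self.concentration_pct)
        self.licks = np.asarray(self.licks, dtype=int)
        if self.concentration_pct.shape != self.licks.shape:
            raise InvalidInputError("trial arrays differ in length")


@dataclass
class ROITrace:
    """Mean-gray-value timelapse of one cell-membrane ROI."""

    frames: np.ndarray
    ligand_frame: int

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.ligand_frame < 10:
            raise InvalidInputError(
                "ligand_frame must be >= 10 (10 pre-ligand frames define F0)"
            )
        if np.any(self.frames < 0):
            raise InvalidInputError("mean gray values must be non-negative")
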