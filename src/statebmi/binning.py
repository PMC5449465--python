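"""Discretization of spike trains into count matrices and decoder features.

Spike times are binned into a pre-stimulus count matrix ``Theta`` (the state
variables) and a post-stimulus count matrix ``R`` (the evoked response).  The
pre-stimulus schedule is adaptive -- coarse bins far from stimulus onset,
fine 5 ms bins immediately before it, 39 bins in total by default -- while
post-stimulus bins are uniformly 5 ms wide starting at the end of the
artifact-blanking interval.  Per-trial matrices are flattened into feature
vectors in one of three variants:

* ``SI``    -- post-stimulus counts only (state-independent);
* ``SD-TA`` -- post counts plus one time-averaged pre-stimulus value per unit;
* ``SD-TD`` -- post counts plus the full pre-stimulus time course.

Feature order is unit-major: for each unit, its pre-stimulus features come
first (oldest bin first), then its post-stimulus counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .neural_sim import SpikeSession, Trial

__all__ = [
    "Variant",
    "Signal",
    "BinningSchedule",
    "TrialCountMatrices",
    "StateActivityDataset",
    "make_default_schedule",
    "bin_spikes",
    "pool_mua",
    "build_activity_vector",
    "assemble_dataset",
]

logger = logging.getLogger(__name__)

#: width of every post-stimulus bin (s)
POST_BIN_WIDTH = 0.005

#: (count, width_s) blocks of the default adaptive pre-stimulus schedule,
#: ordered from the far end of the window toward stimulus onset
DEFAULT_PRE_BLOCKS = ((9, 0.050), (10, 0.020), (20, 0.005))


class Variant(str, Enum):
    """Decoder feature variants."""

    SI = "SI"
    SD_TA = "SD-TA"
    SD_TD = "SD-TD"


class Signal(str, Enum):
    """Single-unit vs pooled multi-unit activity."""

    SUA = "SUA"
    MUA = "MUA"


@dataclass(frozen=True)
class BinningSchedule:
    """Bin edges for the pre- and post-stimulus windows.

    ``pre_edges`` are negative and end at 0; ``post_edges`` start at the end
    of the artifact blank.  Bins are half-open ``[lo, hi)``.
    """

    pre_edges: np.ndarray
    post_edges: np.ndarray

    def __post_init__(self) -> None:
        for name, edges in (("pre", self.pre_edges), ("post", self.post_edges)):
            if edges.ndim != 1 or edges.size < 2:
                raise ValueError(f"{name}_edges must contain at least one bin")
            if not np.all(np.diff(edges) > 0):
                raise ValueError(f"{name}_edges must be strictly increasing")
        if self.pre_edges[-1] > 1e-12:
            raise ValueError("pre_edges must end at stimulus onset (t = 0)")
        pre_widths = np.diff(self.pre_edges)
        if np.any(np.diff(pre_widths) > 1e-12):
            raise ValueError("pre bin widths must be non-increasing toward onset")

    @property
    def t_theta(self) -> int:
        """Number of pre-stimulus bins."""
        return self.pre_edges.size - 1

    @property
    def t_r(self) -> int:
        """Number of post-stimulus bins."""
        return self.post_edges.size - 1

    @property
    def pre_span(self) -> float:
        return float(self.pre_edges[-1] - self.pre_edges[0])

    def truncate(self, t_theta: int | None = None, t_r: int | None = None
                 ) -> "BinningSchedule":
        """Keep only the ``t_theta`` pre bins closest to onset and the first
        ``t_r`` post bins (hyperparameter search over window lengths).

        ``t_theta = 0`` is expressed by passing the full schedule to a
        state-only-unaware variant (``SI``); the schedule itself always keeps
        at least one bin per window.
        """
        tt = self.t_theta if t_theta is None else t_theta
        tr = self.t_r if t_r is None else t_r
        if not 1 <= tt <= self.t_theta:
            raise ValueError(f"t_theta must be in 1..{self.t_theta}")
        if not 1 <= tr <= self.t_r:
            raise ValueError(f"t_r must be in 1..{self.t_r}")
        return BinningSchedule(
            pre_edges=self.pre_edges[-(tt + 1):],
            post_edges=self.post_edges[: tr + 1],
        )


@dataclass(frozen=True)
class TrialCountMatrices:
    """Per-trial count matrices: ``theta`` is units x T_theta (pre-stimulus),
    ``r`` is units x T_r (post-stimulus)."""

    theta: np.ndarray
    r: np.ndarray

    def __post_init__(self) -> None:
        if self.theta.shape[0] != self.r.shape[0]:
            raise ValueError("theta and r must have the same number of units")
        if np.any(self.theta < 0) or np.any(self.r < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def n_units(self) -> int:
        return self.theta.shape[0]


@dataclass(frozen=True)
class StateActivityDataset:
    """Trial x feature matrix ready for decoding, with aligned labels."""

    matrix: np.ndarray  # (M, F)
    labels: np.ndarray  # (M,), values in 1..4
    variant: Variant
    signal: Signal
    n_units: int
    t_theta: int
    t_r: int

    def __post_init__(self) -> None:
        if self.matrix.shape[0] != self.labels.shape[0]:
            raise ValueError("matrix rows and labels must align")

    @property
    def n_trials(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def make_default_schedule(
    pre_span: float = 0.75,
    post_span: float = 0.05,
    artifact_blank: float = 0.030,
) -> BinningSchedule:
    """Build the default adaptive schedule.

    The pre-stimulus window uses 9 bins of 50 ms, then 10 bins of 20 ms, then
    20 bins of 5 ms ending at onset -- 39 bins covering 0.75 s (coarse far
    from onset, fine close to it).  When ``pre_span`` exceeds 0.75 s only the
    final 0.75 s before onset are binned.  Post-stimulus bins are uniform
    5 ms, starting at ``artifact_blank`` and covering ``post_span`` (which
    must be a whole number of bins).
    """
    covered = sum(n * w for n, w in DEFAULT_PRE_BLOCKS)
    if pre_span < covered - 1e-9:
        raise ValueError(
            f"pre_span must be >= {covered} s for the default schedule"
        )
    edges = [-covered]
    for n_bins, width in DEFAULT_PRE_BLOCKS:
        for _ in range(n_bins):
            edges.append(edges[-1] + width)
    pre_edges = np.array(edges)
    pre_edges[-1] = 0.0  # kill accumulated float error at onset

    n_post = post_span / POST_BIN_WIDTH
    if abs(n_post - round(n_post)) > 1e-9 or round(n_post) < 1:
        raise ValueError("post_span must be a positive multiple of 5 ms")
    n_post = int(round(n_post))
    post_edges = artifact_blank + POST_BIN_WIDTH * np.arange(n_post + 1)
    return BinningSchedule(pre_edges=pre_edges, post_edges=post_edges)


def bin_spikes(
    trial: Trial, schedule: BinningSchedule, *, warn_out_of_span: bool = True
) -> TrialCountMatrices:
    """Count spikes of each unit in each bin of the schedule.

    Bins are half-open ``[lo, hi)``.  Spikes outside the schedule span (for
    instance inside the artifact blank, or beyond the analysis windows) are
    dropped with a logged warning, not an error; callers that truncate the
    schedule on purpose pass ``warn_out_of_span=False``.
    """
    n_units = trial.n_units
    theta = np.zeros((n_units, schedule.t_theta), dtype=int)
    r = np.zeros((n_units, schedule.t_r), dtype=int)
    dropped = 0
    for n, st in enumerate(trial.spikes):
        st = np.asarray(st)
        theta[n] = _histogram_halfopen(st, schedule.pre_edges)
        r[n] = _histogram_halfopen(st, schedule.post_edges)
        in_span = (
            ((st >= schedule.pre_edges[0]) & (st < schedule.pre_edges[-1]))
            | ((st >= schedule.post_edges[0]) & (st < schedule.post_edges[-1]))
        )
        dropped += int(st.size - in_span.sum())
    if dropped and warn_out_of_span:
        logger.warning(
            "trial %d: %d spike(s) outside the binning schedule were ignored",
            trial.index,
            dropped,
        )
    return TrialCountMatrices(theta=theta, r=r)


def _histogram_halfopen(times: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Histogram with every bin half-open [lo, hi), including the last."""
    idx = np.searchsorted(edges, times, side="right") - 1
    valid = (idx >= 0) & (idx < edges.size - 1) & (times < edges[-1])
    return np.bincount(idx[valid], minlength=edges.size - 1)


def pool_mua(matrices: TrialCountMatrices) -> TrialCountMatrices:
    """Pool all units into a single multi-unit channel (column sums)."""
    return TrialCountMatrices(
        theta=matrices.theta.sum(axis=0, keepdims=True),
        r=matrices.r.sum(axis=0, keepdims=True),
    )


def build_activity_vector(
    matrices: TrialCountMatrices,
    variant: Variant | str,
    *,
    state_only: bool = False,
) -> np.ndarray:
    """Flatten one trial's count matrices into a decoder feature vector.

    Unit-major layout: per unit, pre-stimulus features (oldest first) then
    post-stimulus counts.  ``SD-TA`` collapses each unit's pre-stimulus row
    to its mean count per bin (proportional to the time-averaged ongoing
    rate; with unequal bin widths this equals the duration-weighted mean rate
    times the mean bin width, so the arrangement of widths does not bias it).
    ``state_only`` drops the response part from the state-dependent variants
    (used by the state-only-information control).
    """
    variant = Variant(variant)
    theta = matrices.theta.astype(float)
    r = matrices.r.astype(float)
    if variant is Variant.SI:
        if state_only:
            raise ValueError("the SI variant has no state part")
        return r.reshape(-1)
    if variant is Variant.SD_TA:
        pre = theta.mean(axis=1, keepdims=True)
    elif variant is Variant.SD_TD:
        pre = theta
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown variant {variant!r}")
    if state_only:
        return pre.reshape(-1)
    return np.concatenate([pre, r], axis=1).reshape(-1)


def assemble_dataset(
    session: SpikeSession,
    schedule: BinningSchedule,
    variant: Variant | str = Variant.SD_TD,
    signal: Signal | str = Signal.SUA,
    *,
    state_only: bool = False,
) -> StateActivityDataset:
    """Bin every trial of a session and stack feature vectors row-wise.

    Rows follow trial order; labels stay aligned.  ``MUA`` pools all units
    into one channel before flattening.
    """
    variant = Variant(variant)
    signal = Signal(signal)
    # a schedule narrower than the recorded windows drops spikes by design
    covers = (
        schedule.pre_span >= session.pre_span - 1e-9
        and schedule.post_edges[-1] >= session.post_span - 1e-9
    )
    rows = []
    for trial in session.trials:
        if trial.n_units != session.n_units:
            raise ValueError(
                f"trial {trial.index} has {trial.n_units} units, "
                f"session declares {session.n_units}"
            )
        counts = bin_spikes(trial, schedule, warn_out_of_span=covers)
        if signal is Signal.MUA:
            counts = pool_mua(counts)
        rows.append(build_activity_vector(counts, variant, state_only=state_only))
    matrix = np.vstack(rows)
    n_units = 1 if signal is Signal.MUA else session.n_units
    return StateActivityDataset(
        matrix=matrix,
        labels=session.labels,
        variant=variant,
        signal=signal,
        n_units=n_units,
        t_theta=schedule.t_theta,
        t_r=0 if state_only else schedule.t_r,
    )
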