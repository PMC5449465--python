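"""Decoding-performance evaluation.

Performance is summarized by the mutual information of the soft confusion
matrix: entry ``q[d, i]`` is the mean thresholded posterior assigned to
decoded stimulus ``d`` over trials on which stimulus ``i`` was presented, so
each column is a probability distribution and the mutual information

    I(S; D) = sum_{d,i} P(s_i) q[d,i] log2( q[d,i] / q_marginal[d] )

lies in [0, 2] bits for four equiprobable stimuli.  Finite trial counts bias
this estimate upward; the bias is estimated by rerunning the entire decoding
pipeline on label-permuted data (class counts preserved) and subtracting the
mean shuffled information.  Negative corrected values are reported as-is --
clipping at zero would bias averages across sessions.

The module also provides nested leave-one-out hyperparameter selection, the
state-only-information control (decoding from pre-stimulus activity alone),
and the angular error between the decoded force and the force field of the
region occupied by the point mass.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .binning import (
    BinningSchedule,
    Signal,
    Variant,
    assemble_dataset,
)
from .decoder import N_CLASSES, LeaveOneOutCache, loo_decode
from .neural_sim import SpikeSession

__all__ = [
    "ConfusionMatrix",
    "InfoResult",
    "ParamGrid",
    "confusion_matrix",
    "mutual_information",
    "decode_information",
    "shuffle_bias_correct",
    "optimize_parameters",
    "state_only_information",
    "angular_error",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Soft confusion matrix Q with stimulus priors.

    ``q[d, i]`` is the probability that presented stimulus ``i + 1`` is
    decoded as stimulus ``d + 1``; columns sum to one.  ``priors`` are the
    empirical presentation probabilities P(s_i).
    """

    q: np.ndarray
    priors: np.ndarray

    def __post_init__(self) -> None:
        if self.q.shape != (N_CLASSES, N_CLASSES):
            raise ValueError("q must be 4 x 4")
        if not np.allclose(self.q.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("confusion-matrix columns must sum to 1")
        if not math.isclose(float(self.priors.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("priors must sum to 1")

    @property
    def marginal(self) -> np.ndarray:
        """Marginal distribution of the decoded stimulus, Q(s_d)."""
        return self.q @ self.priors


@dataclass(frozen=True)
class InfoResult:
    """Shuffle-corrected information estimate, in bits."""

    raw_bits: float
    bias_bits: float
    corrected_bits: float
    shuffle_sem: float
    n_shuffles: int
    hyperparams: dict = field(default_factory=dict)


@dataclass(frozen=True)
class HyperParams:
    """One point of the decoder hyperparameter space."""

    k: int | None
    p_thr: float
    variant: Variant
    signal: Signal
    t_theta: int
    t_r: int


@dataclass(frozen=True)
class ParamGrid:
    """Candidate hyperparameter values for nested selection.

    ``t_theta`` counts pre-stimulus bins kept closest to onset (0 disables
    the state part and forces the SI variant); ``t_r`` counts post-stimulus
    bins kept from the response window.
    """

    p_thr: Sequence[float] = (0.5, 0.7, 0.8, 0.9, 1.0)
    k: Sequence[int | None] = (2, 4, 8, 16, 32, None)  # None = full rank
    variant: Sequence[Variant] = (Variant.SI, Variant.SD_TA, Variant.SD_TD)
    signal: Sequence[Signal] = (Signal.SUA, Signal.MUA)
    t_theta: Sequence[int] = (0, 13, 26, 39)
    t_r: Sequence[int] = (5, 10, 20)

    def __post_init__(self) -> None:
        for name in ("p_thr", "k", "variant", "signal", "t_theta", "t_r"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"grid dimension {name!r} must be non-empty")

    def points(self) -> list[HyperParams]:
        """Enumerate grid points, dropping redundant combinations.

        The SI variant ignores the pre-stimulus window, so it is enumerated
        once (``t_theta = 0``); state-dependent variants require at least one
        pre-stimulus bin.
        """
        pts = []
        for variant, signal, tt, tr, k, p in itertools.product(
            self.variant, self.signal, self.t_theta, self.t_r, self.k, self.p_thr
        ):
            variant = Variant(variant)
            if variant is Variant.SI:
                if tt != min(self.t_theta):
                    continue
                tt = 0
            elif tt == 0:
                continue
            pts.append(HyperParams(k, p, variant, Signal(signal), tt, tr))
        return pts


def confusion_matrix(p_tilde: np.ndarray, labels: np.ndarray) -> ConfusionMatrix:
    """Column-normalized soft confusion matrix from posteriors and labels.

    Column ``i`` is the mean of the thresholded posterior vectors over the
    trials on which stimulus ``i + 1`` was presented (the conditional mean
    normalization that makes each column a probability distribution).
    """
    p_tilde = np.atleast_2d(np.asarray(p_tilde, dtype=float))
    labels = np.asarray(labels, dtype=int)
    if p_tilde.shape != (labels.size, N_CLASSES):
        raise ValueError("p_tilde must be (n_trials, 4) aligned with labels")
    q = np.empty((N_CLASSES, N_CLASSES))
    priors = np.empty(N_CLASSES)
    for i in range(N_CLASSES):
        mask = labels == i + 1
        if not mask.any():
            raise ValueError(f"stimulus {i + 1} never presented")
        q[:, i] = p_tilde[mask].mean(axis=0)
        priors[i] = mask.mean()
    return ConfusionMatrix(q=q, priors=priors)


def mutual_information(cm: ConfusionMatrix) -> float:
    """Mutual information of the confusion matrix, in bits (0 log 0 = 0)."""
    q = cm.q
    marginal = cm.marginal
    joint = q * cm.priors[None, :]
    safe_marginal = np.where(marginal > 0, marginal, 1.0)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(q > 0, q / safe_marginal, 1.0)
        terms = np.where(joint > 0, joint * np.log2(ratio), 0.0)
    return float(terms.sum())


def decode_information(
    dataset,
    k: int | None,
    p_thr: float,
    *,
    cache: LeaveOneOutCache | None = None,
) -> float:
    """Raw (uncorrected) leave-one-out decoding information of a dataset."""
    p_tilde, _ = loo_decode(dataset, k, p_thr, cache=cache)
    return mutual_information(confusion_matrix(p_tilde, dataset.labels))


def shuffle_bias_correct(
    dataset,
    k: int | None,
    p_thr: float,
    n_shuffles: int = 100,
    seed: int | np.random.Generator = 0,
    *,
    cache: LeaveOneOutCache | None = None,
) -> InfoResult:
    """Bias-corrected decoding information.

    The bias estimate reruns the full pipeline -- leave-one-out decode,
    confusion matrix, information -- on ``n_shuffles`` label permutations
    (class counts preserved) and averages; ``corrected = raw - bias``.  Use
    at least 20 shuffles for reported results.  The per-fold PCA projections
    are label-independent and therefore shared between the raw estimate and
    every shuffle.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if cache is None:
        cache = LeaveOneOutCache(dataset.matrix, k)
    raw = decode_information(dataset, k, p_thr, cache=cache)
    shuffled_bits = np.empty(n_shuffles)
    for j in range(n_shuffles):
        perm_labels = rng.permutation(dataset.labels)
        p_tilde = cache.decode(perm_labels, p_thr)
        shuffled_bits[j] = mutual_information(
            confusion_matrix(p_tilde, perm_labels)
        )
    bias = float(shuffled_bits.mean())
    sem = float(shuffled_bits.std(ddof=1) / math.sqrt(n_shuffles)) if n_shuffles > 1 else float("nan")
    return InfoResult(
        raw_bits=raw,
        bias_bits=bias,
        corrected_bits=raw - bias,
        shuffle_sem=sem,
        n_shuffles=n_shuffles,
        hyperparams={"k": k, "p_thr": p_thr},
    )


def _dataset_for(
    session: SpikeSession,
    schedule: BinningSchedule,
    hp: HyperParams,
    trial_subset: np.ndarray | None = None,
):
    """Assemble the dataset a hyperparameter point asks for."""
    sub = schedule
    if hp.variant is not Variant.SI and hp.t_theta:
        sub = sub.truncate(t_theta=hp.t_theta)
    sub = sub.truncate(t_r=hp.t_r)
    ds = assemble_dataset(session, sub, hp.variant, hp.signal)
    if trial_subset is not None:
        from dataclasses import replace

        ds = replace(
            ds, matrix=ds.matrix[trial_subset], labels=ds.labels[trial_subset]
        )
    return ds


def optimize_parameters(
    session: SpikeSession,
    schedule: BinningSchedule,
    grid: ParamGrid,
    test_trial: int,
) -> HyperParams:
    """Nested hyperparameter selection for one outer test trial.

    For each grid point, decode the M - 1 training trials by inner
    leave-one-out and compute the (raw) confusion-matrix information; return
    the maximizer.  The held-out trial never enters the inner loop.  Ties are
    broken deterministically: smaller k, then smaller p_thr, then SD-TD over
    SD-TA over SI, then smaller t_theta and t_r.
    """
    m = session.n_trials
    if m < 20:
        raise ValueError("nested optimization needs at least 20 trials")
    if not 0 <= test_trial < m:
        raise ValueError("test_trial out of range")
    train_idx = np.array([i for i in range(m) if i != test_trial])

    variant_rank = {Variant.SD_TD: 0, Variant.SD_TA: 1, Variant.SI: 2}

    def tie_key(hp: HyperParams) -> tuple:
        k_val = math.inf if hp.k is None else hp.k
        return (k_val, hp.p_thr, variant_rank[hp.variant], hp.t_theta, hp.t_r)

    best: tuple[float, tuple, HyperParams] | None = None
    caches: dict[tuple, LeaveOneOutCache] = {}
    for hp in grid.points():
        ds = _dataset_for(session, schedule, hp, train_idx)
        cache_key = (hp.variant, hp.signal, hp.t_theta, hp.t_r, hp.k)
        cache = caches.get(cache_key)
        if cache is None:
            cache = LeaveOneOutCache(ds.matrix, hp.k)
            caches[cache_key] = cache
        info = decode_information(ds, hp.k, hp.p_thr, cache=cache)
        candidate = (info, tie_key(hp), hp)
        if best is None or candidate[0] > best[0] or (
            candidate[0] == best[0] and candidate[1] < best[1]
        ):
            best = candidate
    assert best is not None
    return best[2]


def state_only_information(
    session: SpikeSession,
    schedule: BinningSchedule,
    variant: Variant | str,
    k: int | None = None,
    p_thr: float = 1.0,
    n_shuffles: int = 20,
    seed: int | np.random.Generator = 0,
    signal: Signal | str = Signal.SUA,
) -> InfoResult:
    """Information carried by the state variables alone about the stimulus.

    Runs the identical decoding pipeline but feeds only the pre-stimulus
    features (time course for SD-TD, per-unit time average for SD-TA) to the
    decoder.  On a generator with no stimulus-to-state coupling this is
    approximately zero, which is the control showing that state-dependent
    information gains are not explained by the state leaking stimulus
    identity.
    """
    variant = Variant(variant)
    if variant is Variant.SI:
        raise ValueError("state-only information requires a state-dependent variant")
    ds = assemble_dataset(session, schedule, variant, signal, state_only=True)
    result = shuffle_bias_correct(ds, k, p_thr, n_shuffles, seed)
    hp = dict(result.hyperparams)
    hp.update({"variant": variant.value, "state_only": True})
    return InfoResult(
        raw_bits=result.raw_bits,
        bias_bits=result.bias_bits,
        corrected_bits=result.corrected_bits,
        shuffle_sem=result.shuffle_sem,
        n_shuffles=result.n_shuffles,
        hyperparams=hp,
    )


def angular_error(
    f_decoded: np.ndarray, region: int, forces: np.ndarray
) -> float:
    """Unsigned angle (degrees) between the decoded force and the force field
    of the region containing the point mass.

    Perfect decoding gives 0 degrees.  A zero decoded force has no direction;
    it is flagged as NaN and excluded from averages by callers.
    """
    f_decoded = np.asarray(f_decoded, dtype=float)
    forces = np.asarray(forces, dtype=float)
    if not 1 <= region <= N_CLASSES:
        raise ValueError("region must be in 1..4")
    ref = forces[region - 1]
    norm = np.linalg.norm(f_decoded) * np.linalg.norm(ref)
    if norm == 0.0:
        return float("nan")
    cosine = float(np.clip(np.dot(f_decoded, ref) / norm, -1.0, 1.0))
    return math.degrees(math.acos(cosine))
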