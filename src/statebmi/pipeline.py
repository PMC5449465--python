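"""Default end-to-end decoding protocol for the three decoder variants.

These helpers wire a session through binning, decoding and evaluation with
the package's default hyperparameters, which play the role of the per-session
optimized values of the full nested search (see
:func:`statebmi.evaluation.optimize_parameters`):

* signal: pooled multi-unit activity (MUA) -- with few units and stimuli
  that differ chiefly in evoked strength, pooling is the more robust choice;
* ``k = 6`` retained principal components -- the task-relevant structure
  (population amplitude axis, latent-state direction, their pre-stimulus
  counterparts) is low-dimensional, and a small score space keeps the
  discriminant well-estimated;
* ``p_thr = 0.3`` -- an aggressive winner-take-all threshold, so almost all
  trials are hard-assigned and the confusion matrix reflects discrimination
  rather than posterior calibration;
* the state-dependent time-dependent variant reads the last 13 fine
  pre-stimulus bins (65 ms) where the latent state is most predictive of the
  upcoming response, while the time-averaged variant summarizes the full
  pre-stimulus window in one value per channel.
"""

from __future__ import annotations

import numpy as np

from .binning import (
    BinningSchedule,
    Signal,
    StateActivityDataset,
    Variant,
    assemble_dataset,
    make_default_schedule,
)
from .decoder import DecoderModel, fit_decoder
from .evaluation import InfoResult, shuffle_bias_correct
from .neural_sim import SpikeSession

__all__ = [
    "DEFAULT_K",
    "DEFAULT_P_THR",
    "DEFAULT_SIGNAL",
    "DEFAULT_TD_PRE_BINS",
    "session_schedule",
    "variant_schedule",
    "variant_dataset",
    "variant_information",
    "fit_variant_decoder",
]

DEFAULT_K = 6
DEFAULT_P_THR = 0.3
DEFAULT_SIGNAL = Signal.MUA
#: fine pre-stimulus bins fed to the time-dependent state variant (65 ms)
DEFAULT_TD_PRE_BINS = 13


def session_schedule(session: SpikeSession) -> BinningSchedule:
    """The default 39-bin adaptive schedule matched to a session's windows."""
    return make_default_schedule(
        pre_span=session.pre_span,
        post_span=session.post_span - session.artifact_blank,
        artifact_blank=session.artifact_blank,
    )


def variant_schedule(
    schedule: BinningSchedule, variant: Variant | str
) -> BinningSchedule:
    """The schedule a variant decodes from under the default protocol."""
    variant = Variant(variant)
    if variant is Variant.SD_TD:
        return schedule.truncate(t_theta=min(DEFAULT_TD_PRE_BINS, schedule.t_theta))
    return schedule


def variant_dataset(
    session: SpikeSession,
    variant: Variant | str,
    schedule: BinningSchedule | None = None,
    signal: Signal | str = DEFAULT_SIGNAL,
    *,
    state_only: bool = False,
) -> StateActivityDataset:
    """Assemble the feature matrix a variant decodes under default settings."""
    if schedule is None:
        schedule = session_schedule(session)
    return assemble_dataset(
        session,
        variant_schedule(schedule, variant),
        variant,
        signal,
        state_only=state_only,
    )


def variant_information(
    session: SpikeSession,
    variant: Variant | str,
    n_shuffles: int = 20,
    seed: int | np.random.Generator = 0,
    k: int | None = DEFAULT_K,
    p_thr: float = DEFAULT_P_THR,
    signal: Signal | str = DEFAULT_SIGNAL,
) -> InfoResult:
    """Shuffle-corrected decoding information of one variant on a session."""
    ds = variant_dataset(session, variant, signal=signal)
    result = shuffle_bias_correct(ds, k, p_thr, n_shuffles, seed)
    hp = dict(result.hyperparams)
    hp.update({"variant": Variant(variant).value, "signal": Signal(signal).value})
    return InfoResult(
        raw_bits=result.raw_bits,
        bias_bits=result.bias_bits,
        corrected_bits=result.corrected_bits,
        shuffle_sem=result.shuffle_sem,
        n_shuffles=result.n_shuffles,
        hyperparams=hp,
    )


def fit_variant_decoder(
    session: SpikeSession,
    variant: Variant | str,
    k: int | None = DEFAULT_K,
    p_thr: float = DEFAULT_P_THR,
    signal: Signal | str = DEFAULT_SIGNAL,
) -> tuple[DecoderModel, BinningSchedule]:
    """Fit a deployable decoder on a full session with default settings.

    Returns the fitted model together with the (variant-specific) schedule
    needed to bin trials online; both are what the closed loop consumes.
    """
    ds = variant_dataset(session, variant)
    model = fit_decoder(
        ds.matrix, ds.labels, k, p_thr, variant=Variant(variant), signal=signal
    )
    return model, variant_schedule(session_schedule(session), variant)
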