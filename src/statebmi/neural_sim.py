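"""Synthetic spike sessions with a latent, temporally structured cortical state.

The generator emulates anesthetized-cortex recordings in which stimulus-evoked
responses ride on top of ongoing fluctuations of network excitability.  Each
trial exposes a pre-stimulus window of ongoing activity and a post-stimulus
window of evoked activity; a shared latent excitability trace ``x(t)``
additively modulates the firing rate of every unit in both windows, so that
the recent history of ongoing activity is informative about the noise that
will corrupt the evoked response.  Spikes are drawn from an inhomogeneous
Poisson process; a stimulation-artifact blanking interval at stimulus onset
contains no spikes; evoked rates drift slowly over the session.

The latent state is an Ornstein--Uhlenbeck process mixed with a random-phase
sinusoid in a low-frequency band, standardized to zero mean and unit variance
in expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SimParams",
    "LatentState",
    "Trial",
    "SpikeSession",
    "default_templates",
    "sample_latent_state",
    "generate_trial",
    "generate_session",
    "SessionOracle",
]

#: resolution of the rate grid on which the Poisson process is sampled (s)
GRID_DT = 0.001

#: number of stimulation patterns (quadrant encoder is 4-way)
N_STIMULI = 4


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic spike-session generator.

    Attributes
    ----------
    n_units:
        Number of single units recorded in the session (real sessions carry
        10--15 sorted units).
    n_trials_per_stimulus:
        Repetitions of each of the four stimulation patterns.
    baseline_rate:
        Ongoing firing rate common to all units, spikes/s.
    evoked_templates:
        Optional array ``(n_units, 4, n_grid_post)`` of evoked rate time
        courses (spikes/s) on the ``GRID_DT`` grid over the post-stimulus
        window.  ``None`` means build tuned exponential-decay templates
        deterministically from the seed (see :func:`default_templates`).
    state_coupling:
        Gain ``g`` of the additive latent-state modulation; ``g = 0`` removes
        all state dependence.
    state_timescale:
        Decorrelation time of the Ornstein--Uhlenbeck component, s.
    state_oscillation_band:
        Frequency band (Hz) of the sinusoidal state component; delta-band by
        default.  One frequency is drawn per session (the anesthetized delta
        rhythm is quasi-regular within a session), with a random phase per
        trial.
    sine_weight:
        Fraction of latent-state variance carried by the sinusoid.
    drift_fraction:
        Fractional linear increase of evoked rate from the first to the last
        trial of the session (the recordings this emulates drifted by about
        +20.5% of the mean evoked rate).
    pre_stimulus_tuning:
        Stimulus leakage into the pre-stimulus window: units whose preferred
        stimulus is the upcoming one have their ongoing rate raised by this
        fraction of baseline.  Zero (the default) keeps ongoing activity
        statistically independent of the stimulus, which is the regime the
        state-dependent decoders are meant for; nonzero values exist to probe
        the state-only-information control.
    artifact_blank:
        Stimulation-artifact blanking interval after onset, s (the 30 ms
        stimulation train); no spikes are emitted inside ``[0, artifact_blank)``.
    pre_span, post_span:
        Durations of the pre- and post-stimulus windows, s.
    state_skew:
        Lognormal shape of the excitability marginal.  Anesthetized-cortex
        excitability is strongly skewed (occasional high-rate up-states, a
        bounded quiet floor); passing the standardized Gaussian state trace
        through a standardized lognormal with this sigma reproduces that
        while keeping zero mean and unit variance.  The floor at about
        -1 standard deviation lets the additive coupling be strong without
        driving rates negative (and hence without rectification distorting
        the state-response relationship).  0 keeps the Gaussian marginal.
    seed:
        Master seed; fully determines the session.
    """

    n_units: int = 14
    n_trials_per_stimulus: int = 100
    baseline_rate: float = 25.0
    evoked_templates: np.ndarray | None = None
    state_coupling: float = 0.3
    state_timescale: float = 0.8
    state_oscillation_band: tuple[float, float] = (1.0, 4.0)
    sine_weight: float = 0.1
    drift_fraction: float = 0.205
    pre_stimulus_tuning: float = 0.0
    artifact_blank: float = 0.030
    pre_span: float = 0.75
    post_span: float = 0.18
    state_skew: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        if self.n_trials_per_stimulus < 1:
            raise ValueError("n_trials_per_stimulus must be >= 1")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.state_timescale <= 0:
            raise ValueError("state_timescale must be > 0")
        if self.drift_fraction < 0:
            raise ValueError("drift_fraction must be >= 0")
        if not 0.0 <= self.sine_weight <= 1.0:
            raise ValueError("sine_weight must be in [0, 1]")
        lo, hi = self.state_oscillation_band
        if not 0 < lo <= hi:
            raise ValueError("state_oscillation_band must satisfy 0 < lo <= hi")
        if self.state_skew < 0:
            raise ValueError("state_skew must be >= 0")
        if not 0.0 <= self.artifact_blank < self.post_span:
            raise ValueError("artifact_blank must lie inside the post window")
        if self.pre_span <= 0 or self.post_span <= 0:
            raise ValueError("windows must have positive duration")

    @property
    def n_trials(self) -> int:
        """Total trial count M = 4 * n_trials_per_stimulus."""
        return N_STIMULI * self.n_trials_per_stimulus

    @property
    def n_grid_pre(self) -> int:
        return int(round(self.pre_span / GRID_DT))

    @property
    def n_grid_post(self) -> int:
        return int(round(self.post_span / GRID_DT))


@dataclass(frozen=True)
class LatentState:
    """One trial's excitability trace on the fine time grid.

    ``times`` spans ``[-pre_span, post_span)`` in steps of ``GRID_DT``;
    ``x`` is dimensionless with zero mean and unit variance in expectation.
    """

    times: np.ndarray
    x: np.ndarray

    def __post_init__(self) -> None:
        if self.times.shape != self.x.shape:
            raise ValueError("times and x must have matching shapes")


@dataclass(frozen=True)
class Trial:
    """A single trial: stimulus label and per-unit spike times (s, onset = 0)."""

    index: int
    stimulus: int
    spikes: tuple[np.ndarray, ...]  # one sorted array per unit

    @property
    def n_units(self) -> int:
        return len(self.spikes)


@dataclass(frozen=True)
class SpikeSession:
    """A full recording session: trials plus generator metadata."""

    trials: tuple[Trial, ...]
    n_units: int
    pre_span: float
    post_span: float
    artifact_blank: float
    seed: int
    params: SimParams | None = None

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def labels(self) -> np.ndarray:
        return np.array([t.stimulus for t in self.trials], dtype=int)


#: relative evoked strength of the four stimulation patterns (shared
#: population-amplitude axis along which excitability also acts)
STIMULUS_STRENGTHS = (0.3, 1.0, 1.7, 2.4)

#: extra gain a unit's preferred stimulus gets on top of the shared axis
PATTERN_TUNING = 0.3


def default_templates(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Build per-unit, per-stimulus evoked rate templates.

    The four stimulation patterns differ chiefly in overall evoked strength
    (``STIMULUS_STRENGTHS``), so the class signal has a large component along
    the shared population-amplitude axis -- the same axis along which
    excitability fluctuations shift responses.  This is the confound that
    makes decoding state-dependent: a weak response to a strong stimulus in a
    low-excitability trial resembles a strong response to a weak stimulus.
    Each unit additionally responds ``PATTERN_TUNING`` more strongly to its
    preferred pattern (assigned cyclically), giving every stimulus a
    pattern-specific signature as well.  The time course rises at the end of
    the artifact-blanking interval and decays with a 60 ms constant.

    Returns an array ``(n_units, 4, n_grid_post)`` in spikes/s.
    """
    t = (np.arange(params.n_grid_post) + 0.5) * GRID_DT
    course = np.where(
        t < params.artifact_blank,
        0.0,
        np.exp(-(t - params.artifact_blank) / 0.060),
    )
    amp = 60.0 * rng.lognormal(mean=0.0, sigma=0.35, size=params.n_units)
    templates = np.zeros((params.n_units, N_STIMULI, params.n_grid_post))
    for n in range(params.n_units):
        pref = _preferred_stimulus(n)
        for s in range(N_STIMULI):
            tuning = STIMULUS_STRENGTHS[s] * (
                1.0 + (PATTERN_TUNING if s == pref else 0.0)
            )
            templates[n, s] = amp[n] * tuning * course
    return templates


def _unit_scales(templates: np.ndarray) -> np.ndarray:
    """Per-unit state-coupling scales, proportional to responsiveness.

    Excitability fluctuations move each unit's rate in proportion to how
    strongly it responds at all (its peak stimulus-averaged evoked rate), so
    the state-noise direction in count space aligns with the shared
    amplitude axis of the evoked responses.
    """
    return templates.mean(axis=1).max(axis=1)


def _preferred_stimulus(unit: int) -> int:
    return unit % N_STIMULI


def _sample_state_components(
    params: SimParams,
    rng: np.random.Generator,
    ou0: float | None = None,
    t_offset: float = 0.0,
    freq: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample the two latent-state components on the trial grid.

    Returns ``(times, ou, sine)`` where ``ou`` is a unit-variance stationary
    Ornstein--Uhlenbeck trace (exact discretization) and ``sine`` is a
    unit-variance sinusoid with random phase at frequency ``freq`` (drawn
    from the oscillation band when not given; session-level callers fix one
    frequency per session, emulating the quasi-regular delta rhythm of the
    anesthetized cortex).  ``ou0`` seeds the OU initial value (closed-loop
    carryover); ``t_offset`` shifts the sinusoid argument so phase stays
    continuous in global session time.
    """
    if params.state_timescale <= 0:
        raise ValueError("state_timescale must be > 0")
    n = params.n_grid_pre + params.n_grid_post
    times = (np.arange(n) - params.n_grid_pre) * GRID_DT

    a = math.exp(-GRID_DT / params.state_timescale)
    noise_sd = math.sqrt(1.0 - a * a)
    ou = np.empty(n)
    ou[0] = rng.standard_normal() if ou0 is None else ou0
    eps = rng.standard_normal(n - 1)
    for i in range(1, n):
        ou[i] = a * ou[i - 1] + noise_sd * eps[i - 1]

    if freq is None:
        lo, hi = params.state_oscillation_band
        freq = rng.uniform(lo, hi)
    phase = rng.uniform(0.0, 2.0 * math.pi)
    sine = math.sqrt(2.0) * np.sin(2.0 * math.pi * freq * (times + t_offset) + phase)
    return times, ou, sine


def _skew_transform(z: np.ndarray, sigma: float) -> np.ndarray:
    """Map a standardized trace through a standardized lognormal.

    ``(exp(sigma * z) - m) / s`` with ``m = exp(sigma^2 / 2)`` and
    ``s = m * sqrt(exp(sigma^2) - 1)`` has zero mean and unit variance for
    standard-normal input and a floor at ``-m / s`` (about -1 for
    ``sigma = 0.8``), emulating skewed up-state/down-state excitability.
    ``sigma = 0`` is the identity.
    """
    if sigma == 0.0:
        return z
    m = math.exp(sigma * sigma / 2.0)
    s = m * math.sqrt(math.exp(sigma * sigma) - 1.0)
    return (np.exp(sigma * z) - m) / s


def _mix_state(params: SimParams, ou: np.ndarray, sine: np.ndarray) -> np.ndarray:
    w = params.sine_weight
    z = math.sqrt(1.0 - w) * ou + math.sqrt(w) * sine
    return _skew_transform(z, params.state_skew)


def sample_latent_state(
    params: SimParams,
    rng: np.random.Generator,
) -> LatentState:
    """Sample one trial's latent excitability trace.

    The underlying Gaussian trace is a stationary Ornstein--Uhlenbeck
    process (decorrelation time ``state_timescale``) mixed with a sinusoid
    whose frequency is drawn uniformly from ``state_oscillation_band`` and
    whose phase is random; the variance split is
    ``(1 - sine_weight) : sine_weight``.  The mixture is then passed through
    the skew transform (``state_skew``), leaving the marginal at zero mean
    and unit variance in expectation.
    """
    times, ou, sine = _sample_state_components(params, rng)
    return LatentState(times=times, x=_mix_state(params, ou, sine))


def _trial_rates(
    params: SimParams,
    stimulus: int,
    trial_index: int,
    state: LatentState,
    templates: np.ndarray,
    scales: np.ndarray,
    n_total_trials: int,
) -> np.ndarray:
    """Instantaneous firing rate (spikes/s) per unit on the trial grid.

    rate_n(t) = max(0, baseline + template_{n,s}(t) * drift(trial)
                       + g * x(t) * scale_n)
    with the template term present only after stimulus onset and the rate
    forced to zero inside the artifact-blanking interval.  The drift factor
    rises linearly from 1 on the first trial to ``1 + drift_fraction`` on the
    last trial of the session.
    """
    n_pre, n_post = params.n_grid_pre, params.n_grid_post
    if n_total_trials > 1:
        drift = 1.0 + params.drift_fraction * trial_index / (n_total_trials - 1)
    else:
        drift = 1.0
    rates = np.full((params.n_units, n_pre + n_post), float(params.baseline_rate))
    rates += params.state_coupling * scales[:, None] * state.x[None, :]
    rates[:, n_pre:] += templates[:, stimulus - 1, :] * drift
    if params.pre_stimulus_tuning != 0.0:
        leak = params.pre_stimulus_tuning * params.baseline_rate
        for n in range(params.n_units):
            if _preferred_stimulus(n) == stimulus - 1:
                rates[n, :n_pre] += leak
    np.clip(rates, 0.0, None, out=rates)
    # artifact blanking: no spikes while the stimulation train is delivered
    n_blank = int(round(params.artifact_blank / GRID_DT))
    rates[:, n_pre : n_pre + n_blank] = 0.0
    return rates


def _draw_spikes(
    rates: np.ndarray, times: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, ...]:
    """Inhomogeneous Poisson sampling: per-cell Poisson counts, uniform jitter."""
    spikes = []
    for unit_rates in rates:
        counts = rng.poisson(unit_rates * GRID_DT)
        idx = np.repeat(np.arange(counts.size), counts)
        if idx.size:
            st = times[idx] + rng.uniform(0.0, GRID_DT, size=idx.size)
            st.sort()
        else:
            st = np.empty(0)
        spikes.append(st)
    return tuple(spikes)


def generate_trial(
    params: SimParams,
    stimulus: int,
    trial_index: int,
    rng: np.random.Generator,
    *,
    templates: np.ndarray | None = None,
    scales: np.ndarray | None = None,
    n_total_trials: int | None = None,
    state: LatentState | None = None,
    freq: float | None = None,
) -> Trial:
    """Generate one trial's spike trains for a given stimulation pattern.

    ``templates``/``scales`` default to the seed-determined session values;
    ``state`` defaults to a freshly sampled latent trace (at oscillation
    frequency ``freq`` when given).  Spike times are relative to stimulus
    onset (negative = pre-stimulus) and never fall inside the
    artifact-blanking interval.
    """
    if stimulus not in range(1, N_STIMULI + 1):
        raise ValueError(f"stimulus must be in 1..{N_STIMULI}, got {stimulus}")
    if templates is None:
        templates = default_templates(params, np.random.default_rng(params.seed))
    if scales is None:
        scales = np.ones(params.n_units)
    if n_total_trials is None:
        n_total_trials = params.n_trials
    if state is None:
        times, ou, sine = _sample_state_components(params, rng, freq=freq)
        state = LatentState(times=times, x=_mix_state(params, ou, sine))
    rates = _trial_rates(
        params, stimulus, trial_index, state, templates, scales, n_total_trials
    )
    spikes = _draw_spikes(rates, state.times, rng)
    return Trial(index=trial_index, stimulus=stimulus, spikes=spikes)


def generate_session(params: SimParams) -> SpikeSession:
    """Generate a full session: M = 4 * n_trials_per_stimulus trials in
    randomized (seeded) stimulus order.

    The master seed spawns independent substreams -- one for session-level
    draws (templates, coupling scales, trial order) and one per trial -- so
    individual trials are reproducible and adding trials never perturbs
    earlier ones.
    """
    root = np.random.SeedSequence(params.seed)
    session_ss, trials_ss = root.spawn(2)
    srng = np.random.default_rng(session_ss)

    templates = (
        params.evoked_templates
        if params.evoked_templates is not None
        else default_templates(params, srng)
    )
    if templates.shape != (params.n_units, N_STIMULI, params.n_grid_post):
        raise ValueError(
            "evoked_templates must have shape (n_units, 4, n_grid_post) = "
            f"{(params.n_units, N_STIMULI, params.n_grid_post)}"
        )
    scales = _unit_scales(templates)
    lo, hi = params.state_oscillation_band
    session_freq = float(srng.uniform(lo, hi))

    labels = np.repeat(np.arange(1, N_STIMULI + 1), params.n_trials_per_stimulus)
    labels = srng.permutation(labels)

    trial_streams = trials_ss.spawn(params.n_trials)
    trials = []
    for m, (label, ss) in enumerate(zip(labels, trial_streams)):
        rng = np.random.default_rng(ss)
        trials.append(
            generate_trial(
                params,
                int(label),
                m,
                rng,
                templates=templates,
                scales=scales,
                n_total_trials=params.n_trials,
                freq=session_freq,
            )
        )
    return SpikeSession(
        trials=tuple(trials),
        n_units=params.n_units,
        pre_span=params.pre_span,
        post_span=params.post_span,
        artifact_blank=params.artifact_blank,
        seed=params.seed,
        params=params,
    )


class SessionOracle:
    """Stateful trial generator for the closed loop.

    Unlike :func:`generate_session`, which draws an independent latent trace
    per trial, the oracle evolves the excitability process continuously across
    consecutive queries: the OU component carries over from the end of one
    trial to the start of the next and the sinusoid stays phase-continuous in
    global time.  Evoked-rate drift advances with the query counter against
    ``expected_trials`` (default: the session size in ``params``).
    """

    def __init__(
        self,
        params: SimParams,
        seed: int | np.random.SeedSequence | None = None,
        expected_trials: int | None = None,
    ) -> None:
        self.params = params
        ss = (
            seed
            if isinstance(seed, np.random.SeedSequence)
            else np.random.SeedSequence(params.seed if seed is None else seed)
        )
        session_ss, stream_ss = ss.spawn(2)
        srng = np.random.default_rng(session_ss)
        self.templates = (
            params.evoked_templates
            if params.evoked_templates is not None
            else default_templates(params, srng)
        )
        self.scales = _unit_scales(self.templates)
        lo, hi = params.state_oscillation_band
        self.session_freq = float(srng.uniform(lo, hi))
        self.rng = np.random.default_rng(stream_ss)
        self.expected_trials = expected_trials or params.n_trials
        self._trial_count = 0
        self._ou_carry: float | None = None
        self._global_time = 0.0

    def emit_trial(self, stimulus: int) -> Trial:
        """Generate the next trial in response to a stimulation pattern."""
        params = self.params
        times, ou, sine = _sample_state_components(
            params, self.rng, ou0=self._ou_carry, t_offset=self._global_time,
            freq=self.session_freq,
        )
        state = LatentState(times=times, x=_mix_state(params, ou, sine))
        trial_index = min(self._trial_count, self.expected_trials - 1)
        rates = _trial_rates(
            params,
            stimulus,
            trial_index,
            state,
            self.templates,
            self.scales,
            self.expected_trials,
        )
        spikes = _draw_spikes(rates, state.times, self.rng)
        self._ou_carry = float(ou[-1])
        self._global_time += params.pre_span + params.post_span
        self._trial_count += 1
        return Trial(index=trial_index, stimulus=stimulus, spikes=spikes)


def with_seed(params: SimParams, seed: int) -> SimParams:
    """Return a copy of ``params`` with a different master seed."""
    return replace(params, seed=seed)
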