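"""Closed-loop bidirectional BMI simulation.

A point mass moves in a viscous medium on a square workspace divided into
four quadrant sensory regions.  Each control step, an encoder maps the
current position to the stimulation pattern of its region; the synthetic
neural oracle emits a trial (ongoing activity followed by the evoked
response, with the latent excitability state evolving continuously across
steps); the decoder turns the trial into a thresholded posterior; the
posterior-weighted sum of the four force fields (fixed vectors at the
quadrant centroids, pointing at the central target) is applied to the mass,
which is advanced by the exact exponential solution of

    m dv/dt = F - b v.

A trajectory converges when the mass enters the target disc (the crossing is
detected on a sub-sampled path within each step, so a step that sweeps
through the target counts); otherwise it truncates at ``max_steps``.  The
trajectory-metric suite covers convergence rate, steps to target, closest
approach to a point target, the force component directed at the target, and
the within-trajectory variance of per-step displacements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .binning import BinningSchedule, Signal, bin_spikes, build_activity_vector, pool_mua
from .decoder import DecoderModel, apply_wta, decode_force, predict_posteriors
from .evaluation import angular_error
from .neural_sim import Trial

__all__ = [
    "Workspace",
    "Dynamics",
    "PointMassState",
    "Trajectory",
    "TrajectoryMetrics",
    "ClosedLoopDecoder",
    "encode_position",
    "step_dynamics",
    "run_trajectory",
    "run_session_protocol",
    "closest_point_distance",
    "directed_force",
    "within_trajectory_variance",
]

#: default start positions (cm): four on-axis, four diagonal, all 14-14.1 cm out
DEFAULT_STARTS = (
    (14.0, 0.0),
    (0.0, 14.0),
    (-14.0, 0.0),
    (0.0, -14.0),
    (10.0, 10.0),
    (-10.0, 10.0),
    (-10.0, -10.0),
    (10.0, -10.0),
)


@dataclass(frozen=True)
class Workspace:
    """Square workspace with four quadrant regions and their force fields.

    Regions are numbered counterclockwise from the upper-right quadrant:
    1 = (x >= 0, y >= 0), 2 = (x < 0, y >= 0), 3 = (x < 0, y < 0),
    4 = (x >= 0, y < 0); the half-open convention puts axis points in the
    region with the lower index, and the origin in region 1.  Force field
    ``d`` sits at the centroid of region ``d`` and points at the origin with
    magnitude ``f_mag`` (newtons).
    """

    side: float = 36.0
    f_mag: float = 0.008
    r_target: float = 1.0
    starts: tuple[tuple[float, float], ...] = DEFAULT_STARTS

    def __post_init__(self) -> None:
        if self.side <= 0:
            raise ValueError("side must be > 0")
        if self.f_mag <= 0:
            raise ValueError("f_mag must be > 0")
        if self.r_target < 0:
            raise ValueError("r_target must be >= 0")
        half = self.side / 2
        for x, y in self.starts:
            if abs(x) > half or abs(y) > half:
                raise ValueError(f"start ({x}, {y}) outside the workspace")

    @property
    def centroids(self) -> np.ndarray:
        """Quadrant centroids (cm), region order 1..4."""
        q = self.side / 4
        return np.array([[q, q], [-q, q], [-q, -q], [q, -q]])

    @property
    def forces(self) -> np.ndarray:
        """Force vectors F_1..F_4 (N), each pointing centroid -> origin."""
        c = self.centroids
        return -self.f_mag * c / np.linalg.norm(c, axis=1, keepdims=True)


@dataclass(frozen=True)
class Dynamics:
    """Point-mass-in-viscous-medium constants.

    Defaults put the system in an overdamped regime: the velocity relaxation
    time m/b = 50 ms is much shorter than a control step, so each step moves
    the mass about f_mag/b * dt = 0.5 cm at terminal velocity.  The farthest
    start (~14 cm) then needs on the order of 30-40 perfectly decoded steps,
    comfortably below the 100-step cap, while imperfect decoders leave a
    measurable signature in every trajectory metric.
    """

    mass: float = 0.02  # kg
    viscosity: float = 0.4  # N s / m
    dt: float = 0.25  # s per control step

    def __post_init__(self) -> None:
        if min(self.mass, self.viscosity, self.dt) <= 0:
            raise ValueError("mass, viscosity and dt must all be > 0")


@dataclass(frozen=True)
class PointMassState:
    """Kinematic state: position (cm), velocity (cm/s), step index."""

    position: np.ndarray
    velocity: np.ndarray
    step: int = 0

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.position)) and np.all(np.isfinite(self.velocity))):
            raise ValueError("state must be finite")


@dataclass
class Trajectory:
    """One closed-loop run: states, per-step decoded forces and posteriors."""

    states: list[PointMassState]
    forces: list[np.ndarray]
    posteriors: list[np.ndarray]
    stimuli: list[int]
    converged: bool
    start_index: int | None = None

    @property
    def n_steps(self) -> int:
        return len(self.forces)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.states])


@dataclass(frozen=True)
class TrajectoryMetrics:
    """Aggregate metrics over a session's trajectories."""

    convergence_rate: float  # percent
    mean_steps: float  # converging trajectories only; NaN if none
    mean_closest_distance_mm: float
    mean_f_dir: float  # newtons, positive = toward target
    mean_wtv: float  # averaged over start positions
    mean_angular_error_deg: float
    n_trajectories: int
    per_start_wtv: tuple[float, ...] = ()
    mean_trajectories: tuple[np.ndarray, ...] = field(default=(), repr=False)
    displacement_covariances: tuple[np.ndarray, ...] = field(default=(), repr=False)


def _region_of(position: np.ndarray) -> int:
    x, y = position
    if x >= 0:
        return 1 if y >= 0 else 4
    return 2 if y >= 0 else 3


def encode_position(position: np.ndarray, workspace: Workspace) -> int:
    """Map a position to the stimulation pattern of its quadrant region."""
    x, y = position
    half = workspace.side / 2
    if abs(x) > half + 1e-9 or abs(y) > half + 1e-9:
        raise ValueError(f"position {position} outside the workspace")
    return _region_of(position)


def step_dynamics(
    state: PointMassState,
    force: np.ndarray,
    dynamics: Dynamics,
    dt: float | None = None,
) -> PointMassState:
    """Advance the point mass by one step using the exact exponential update.

    With constant force over the step, m dv/dt = F - b v integrates to
    v(t) = v_inf + (v_0 - v_inf) exp(-b t / m) with v_inf = F / b, and the
    position integral follows in closed form -- no integration error
    accumulates regardless of step size.  Positions/velocities are in cm and
    cm/s; force in newtons.
    """
    force = np.asarray(force, dtype=float)
    if not np.all(np.isfinite(force)):
        raise ValueError("force must be finite")
    dt = dynamics.dt if dt is None else dt
    b, m = dynamics.viscosity, dynamics.mass
    v0 = state.velocity / 100.0  # cm/s -> m/s
    x0 = state.position / 100.0
    v_inf = force / b
    decay = math.exp(-b * dt / m)
    v1 = v_inf + (v0 - v_inf) * decay
    x1 = x0 + v_inf * dt + (v0 - v_inf) * (m / b) * (1.0 - decay)
    return PointMassState(
        position=x1 * 100.0, velocity=v1 * 100.0, step=state.step + 1
    )


def _clamp_to_workspace(
    state: PointMassState, workspace: Workspace
) -> PointMassState:
    """Clamp position to the walls, zeroing the inward velocity component."""
    half = workspace.side / 2
    pos = state.position.copy()
    vel = state.velocity.copy()
    changed = False
    for axis in range(2):
        if pos[axis] > half:
            pos[axis], changed = half, True
            vel[axis] = min(vel[axis], 0.0)
        elif pos[axis] < -half:
            pos[axis], changed = -half, True
            vel[axis] = max(vel[axis], 0.0)
    if not changed:
        return state
    return PointMassState(position=pos, velocity=vel, step=state.step)


class ClosedLoopDecoder:
    """Bundle of a fitted decoder and the binning needed to apply it online.

    Turns a raw trial emitted by the neural oracle into a thresholded
    posterior over the four stimulation patterns.
    """

    def __init__(self, model: DecoderModel, schedule: BinningSchedule):
        if model.variant is None or model.signal is None:
            raise ValueError("model must carry its variant and signal tags")
        self.model = model
        self.schedule = schedule

    def decode(self, trial: Trial) -> np.ndarray:
        counts = bin_spikes(trial, self.schedule, warn_out_of_span=False)
        if self.model.signal is Signal.MUA:
            counts = pool_mua(counts)
        features = build_activity_vector(counts, self.model.variant)
        raw = predict_posteriors(self.model, features)
        return apply_wta(raw, self.model.p_thr)


#: sub-sampling resolution of the within-step path for target-entry detection
_SUBSTEPS = 20


def _enters_target(
    state: PointMassState,
    next_state: PointMassState,
    force: np.ndarray,
    workspace: Workspace,
    dynamics: Dynamics,
) -> bool:
    """Did the continuous within-step path dip inside the target disc?"""
    r = workspace.r_target
    if np.linalg.norm(next_state.position) <= r:
        return True
    if r == 0.0:
        return False
    for j in range(1, _SUBSTEPS):
        partial = step_dynamics(state, force, dynamics, dt=dynamics.dt * j / _SUBSTEPS)
        if np.linalg.norm(partial.position) <= r:
            return True
    return False


def run_trajectory(
    start: tuple[float, float] | np.ndarray,
    workspace: Workspace,
    decoder,
    oracle,
    dynamics: Dynamics | None = None,
    max_steps: int = 100,
    start_index: int | None = None,
) -> Trajectory:
    """Run the closed loop from one start position.

    Each step: encode the position, query the oracle for a trial, decode it,
    convert the posterior to a force, advance the dynamics.  Stops on target
    entry or after ``max_steps`` (non-converging trajectories always carry
    exactly ``max_steps`` steps).  ``decoder`` needs a
    ``decode(trial) -> (4,)`` method and ``oracle`` an
    ``emit_trial(stimulus) -> Trial`` method; determinism follows from
    theirs.
    """
    dynamics = dynamics or Dynamics()
    state = PointMassState(
        position=np.asarray(start, dtype=float), velocity=np.zeros(2), step=0
    )
    traj = Trajectory(
        states=[state],
        forces=[],
        posteriors=[],
        stimuli=[],
        converged=False,
        start_index=start_index,
    )
    if np.linalg.norm(state.position) <= workspace.r_target:
        traj.converged = True
        return traj
    forces = workspace.forces
    for _ in range(max_steps):
        stimulus = encode_position(state.position, workspace)
        trial = oracle.emit_trial(stimulus)
        p_tilde = decoder.decode(trial)
        force = decode_force(p_tilde, forces)
        next_state = _clamp_to_workspace(
            step_dynamics(state, force, dynamics), workspace
        )
        traj.stimuli.append(stimulus)
        traj.posteriors.append(p_tilde)
        traj.forces.append(force)
        traj.states.append(next_state)
        if _enters_target(state, next_state, force, workspace, dynamics):
            traj.converged = True
            break
        state = next_state
    return traj


def closest_point_distance(
    trajectory: Trajectory, target: np.ndarray | None = None
) -> float:
    """Minimum distance (mm) of the recorded positions from the target point."""
    positions = trajectory.positions
    if positions.size == 0:
        raise ValueError("trajectory has no states")
    target = np.zeros(2) if target is None else np.asarray(target, dtype=float)
    d_cm = np.linalg.norm(positions - target[None, :], axis=1).min()
    return float(d_cm * 10.0)


def directed_force(
    f_decoded: np.ndarray,
    position: np.ndarray,
    target: np.ndarray | None = None,
) -> float:
    """Signed component of the decoded force toward the target (newtons).

    Positive values push the mass toward the target.  Undefined at the
    target itself (no direction); returns NaN there.
    """
    target = np.zeros(2) if target is None else np.asarray(target, dtype=float)
    to_target = target - np.asarray(position, dtype=float)
    dist = np.linalg.norm(to_target)
    if dist == 0.0:
        return float("nan")
    return float(np.dot(np.asarray(f_decoded, dtype=float), to_target / dist))


def within_trajectory_variance(trajectories: list[Trajectory]) -> float:
    """Dispersion of per-step displacements across repeats from one start.

    Displacement vectors of all trajectories in the group are pooled;
    ``C_x`` and ``C_y`` are the variances of their x and y components and
    wtv = sqrt(C_x^2 + C_y^2).  Identical trajectories give 0; a constant
    drift added to every displacement leaves it unchanged.
    """
    if len(trajectories) < 2:
        raise ValueError("need at least 2 trajectories")
    disps = []
    for traj in trajectories:
        pos = traj.positions
        if pos.shape[0] < 2:
            raise ValueError("each trajectory needs at least 2 states")
        disps.append(np.diff(pos, axis=0))
    pooled = np.concatenate(disps, axis=0)
    c_x, c_y = pooled.var(axis=0, ddof=1)
    return float(math.hypot(c_x, c_y))


def _mean_trajectory(trajectories: list[Trajectory]) -> np.ndarray:
    """Pointwise mean path over repeats (NaN-mean where lengths differ)."""
    longest = max(t.positions.shape[0] for t in trajectories)
    stack = np.full((len(trajectories), longest, 2), np.nan)
    for i, t in enumerate(trajectories):
        pos = t.positions
        stack[i, : pos.shape[0]] = pos
    return np.nanmean(stack, axis=0)


def run_session_protocol(
    workspace: Workspace,
    decoder,
    oracle,
    dynamics: Dynamics | None = None,
    reps_per_start: int = 100,
    max_steps: int = 100,
) -> tuple[list[Trajectory], TrajectoryMetrics]:
    """Full session protocol: ``reps_per_start`` runs from each start.

    The oracle's latent state keeps evolving across trajectories, as in a
    continuous recording session.  Returns all trajectories plus aggregate
    metrics (and per-start mean paths / displacement covariances).
    """
    dynamics = dynamics or Dynamics()
    all_trajs: list[Trajectory] = []
    per_start: list[list[Trajectory]] = [[] for _ in workspace.starts]
    for rep in range(reps_per_start):
        for s_idx, start in enumerate(workspace.starts):
            traj = run_trajectory(
                start, workspace, decoder, oracle, dynamics, max_steps, s_idx
            )
            all_trajs.append(traj)
            per_start[s_idx].append(traj)
    return all_trajs, compute_metrics(all_trajs, per_start)


def compute_metrics(
    trajectories: list[Trajectory],
    per_start: list[list[Trajectory]] | None = None,
) -> TrajectoryMetrics:
    """Aggregate the trajectory-metric suite over a list of runs."""
    if not trajectories:
        raise ValueError("no trajectories")
    if per_start is None:
        groups: dict[int | None, list[Trajectory]] = {}
        for t in trajectories:
            groups.setdefault(t.start_index, []).append(t)
        per_start = list(groups.values())

    n = len(trajectories)
    converged = [t for t in trajectories if t.converged]
    rate = 100.0 * len(converged) / n
    mean_steps = (
        float(np.mean([t.n_steps for t in converged])) if converged else float("nan")
    )
    closest = float(np.mean([closest_point_distance(t) for t in trajectories]))

    f_dirs: list[float] = []
    ang_errs: list[float] = []
    for t in trajectories:
        positions = t.positions
        for i, force in enumerate(t.forces):
            fd = directed_force(force, positions[i])
            if not math.isnan(fd):
                f_dirs.append(fd)
            # angular error against the force field of the occupied region
            ae = angular_error(force, _region_of(positions[i]), _unit_forces())
            if not math.isnan(ae):
                ang_errs.append(ae)

    wtvs = [
        within_trajectory_variance(group)
        for group in per_start
        if len(group) >= 2 and all(g.positions.shape[0] >= 2 for g in group)
    ]
    mean_paths = tuple(
        _mean_trajectory(group) for group in per_start if group
    )
    disp_covs = tuple(
        np.cov(np.concatenate([np.diff(g.positions, axis=0) for g in group]).T)
        for group in per_start
        if group and sum(g.positions.shape[0] - 1 for g in group) >= 2
    )
    return TrajectoryMetrics(
        convergence_rate=rate,
        mean_steps=mean_steps,
        mean_closest_distance_mm=closest,
        mean_f_dir=float(np.mean(f_dirs)) if f_dirs else float("nan"),
        mean_wtv=float(np.mean(wtvs)) if wtvs else float("nan"),
        mean_angular_error_deg=float(np.mean(ang_errs)) if ang_errs else float("nan"),
        n_trajectories=n,
        per_start_wtv=tuple(wtvs),
        mean_trajectories=mean_paths,
        displacement_covariances=disp_covs,
    )


def _unit_forces() -> np.ndarray:
    """Direction-only force set for angular comparisons (magnitude-free)."""
    q = 1.0
    c = np.array([[q, q], [-q, q], [-q, -q], [q, -q]])
    return -c / np.linalg.norm(c, axis=1, keepdims=True)
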