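"""Synthetic dyad and fish-vs-animation generators.

Two coupled semi-Markov agents alternate aggressive displays (flaring) with
exponentially distributed state dwell times.  Coupling is implemented as
hazard-rate modulation of flare initiation — an agent's probability of
starting a flare is suppressed by (1 - coupling) while its opponent flares
and transiently boosted at the opponent's flare offsets — so marginal dwell
times stay exponential.  A geometric renderer maps ground-truth states to
pose keypoints so the full feature/classification pipeline can be tested
end to end without recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DEFAULT_FRAME_RATE, FeatureSeries, Ethogram, subseed

ORIENTATION_STATES = ("facing", "turning", "lateral", "turning_away")

# band centers used to emit an orientation angle for each discrete state
_ORIENT_CENTERS_DEG = np.array([22.5, 67.5, 112.5, 157.5])
_ORIENT_JITTER_DEG = 15.0

# operculum opening (degrees at the nose) per flare class, used by the
# renderer; classification thresholds sit halfway between the levels
OPERCULUM_ANGLE_BY_CLASS = (30.0, 60.0, 90.0)
OPERCULUM_PARTIAL_THRESH = 45.0
OPERCULUM_FULL_THRESH = 75.0

KEYPOINT_NAMES = ("nose", "left_operculum", "right_operculum",
                  "spine1", "spine2", "spine3", "tail")


@dataclass
class DyadSimConfig:
    """Configuration of a two-agent display simulation."""

    frame_rate: float = DEFAULT_FRAME_RATE
    duration: float = 600.0                       # s
    dwell_means: tuple = (2.0, 1.0, 2.0, 1.5)     # s, per orientation state
    flare_bout_mean: float = 1.1                  # s, mean flare duration
    flare_rate: float = 0.25                      # flare initiations / s
    turn_taking_coupling: float = 0.0             # 0 = independent, 1 = alternation
    offset_boost_window: float = 0.5              # s after opponent flare offset
    engagement_tau: float = math.inf              # s; inf = stationary
    elevation_gain: float = 1.0                   # cm added to elevation while flaring
    lateral_bias: float = 0.0                     # hazard boost while opponent lateral
    full_flare_prob: float = 0.6                  # P(bout is full rather than partial)
    px_per_cm: float = 20.0
    seed: int = 0

    def __post_init__(self):
        if self.duration <= 0 or self.frame_rate <= 0:
            raise ValueError("duration and frame_rate must be positive")
        if any(m <= 0 for m in self.dwell_means):
            raise ValueError("dwell_means must be positive")
        if not 0.0 <= self.turn_taking_coupling <= 1.0:
            raise ValueError("turn_taking_coupling must be in [0, 1]")
        if self.flare_bout_mean <= 0 or self.flare_rate <= 0:
            raise ValueError("flare_bout_mean and flare_rate must be positive")
        if self.engagement_tau <= 0:
            raise ValueError("engagement_tau must be positive (use inf for stationary)")

    @property
    def n_orientation_states(self) -> int:
        return len(self.dwell_means)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


@dataclass
class AnimationSimConfig:
    """Configuration of a single fish responding to a repeating stimulus loop."""

    loop_length: float = 37.0      # s
    n_loops: int = 16
    lock_strength: float = 0.0     # 0 = homogeneous Bernoulli, 1 = deterministic
    base_flare_rate: float = 0.2   # per-frame flare probability at lock 0
    frame_rate: float = DEFAULT_FRAME_RATE
    template_window: tuple = (0.35, 0.65)   # loop fraction where the template flares
    seed: int = 0

    def __post_init__(self):
        if self.n_loops < 2:
            raise ValueError("n_loops must be >= 2")
        if not 0.0 <= self.lock_strength <= 1.0:
            raise ValueError("lock_strength must be in [0, 1]")
        if not 0.0 < self.base_flare_rate < 1.0:
            raise ValueError("base_flare_rate must be in (0, 1)")
        if self.loop_length <= 0 or self.frame_rate <= 0:
            raise ValueError("loop_length and frame_rate must be positive")


@dataclass
class AgentTrace:
    """Ground truth and derived observables for one simulated agent."""

    flare_class: np.ndarray          # int8 per frame: 0/1/2
    orientation_state: np.ndarray    # int8 per frame: 0..3
    features: FeatureSeries
    keypoints: pd.DataFrame | None = None

    @property
    def flare_binary(self) -> np.ndarray:
        return (self.flare_class != 0).astype(np.int8)

    @property
    def ethogram(self) -> Ethogram:
        return Ethogram(self.flare_class, self.features.frame_rate,
                        provenance="simulated")

    @property
    def state8(self) -> np.ndarray:
        """Per-frame 8-state id: 4 * flaring + orientation category."""
        return (4 * (self.flare_class != 0) + self.orientation_state).astype(np.int8)


@dataclass
class SimulatedTrial:
    agents: list
    config: object
    ground_truth: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.agents[0].flare_class)


def _orientation_chain(n_frames, dwell_means, fps, rng):
    """Semi-Markov orientation sequence with exponential dwells.

    Jumps move to an adjacent band (orientation is a continuous angle, so
    the fish passes through intermediate bands), uniformly between the two
    neighbors where both exist.
    """
    n_states = len(dwell_means)
    seq = np.empty(n_frames, dtype=np.int8)
    t = 0
    state = int(rng.integers(n_states))
    while t < n_frames:
        dwell = max(1, int(round(rng.exponential(dwell_means[state]) * fps)))
        seq[t:t + dwell] = state
        t += dwell
        if state == 0:
            state = 1
        elif state == n_states - 1:
            state = n_states - 2
        else:
            state += 1 if rng.random() < 0.5 else -1
    return seq


def _ou_noise(n, rng, sd=6.0, beta=0.1, clip=14.0):
    """Temporally smooth mean-zero jitter (Ornstein-Uhlenbeck walk)."""
    sigma = sd * math.sqrt(max(2 * beta - beta * beta, 1e-9))
    x = np.empty(n)
    v = 0.0
    eps = rng.normal(0.0, sigma, size=n)
    for i in range(n):
        v += -beta * v + eps[i]
        x[i] = v
    return np.clip(x, -clip, clip)


def _emit_features(flare_class, orientation_state, cfg, rng):
    """Map ground-truth states to continuous observable channels.

    Channels vary smoothly in time (band-center orientation with OU jitter
    and a short rolling mean across state changes) so that rendered
    keypoints move continuously and uncorrupted tables pass the cleaning
    rules unchanged.
    """
    n = len(flare_class)
    fps = cfg.frame_rate
    raw = (_ORIENT_CENTERS_DEG[orientation_state]
           + _ou_noise(n, rng, sd=6.0, clip=_ORIENT_JITTER_DEG - 1.0))
    orient = pd.Series(raw).rolling(5, center=True, min_periods=1).mean().to_numpy()
    opang = (np.take(OPERCULUM_ANGLE_BY_CLASS, flare_class)
             + rng.normal(0.0, 2.0, size=n))
    flare = (flare_class != 0).astype(float)
    # elevation tracks flaring through a short leaky integrator plus noise
    elev = np.empty(n)
    level = 0.0
    alpha = 1.0 / (0.5 * fps)    # ~0.5 s time constant
    for i in range(n):
        level += alpha * (flare[i] - level)
        elev[i] = level
    elevation = 5.0 + cfg.elevation_gain * elev + rng.normal(0.0, 0.05, size=n)
    # slow random-walk position inside a 12 x 12 cm arena
    steps = rng.normal(0.0, 0.02, size=(n, 2))
    pos = np.clip(np.cumsum(steps, axis=0) + 6.0, 1.0, 11.0)
    speed = np.zeros(n)
    speed[1:] = np.linalg.norm(np.diff(pos, axis=0), axis=1) * fps
    heading = orient    # stimulus normal along +x; fish stays on one side
    data = pd.DataFrame({
        "orientation": orient,
        "speed": speed,
        "operculum_angle": opang,
        "elevation": elevation,
        "centroid_x": pos[:, 0],
        "centroid_y": pos[:, 1],
        "heading": heading,
    })
    units = {"orientation": "deg", "speed": "cm/s", "operculum_angle": "deg",
             "elevation": "cm", "centroid_x": "cm", "centroid_y": "cm",
             "heading": "deg"}
    return FeatureSeries(data=data, frame_rate=fps, units=units)


def simulate_dyad(config: DyadSimConfig) -> SimulatedTrial:
    """Simulate two coupled agents taking turns at flaring.

    Flare initiation is a per-frame hazard ``flare_rate / fps`` scaled by
    ``exp(-t / engagement_tau)`` and modulated by the opponent: while the
    opponent flares the hazard is multiplied by ``(1 - coupling)``; within
    ``offset_boost_window`` seconds of the opponent's flare offset it is
    multiplied by ``(1 + 4 * coupling)``; while the opponent holds a lateral
    orientation it is multiplied by ``(1 + lateral_bias)``.  Bout durations
    are exponential with mean ``flare_bout_mean``.
    """
    cfg = config
    fps = cfg.frame_rate
    n = cfg.n_frames
    streams = [np.random.default_rng(subseed(cfg.seed, a)) for a in (0, 1)]

    orientation = [_orientation_chain(n, cfg.dwell_means, fps, streams[a])
                   for a in (0, 1)]
    flare_class = [np.zeros(n, dtype=np.int8) for _ in (0, 1)]

    base_hazard = cfg.flare_rate / fps
    end_hazard = min(1.0, 1.0 / (cfg.flare_bout_mean * fps))
    boost_frames = int(round(cfg.offset_boost_window * fps))
    c = cfg.turn_taking_coupling

    flaring = [False, False]
    bout_cls = [1, 1]
    offset_at = [-10 * boost_frames, -10 * boost_frames]
    LATERAL = 2

    decay = (np.ones(n) if math.isinf(cfg.engagement_tau)
             else np.exp(-np.arange(n) / (cfg.engagement_tau * fps)))
    u = [streams[a].random(size=(n, 2)) for a in (0, 1)]

    for t in range(n):
        for a in (0, 1):
            b = 1 - a
            if flaring[a]:
                flare_class[a][t] = bout_cls[a]
                if u[a][t, 0] < end_hazard:
                    flaring[a] = False
                    offset_at[a] = t
            else:
                h = base_hazard * decay[t]
                if flaring[b]:
                    h *= (1.0 - c)
                elif t - offset_at[b] <= boost_frames:
                    h *= (1.0 + 4.0 * c)
                if orientation[b][t] == LATERAL:
                    h *= (1.0 + cfg.lateral_bias)
                if u[a][t, 0] < min(h, 1.0):
                    flaring[a] = True
                    bout_cls[a] = 2 if u[a][t, 1] < cfg.full_flare_prob else 1
                    flare_class[a][t] = bout_cls[a]

    agents = []
    for a in (0, 1):
        feat_rng = np.random.default_rng(subseed(cfg.seed, a, 1))
        feats = _emit_features(flare_class[a], orientation[a], cfg, feat_rng)
        agents.append(AgentTrace(flare_class=flare_class[a],
                                 orientation_state=orientation[a],
                                 features=feats))
    truth = {"coupling": c, "engagement_tau": cfg.engagement_tau,
             "flare_bout_mean": cfg.flare_bout_mean}
    return SimulatedTrial(agents=agents, config=cfg, ground_truth=truth)


def simulate_animation_response(config: AnimationSimConfig) -> SimulatedTrial:
    """Simulate one fish flaring at a repeating stimulus loop.

    The per-frame flare probability interpolates between a homogeneous
    Bernoulli(base_flare_rate) and a deterministic within-loop template:
    ``p(t) = (1 - lock) * base + lock * template(phase)`` where the template
    is 1 on a fixed contiguous window covering 30% of the loop.
    """
    cfg = config
    fps = cfg.frame_rate
    T = int(round(cfg.loop_length * fps))
    n = cfg.n_loops * T
    rng = np.random.default_rng(cfg.seed)

    phase = np.arange(n) % T
    lo = int(cfg.template_window[0] * T)
    hi = int(cfg.template_window[1] * T)
    template = ((phase >= lo) & (phase < hi)).astype(float)
    p = (1.0 - cfg.lock_strength) * cfg.base_flare_rate + cfg.lock_strength * template
    flare = (rng.random(n) < p).astype(np.int8)

    flare_class = (2 * flare).astype(np.int8)
    orientation = np.zeros(n, dtype=np.int8)
    dummy = DyadSimConfig(frame_rate=fps, duration=n / fps, seed=cfg.seed)
    feats = _emit_features(flare_class, orientation, dummy,
                           np.random.default_rng(subseed(cfg.seed, 99)))
    agent = AgentTrace(flare_class=flare_class, orientation_state=orientation,
                       features=feats)
    truth = {"lock_strength": cfg.lock_strength,
             "base_flare_rate": cfg.base_flare_rate,
             "template": (lo, hi), "frames_per_loop": T}
    return SimulatedTrial(agents=[agent], config=cfg, ground_truth=truth)


def render_keypoints(agent: AgentTrace, px_per_cm: float = 20.0,
                     corruption_rate: float = 0.0,
                     jump_px: float = 20.0,
                     seed: int = 0) -> pd.DataFrame:
    """Render an agent's states to a wide pose-tracker keypoint table.

    The fish is drawn as a rigid stick figure: nose, three midline points
    and tail along the body axis, plus two operculum tips placed behind the
    nose so the angle they subtend at the nose equals the class-specific
    opening (closed < partial < full).  Confidence is 1.0 everywhere;
    ``corruption_rate > 0`` additionally injects i.i.d. low-confidence
    samples and isolated ``jump_px`` displacements for testing cleaning.
    """
    feats = agent.features
    n = feats.n_frames
    cx = feats.channel("centroid_x") * px_per_cm
    cy = feats.channel("centroid_y") * px_per_cm
    heading = np.deg2rad(feats.channel("heading"))
    opang = np.deg2rad(np.take(OPERCULUM_ANGLE_BY_CLASS, agent.flare_class))

    L = 4.0 * px_per_cm            # body length, px
    ux, uy = np.cos(heading), np.sin(heading)

    def along(dist):
        return cx + dist * ux, cy + dist * uy

    pts = {}
    pts["nose"] = along(L / 2)
    pts["spine1"] = along(L / 4)
    pts["spine2"] = along(0.0)
    pts["spine3"] = along(-L / 4)
    pts["tail"] = along(-L / 2)
    # operculum tips: 1 cm behind the nose, split symmetrically about the axis
    d = 1.0 * px_per_cm
    back = heading + np.pi
    for name, sgn in (("left_operculum", 1.0), ("right_operculum", -1.0)):
        ang = back + sgn * opang / 2.0
        pts[name] = (pts["nose"][0] + d * np.cos(ang),
                     pts["nose"][1] + d * np.sin(ang))

    cols = {}
    for name in KEYPOINT_NAMES:
        x, y = pts[name]
        cols[f"{name}_x"] = np.asarray(x, dtype=float)
        cols[f"{name}_y"] = np.asarray(y, dtype=float)
        cols[f"{name}_likelihood"] = np.ones(n)
    table = pd.DataFrame(cols)

    if corruption_rate > 0.0:
        rng = np.random.default_rng(seed)
        for name in KEYPOINT_NAMES:
            drop = rng.random(n) < corruption_rate
            table.loc[drop, f"{name}_likelihood"] = 0.3
            table.loc[drop, f"{name}_x"] += rng.normal(0, 30, size=int(drop.sum()))
            # isolated single-frame jumps with intact confidence
            n_jumps = rng.binomial(n, corruption_rate / 2.0)
            at = rng.choice(n, size=min(n_jumps, n), replace=False)
            table.loc[at, f"{name}_y"] += jump_px
    return table


def classify_operculum_angle(angle_deg: np.ndarray) -> np.ndarray:
    """Threshold rule recovering flare class from the operculum opening."""
    angle_deg = np.asarray(angle_deg, dtype=float)
    out = np.zeros(angle_deg.shape, dtype=np.int8)
    out[angle_deg >= OPERCULUM_PARTIAL_THRESH] = 1
    out[angle_deg >= OPERCULUM_FULL_THRESH] = 2
    return out


def write_trial(trial: SimulatedTrial, out_dir, px_per_cm: float = 20.0) -> None:
    """Write keypoint tables, feature tables and label event logs as CSV."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, agent in enumerate(trial.agents):
        kp = (agent.keypoints if agent.keypoints is not None
              else render_keypoints(agent, px_per_cm=px_per_cm))
        kp.to_csv(out / f"agent{i}_keypoints.csv", index=False)
        agent.features.to_csv(out / f"agent{i}_features.csv")
        agent.ethogram.to_events().to_csv(out / f"agent{i}_events.csv", index=False)
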