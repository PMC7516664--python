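"""Synthetic dyads: paired percussive envelopes with controlled coupling.

The generator emulates what the downstream metrics actually see in a
drum-pad improvisation trial: a non-negative amplitude envelope per player,
sampled every 150 ms for two minutes (T = 800 samples).  Strikes live on a
pulse grid.  Each player maintains a rhythmic cell (motif) of
``motif_len`` pulse slots, each slot holding a strike velocity in [0, 1]
(0 = rest); the cell repeats, individual slots mutate with probability
``motif_noise`` per visit (the motif evolves rather than resetting), and the
player's position in the cell occasionally slips by one slot
(``phase_slip``), emulating human tempo drift.  A struck slot resets the
envelope to its velocity, which then decays geometrically
(``decay_per_sample``); additive measurement noise is folded in last.

Directional coupling is applied at the slot level so ground truth is
unambiguous: with probability ``coupling_eps`` per pulse, player B's emitted
slot copies player A's realized slot one pulse earlier.  The copy is
transient — B's internal motif is not rewritten — and all of B's randomness
comes from B's own stream, so at ``coupling_eps=0`` the two series are
generated from fully independent streams.

Two design points matter for calibration.  Phase slips make the relative
alignment of two *independent* players a mixing random walk; without them
both motifs would stay phase-locked on the shared grid forever and
independent dyads would show spurious mutual information.  Sparse strikes
(``hit_prob``) with slow decay concentrate the ordinal-symbol distribution,
which keeps the plug-in estimator bias at T = 800 well below the coupling
signal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, LengthError
from .ingest import AmplitudeSeries

__all__ = [
    "DyadSimConfig",
    "SyntheticDyad",
    "ExpertiseLink",
    "Cohort",
    "generate_dyad",
    "generate_iid_series",
    "generate_cohort",
    "LIKERT_PROBS",
]

#: Distribution of the 0-4 collaboration-experience score used when sampling
#: synthetic participants (proportions observed in a 60-participant survey
#: of university students: 12/11/17/13/7).
LIKERT_PROBS = np.array([12, 11, 17, 13, 7], dtype=float) / 60.0


@dataclass(frozen=True)
class DyadSimConfig:
    """Parameters of one synthetic dyad.

    Defaults reproduce the study conditions: 120 s trials sampled at 150 ms
    (T = 800), one pulse per sample, evolving 8-slot motifs with sparse
    strikes, and moderate directional coupling.
    """

    duration_s: float = 120.0
    dt_s: float = 0.15
    tempo_period: int = 1
    motif: Optional[Sequence[float]] = None
    motif_len: int = 8
    motif_noise: float = 0.1
    hit_prob: float = 0.3
    velocity_range: tuple[float, float] = (0.3, 1.0)
    phase_slip: float = 0.1
    coupling_eps: float = 0.5
    decay_per_sample: float = 0.8
    noise_sd: float = 0.01
    seed: int = 0
    seed_a: Optional[int] = None
    seed_b: Optional[int] = None

    def __post_init__(self) -> None:
        n = self.duration_s / self.dt_s
        if not (n > 0 and abs(n - round(n)) < 1e-9):
            raise ConfigurationError(
                f"duration_s/dt_s must be a positive integer, got {n}"
            )
        for name in ("motif_noise", "hit_prob", "phase_slip", "coupling_eps"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 < self.decay_per_sample < 1.0):
            raise ConfigurationError(
                f"decay_per_sample must lie in (0, 1), got {self.decay_per_sample}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.tempo_period < 1 or int(self.tempo_period) != self.tempo_period:
            raise ConfigurationError("tempo_period must be a positive integer")
        if self.motif is not None:
            mv = np.asarray(self.motif, dtype=float)
            if mv.ndim != 1 or mv.size < 1:
                raise ConfigurationError("motif must be a non-empty sequence")
            if np.any((mv < 0) | (mv > 1)):
                raise ConfigurationError("motif velocities must lie in [0, 1]")
        if self.motif_len < 1:
            raise ConfigurationError("motif_len must be a positive integer")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s / self.dt_s))


@dataclass(frozen=True)
class SyntheticDyad:
    """A generated pair of envelopes plus the generating ground truth.

    ``truth`` records the per-pulse slot velocities actually emitted by both
    players (the event log), the coupling strength and its direction, and
    the initial motifs — enough to verify slot-level copying directly.
    """

    series_a: AmplitudeSeries
    series_b: AmplitudeSeries
    truth: dict

    def __post_init__(self) -> None:
        if len(self.series_a) != len(self.series_b):
            raise ConfigurationError("paired series must have equal length")


def _player_seeds(config: DyadSimConfig) -> tuple[np.random.Generator, np.random.Generator]:
    sa = config.seed_a
    sb = config.seed_b
    rng_a = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 0]) if sa is None else int(sa)
    )
    rng_b = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 1]) if sb is None else int(sb)
    )
    return rng_a, rng_b


def _draw_cell(rng: np.random.Generator, config: DyadSimConfig, n: int) -> np.ndarray:
    lo, hi = config.velocity_range
    vel = rng.uniform(lo, hi, n)
    return np.where(rng.random(n) < config.hit_prob, vel, 0.0)


def _evolve_slots(
    rng: np.random.Generator, config: DyadSimConfig, n_pulses: int
) -> np.ndarray:
    """One player's emitted slot velocities, pulse by pulse."""
    if config.motif is not None:
        cell = np.asarray(config.motif, dtype=float).copy()
    else:
        cell = _draw_cell(rng, config, config.motif_len)
    L = cell.size
    # Pre-draw all randomness so the inner loop is pure bookkeeping.
    mutate = rng.random(n_pulses) < config.motif_noise
    new_vals = _draw_cell(rng, config, n_pulses)
    slip = rng.random(n_pulses) < config.phase_slip
    slip_step = rng.integers(0, 2, n_pulses) * 2  # 0 = repeat slot, 2 = skip one
    out = np.empty(n_pulses)
    j = 0
    for k in range(n_pulses):
        if mutate[k]:
            cell[j] = new_vals[k]
        out[k] = cell[j]
        j = (j + (slip_step[k] if slip[k] else 1)) % L
    return out


def _render(
    slots: np.ndarray, config: DyadSimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Expand pulse-slot velocities into a decaying amplitude envelope."""
    T = config.n_samples
    strike = np.zeros(T)
    pulse_samples = np.arange(0, T, config.tempo_period)
    strike[pulse_samples] = slots[: pulse_samples.size]
    idx = np.arange(T)
    last = np.maximum.accumulate(np.where(strike > 0, idx, -1))
    with np.errstate(invalid="ignore"):
        amp = np.where(
            last >= 0,
            strike[np.maximum(last, 0)] * config.decay_per_sample ** (idx - last),
            0.0,
        )
    if config.noise_sd > 0:
        amp = np.abs(amp + rng.normal(0.0, config.noise_sd, T))
    return amp


def generate_dyad(config: DyadSimConfig) -> SyntheticDyad:
    """Generate one pair of coupled percussive envelopes.

    Identical config (and seed) gives bit-identical output.  At
    ``coupling_eps=0`` player B's series depends only on B's random stream.
    """
    rng_a, rng_b = _player_seeds(config)
    n_pulses = -(-config.n_samples // config.tempo_period) + 1
    slots_a = _evolve_slots(rng_a, config, n_pulses)
    slots_b = _evolve_slots(rng_b, config, n_pulses)
    copied = rng_b.random(n_pulses) < config.coupling_eps
    copied[0] = False
    slots_b = slots_b.copy()
    slots_b[1:][copied[1:]] = slots_a[:-1][copied[1:]]
    amp_a = _render(slots_a, config, rng_a)
    amp_b = _render(slots_b, config, rng_b)
    return SyntheticDyad(
        series_a=AmplitudeSeries(values=amp_a, dt_s=config.dt_s, player_id="a"),
        series_b=AmplitudeSeries(values=amp_b, dt_s=config.dt_s, player_id="b"),
        truth={
            "coupling_eps": config.coupling_eps,
            "direction": "a->b",
            "slots_a": slots_a,
            "slots_b": slots_b,
            "copied": copied,
            "motif": config.motif,
        },
    )


def generate_iid_series(T: int, seed: int, dt_s: float = 0.15) -> AmplitudeSeries:
    """T independent draws from Uniform(0, 1) — the i.i.d. reference series.

    Continuous, so exact ties occur with probability zero and the ordinal
    alphabet is sampled uniformly; SRR approaches 1/m! and the recurrence
    entropy approaches log2(m!) for long series.
    """
    if T < 3:
        raise LengthError(f"T={T} is too short for the default embedding length")
    values = np.random.default_rng(int(seed)).random(T)
    return AmplitudeSeries(values=values, dt_s=dt_s)


@dataclass(frozen=True)
class ExpertiseLink:
    """Logistic map from a pair's summed collaboration scores to coupling.

    ``coupling_eps = sigmoid(intercept + slope * (score_a + score_b))``.
    With the defaults the coupling spans roughly 0.12 (two complete novices)
    to 0.69 (two players who always play with others).  Set ``slope=0`` for
    a null cohort with constant coupling.
    """

    intercept: float = -2.0
    slope: float = 0.35

    def coupling(self, score_a: float, score_b: float) -> float:
        return float(
            1.0 / (1.0 + math.exp(-(self.intercept + self.slope * (score_a + score_b))))
        )


@dataclass
class Cohort:
    """A full synthetic study: dyads for every pair and session, plus surveys."""

    participants: pd.DataFrame
    dyads: dict  # (pair_id, session) -> SyntheticDyad
    truth: dict  # pair_id -> {"coupling_eps": float, "follower": "a"|"b"}
    n_sessions: int

    @property
    def pair_ids(self) -> list[str]:
        return sorted(self.truth)


def _sample_years(rng: np.random.Generator, likert: int) -> float:
    """Years of practice, loosely increasing with collaboration experience."""
    p_zero = max(0.05, 0.5 - 0.1 * likert)
    if rng.random() < p_zero:
        return 0.0
    return float(np.round(min(15.0, rng.gamma(1.5, 1.0 + likert)), 1))


def generate_cohort(
    n_pairs: int,
    expertise_model: ExpertiseLink | None = None,
    seed: int = 0,
    config: DyadSimConfig | None = None,
    n_sessions: int = 2,
) -> Cohort:
    """Generate ``n_pairs`` dyads per session with matched expertise records.

    Each pair gets two participants (players "a" and "b") with a Likert
    collaboration score in {0..4} and years of practice; the dyad's coupling
    strength is the expertise model's logistic function of the two scores,
    and the copying (follower) role is assigned to one random player and
    kept across sessions, as is the coupling strength — so cross-session
    consistency is built in while each session's audio is fresh.
    """
    if n_pairs < 1:
        raise ConfigurationError("n_pairs must be >= 1")
    link = expertise_model if expertise_model is not None else ExpertiseLink()
    base = config if config is not None else DyadSimConfig()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 12345]))
    rows = []
    dyads: dict = {}
    truth: dict = {}
    for i in range(n_pairs):
        pair_id = f"pair{i:03d}"
        scores = rng.choice(5, size=2, p=LIKERT_PROBS)
        years = [_sample_years(rng, int(s)) for s in scores]
        eps = link.coupling(float(scores[0]), float(scores[1]))
        follower = "ab"[int(rng.integers(0, 2))]
        truth[pair_id] = {"coupling_eps": eps, "follower": follower}
        for player, score, yr in zip("ab", scores, years):
            rows.append(
                {
                    "pair_id": pair_id,
                    "player_id": player,
                    "likert": int(score),
                    "years": yr,
                }
            )
        for session in range(1, n_sessions + 1):
            dyad_seed = int(rng.integers(0, 2**31 - 1))
            cfg_kwargs = {
                "coupling_eps": eps,
                "seed": dyad_seed,
                "seed_a": None,
                "seed_b": None,
            }
            cfg = DyadSimConfig(
                **{**_config_as_dict(base), **cfg_kwargs}
            )
            dyad = generate_dyad(cfg)
            if follower == "a":
                # player "a" is the copier: swap the generated roles
                dyad = SyntheticDyad(
                    series_a=_relabel(dyad.series_b, "a"),
                    series_b=_relabel(dyad.series_a, "b"),
                    truth={**dyad.truth, "direction": "b->a"},
                )
            for s in (dyad.series_a, dyad.series_b):
                object.__setattr__(s, "trial_id", pair_id)
                object.__setattr__(s, "session", session)
            dyads[(pair_id, session)] = dyad
    participants = pd.DataFrame(rows)
    return Cohort(
        participants=participants, dyads=dyads, truth=truth, n_sessions=n_sessions
    )


def _config_as_dict(cfg: DyadSimConfig) -> dict:
    from dataclasses import asdict

    return asdict(cfg)


def _relabel(series: AmplitudeSeries, player_id: str) -> AmplitudeSeries:
    from dataclasses import replace

    return replace(series, player_id=player_id)
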