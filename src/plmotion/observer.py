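"""Synthetic observers for the velocity-uniformity adjustment task.

No raw human responses are available for this paradigm, so every analysis
stage is exercised against a generative stand-in: each simulated participant
holds a latent prototype of "uniform-looking" motion on the ordinal profile
scale (0-20), corrupted by trial-to-trial Gaussian noise and shifted by a
per-participant random effect.  A trial either samples the resulting ordinal
response directly, or replays the forward/backward staircase protocol (start
at one of {2, 6, 10, 14, 18}, step one profile at a time, out-of-range steps
replaced at random from {6, 10, 14}) until the drawn target is reached.

The model is parameterized on the cumulative-response scale: ``mu`` is the
population point of subjective equality (PSE), i.e. the ordinal cumulative
distribution satisfies P(response <= i) = Phi((i - mu)/sigma_trial) exactly.
Internally the latent draw is centred half an index above ``mu`` because the
cumulative count at index i collects all latents below i + 1/2; the
discretization rounds half-down so that the noise-free observer reports
exactly ``mu`` for any integer prototype.

Default parameter values reproduce the fitted population PSE/JND of the three
pendulum orientations (0/90/180 deg) of the back-and-forth arc experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "ObserverModel",
    "ExperimentDesign",
    "TrialRecord",
    "simulate_trial_direct",
    "simulate_trial_procedural",
    "simulate_experiment",
    "validate_response_table",
    "write_response_table",
    "read_response_table",
    "DEFAULT_PSE",
    "DEFAULT_JND",
    "EXP1_CONDITIONS",
]

N_LEVELS = 21  # ordinal profiles K_0 .. K_20
STARTING_SET = (2, 6, 10, 14, 18)
REPLACEMENT_SET = (6, 10, 14)

#: Published population PSE / JND of the three arc orientations (index units);
#: sigma_trial defaults to JND / Phi^-1(0.75) so that the synthetic study
#: reproduces the fitted psychometric scale.
EXP1_CONDITIONS = ("0", "90", "180")
DEFAULT_PSE = {"0": 10.08, "90": 9.15, "180": 8.66}
DEFAULT_JND = {"0": 0.939, "90": 1.383, "180": 1.087}
_Z75 = float(norm.ppf(0.75))


def _as_condition_map(value, conditions) -> dict[str, float]:
    if isinstance(value, dict):
        missing = [c for c in conditions if c not in value]
        if missing:
            raise ValueError(f"missing value for condition(s) {missing}")
        return {c: float(value[c]) for c in conditions}
    return {c: float(value) for c in conditions}


@dataclass
class ObserverModel:
    """Latent-prototype observer population.

    Parameters
    ----------
    mu : dict or float
        Population PSE per condition, index units, each in [0, 20].
    sigma_trial : dict or float
        Trial-to-trial latent noise SD per condition, index units, > 0.
    tau : float
        Between-participant SD of the prototype (shared random shift across
        conditions), index units, >= 0.
    slope_jitter : float
        Between-participant SD of 1/sigma (optional heterogeneity of response
        precision), >= 0.
    start_pull : float
        Optional linear attraction of the response toward the trial's starting
        profile (0 = off, the default; the reported effect in the human data
        is at most one index unit and no mechanism is given).
    seed : int or None
        Default RNG seed for :func:`simulate_experiment`.
    """

    mu: dict[str, float] | float = field(default_factory=lambda: dict(DEFAULT_PSE))
    sigma_trial: dict[str, float] | float = field(
        default_factory=lambda: {c: DEFAULT_JND[c] / _Z75 for c in EXP1_CONDITIONS}
    )
    tau: float = 0.5
    slope_jitter: float = 0.0
    start_pull: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.slope_jitter < 0:
            raise ValueError("slope_jitter must be >= 0")
        mus = self.mu.values() if isinstance(self.mu, dict) else [self.mu]
        for m in mus:
            if not (0.0 <= m <= 20.0):
                raise ValueError(f"mu must lie in [0, 20], got {m}")
        sigmas = (
            self.sigma_trial.values()
            if isinstance(self.sigma_trial, dict)
            else [self.sigma_trial]
        )
        for s in sigmas:
            if not s > 0:
                raise ValueError(f"sigma_trial must be > 0, got {s}")

    def condition_params(self, condition: str) -> tuple[float, float]:
        mu = self.mu[condition] if isinstance(self.mu, dict) else self.mu
        sig = (
            self.sigma_trial[condition]
            if isinstance(self.sigma_trial, dict)
            else self.sigma_trial
        )
        return float(mu), float(sig)


@dataclass(frozen=True)
class ExperimentDesign:
    """Balanced session design: participants x conditions x (starts x repetitions)."""

    conditions: tuple[str, ...] = EXP1_CONDITIONS
    n_participants: int = 12
    starting_set: tuple[int, ...] = STARTING_SET
    n_repetitions: int = 10

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("need at least one participant")
        if len(self.conditions) == 0:
            raise ValueError("design lists no conditions")
        for s in self.starting_set:
            if not (0 <= s < N_LEVELS):
                raise ValueError(f"starting index {s} outside [0, 20]")

    @property
    def trials_per_condition(self) -> int:
        return len(self.starting_set) * self.n_repetitions


@dataclass
class TrialRecord:
    """One ordinal selection by one participant."""

    participant: int
    condition: str
    starting_index: int
    repetition: int
    response_index: int
    n_adjustments: int

    def __post_init__(self) -> None:
        if self.starting_index not in STARTING_SET:
            raise ValueError(f"starting_index {self.starting_index} not in {STARTING_SET}")
        if not (0 <= self.response_index < N_LEVELS):
            raise ValueError(f"response_index {self.response_index} outside [0, 20]")


@dataclass
class _ParticipantEffects:
    """Per-participant random effects, drawn once per participant."""

    shift: float = 0.0  # added to the latent prototype
    inv_sigma_shift: float = 0.0  # added to 1/sigma_trial


def _draw_target(
    obs: ObserverModel,
    effects: _ParticipantEffects,
    condition: str,
    rng: np.random.Generator,
    starting_index: int | None = None,
) -> float:
    """Latent target for one trial (continuous, before discretization)."""
    mu, sigma = obs.condition_params(condition)
    if effects.inv_sigma_shift:
        sigma = 1.0 / max(1.0 / sigma + effects.inv_sigma_shift, 1e-3)
    centre = mu + 0.5 + effects.shift
    if obs.start_pull and starting_index is not None:
        centre = centre + obs.start_pull * (starting_index - mu)
    return float(rng.normal(centre, sigma))


def _discretize(x: float) -> int:
    """Round half-down after clipping to the ordinal range."""
    x = min(max(x, 0.0), float(N_LEVELS - 1))
    return int(math.ceil(x - 0.5))


def _apply_step(current: int, step: int, rng: np.random.Generator) -> int:
    """One forward/backward button press with the out-of-range replacement rule.

    A requested index beyond 0 or 20 is replaced by a uniformly random member
    of {6, 10, 14}, exactly as the protocol's computer did.
    """
    requested = current + step
    if requested < 0 or requested >= N_LEVELS:
        return int(rng.choice(REPLACEMENT_SET))
    return requested


def simulate_trial_direct(
    obs: ObserverModel,
    effects: _ParticipantEffects,
    condition: str,
    rng: np.random.Generator,
    starting_index: int = 10,
    participant: int = 0,
    repetition: int = 1,
) -> TrialRecord:
    """Sample the trial endpoint directly from the latent model.

    ``n_adjustments`` is the walk-to-target minimum |start - response|.
    """
    x = _draw_target(obs, effects, condition, rng, starting_index)
    response = _discretize(x)
    return TrialRecord(
        participant=participant,
        condition=condition,
        starting_index=starting_index,
        repetition=repetition,
        response_index=response,
        n_adjustments=abs(starting_index - response),
    )


def simulate_trial_procedural(
    obs: ObserverModel,
    effects: _ParticipantEffects,
    condition: str,
    rng: np.random.Generator,
    starting_index: int = 10,
    participant: int = 0,
    repetition: int = 1,
    max_steps: int = 500,
) -> TrialRecord:
    """Replay the staircase protocol: step toward the drawn target, then OK.

    The observer draws its trial target once, then presses forward/backward to
    walk one profile at a time toward it.  A step requested beyond index 0 or
    20 triggers replacement by a uniformly random member of {6, 10, 14} (the
    protocol's out-of-range rule), after which walking resumes.  Exceeding
    ``max_steps`` raises RuntimeError (runaway trial).
    """
    x = _draw_target(obs, effects, condition, rng, starting_index)
    target = _discretize(x)
    current = starting_index
    n_adjust = 0
    while current != target:
        if n_adjust >= max_steps:
            raise RuntimeError(
                f"runaway trial: {n_adjust} adjustments without reaching target"
            )
        step = 1 if target > current else -1
        current = _apply_step(current, step, rng)
        n_adjust += 1
    return TrialRecord(
        participant=participant,
        condition=condition,
        starting_index=starting_index,
        repetition=repetition,
        response_index=current,
        n_adjustments=n_adjust,
    )


def _starting_sequence(
    starting_set: tuple[int, ...], n_repetitions: int, rng: np.random.Generator
) -> list[int]:
    """Pseudo-random trial order: each start n_repetitions times, no immediate repeats."""
    seq = list(starting_set) * n_repetitions
    for _ in range(1000):
        rng.shuffle(seq)
        if all(a != b for a, b in zip(seq, seq[1:])):
            return seq
    # fall back to a deterministic repair: swap offending neighbours
    for i in range(1, len(seq)):
        if seq[i] == seq[i - 1]:
            for j in range(len(seq)):
                if seq[j] != seq[i] and (j == 0 or seq[j - 1] != seq[i]) and (
                    j + 1 >= len(seq) or seq[j + 1] != seq[i]
                ):
                    seq[i], seq[j] = seq[j], seq[i]
                    break
    return seq


def simulate_experiment(
    obs: ObserverModel,
    design: ExperimentDesign = ExperimentDesign(),
    seed: int | None = None,
    mode: str = "procedural",
) -> pd.DataFrame:
    """Simulate a full balanced study; returns the trial-level response table.

    Columns: participant, condition, starting_index, repetition,
    response_index, n_adjustments.  Identical seeds give identical tables.
    """
    if mode not in ("procedural", "direct"):
        raise ValueError(f"unknown mode {mode!r}")
    if seed is None:
        seed = obs.seed
    rng = np.random.default_rng(seed)
    trial_fn = (
        simulate_trial_procedural if mode == "procedural" else simulate_trial_direct
    )
    rows = []
    for j in range(design.n_participants):
        effects = _ParticipantEffects(
            shift=float(rng.normal(0.0, obs.tau)) if obs.tau > 0 else 0.0,
            inv_sigma_shift=(
                float(rng.normal(0.0, obs.slope_jitter)) if obs.slope_jitter > 0 else 0.0
            ),
        )
        for condition in design.conditions:
            seq = _starting_sequence(design.starting_set, design.n_repetitions, rng)
            rep_count: dict[int, int] = {s: 0 for s in design.starting_set}
            for start in seq:
                rep_count[start] += 1
                rec = trial_fn(
                    obs,
                    effects,
                    condition,
                    rng,
                    starting_index=start,
                    participant=j,
                    repetition=rep_count[start],
                )
                rows.append(rec)
    return pd.DataFrame([r.__dict__ for r in rows])


def validate_response_table(table: pd.DataFrame, design: ExperimentDesign | None = None) -> None:
    """Check table integrity: ranges, balance, and the no-repeat start rule."""
    required = {
        "participant",
        "condition",
        "starting_index",
        "repetition",
        "response_index",
        "n_adjustments",
    }
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"response table missing column(s) {sorted(missing)}")
    if not table["response_index"].between(0, N_LEVELS - 1).all():
        raise ValueError("response_index outside [0, 20]")
    if not table["starting_index"].isin(STARTING_SET).all():
        raise ValueError(f"starting_index outside {STARTING_SET}")
    for (p, c), grp in table.groupby(["participant", "condition"], sort=False):
        starts = grp["starting_index"].to_numpy()
        if np.any(starts[1:] == starts[:-1]):
            raise ValueError(
                f"participant {p}, condition {c}: successive trials share a starting index"
            )
    if design is not None:
        counts = table.groupby(["participant", "condition"]).size()
        if not (counts == design.trials_per_condition).all():
            raise ValueError("unbalanced design: wrong trial count per cell")


def write_response_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_response_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, dtype={"condition": str})
    if table.empty:
        raise ValueError(f"empty response table: {path}")
    return table
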