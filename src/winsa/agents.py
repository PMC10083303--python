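"""Behavioral agents: scripted pokers and a stochastic trait-driven cohort.

Scripted agents (:class:`ScriptedAgent`, :class:`PeriodicAgent`,
:class:`NullAgent`) emit pokes at predetermined absolute times and are
the workhorses of contingency tests and worked examples.

:class:`TraitAgent` is a renewal-process responder whose inter-poke
intervals are exponential with a hazard assembled from a latent
:class:`TraitProfile`: a baseline active/inactive rate (pokes/min), a
saturating per-session learning multiplier during fixed-ratio training,
an impulsivity multiplier during time-outs, a perseverance multiplier
during the drug-free period, a hard give-up threshold on the
progressive-ratio requirement, a per-shock probability of continuing to
respond in the punished session, and an exponential per-session decline
(with a first-session burst) once reinforcement is withheld. Memoryless
waits make the engine's re-ask after phase transitions exact rather
than approximate.

:func:`sample_cohort` draws a cohort of profiles from per-label trait
distributions with planted ``vulnerable`` / ``resilient`` ground truth,
emulating the individual variability that the phenotyping pipeline is
designed to resolve.
"""

from __future__ import annotations

import bisect
import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import PR_RATIO_SERIES
from .engine import (ACTIVE, INACTIVE, NONE, PHASE_CUE, PHASE_DRUGFREE,
                     PHASE_TIMEOUT, SessionSnapshot)
from .exceptions import ConfigError

VULNERABLE, RESILIENT = "vulnerable", "resilient"

#: e-folding constant (in sessions) of the saturating acquisition curve
LEARNING_TAU = 2.0


# -- scripted agents -------------------------------------------------------

class NullAgent:
    """Never pokes."""

    def next_action(self, state, elapsed_s, rng):
        return (math.inf, NONE)


class ScriptedAgent:
    """Pokes at fixed absolute session times.

    Parameters
    ----------
    schedule : sequence of (t, hole)
        Strictly increasing absolute times (s) and the hole poked.
        Stateless lookup by elapsed time, so the engine may re-ask freely.
    """

    def __init__(self, schedule):
        self.times = [float(t) for t, _ in schedule]
        self.holes = [h for _, h in schedule]
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ConfigError("scripted schedule times must strictly increase")

    def next_action(self, state, elapsed_s, rng):
        i = bisect.bisect_right(self.times, elapsed_s)
        if i >= len(self.times):
            return (math.inf, NONE)
        return (self.times[i] - elapsed_s, self.holes[i])


class PeriodicAgent(ScriptedAgent):
    """Pokes one hole every ``period_s`` seconds, forever (up to ``horizon_s``)."""

    def __init__(self, period_s: float, hole: str = ACTIVE,
                 horizon_s: float = 20000.0):
        n = int(horizon_s / period_s)
        super().__init__([(period_s * (k + 1), hole) for k in range(n)])


def burst_agent(n_pokes: int, spacing_s: float, hole: str = ACTIVE,
                start_s: float = 1.0) -> ScriptedAgent:
    """``n_pokes`` pokes at fixed spacing starting at ``start_s``, then silence."""
    return ScriptedAgent([(start_s + k * spacing_s, hole)
                          for k in range(n_pokes)])


# -- trait profiles --------------------------------------------------------

@dataclass
class TraitProfile:
    """Latent per-agent parameters plus planted ground-truth phenotype."""

    subject_id: str
    base_active_rate: float        # pokes/min on the active hole
    base_inactive_rate: float      # pokes/min on the inactive hole
    learning_gain: float           # asymptotic multiplier on active rate
    impulsivity: float             # hazard multiplier during time-outs
    perseverance: float            # hazard multiplier during drug-free period
    motivation: int                # give-up PR requirement (from the series)
    shock_tolerance: float         # P(keep responding) after each shock
    extinction_decay: float        # per-session decline without reinforcement
    burst_gain: float              # active-hazard multiplier, extinction day 1
    cue_gain: float                # active-hazard multiplier in the cue phase
    ground_truth_label: str = RESILIENT
    group: str = "saline"
    dropout: bool = False          # failed catheter-patency check

    def validate(self) -> None:
        for name in ("base_active_rate", "base_inactive_rate",
                     "learning_gain", "impulsivity", "perseverance",
                     "extinction_decay", "burst_gain", "cue_gain"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigError(f"{name} must be finite and >= 0, got {v}")
        if self.base_active_rate <= 0:
            raise ConfigError("base_active_rate must be > 0")
        if not 0.0 <= self.shock_tolerance <= 1.0:
            raise ConfigError("shock_tolerance must lie in [0, 1]")
        if self.motivation < 1:
            raise ConfigError("motivation (give-up ratio) must be >= 1")
        if self.ground_truth_label not in (VULNERABLE, RESILIENT):
            raise ConfigError(f"bad label {self.ground_truth_label!r}")


def learning_multiplier(gain: float, session_index: int,
                        tau: float = LEARNING_TAU) -> float:
    """Saturating acquisition curve: 1 on session 0, -> ``gain`` asymptotically."""
    return gain - (gain - 1.0) * math.exp(-session_index / tau)


class TraitAgent:
    """Stochastic responder for one session, parameterized by a TraitProfile.

    Parameters
    ----------
    profile : TraitProfile
    session_kind : one of the engine session kinds
    kind_index : session index within its kind (FR training index across
        FR1+FR2 for the learning curve; extinction day 0..9 for decay)
    n_extinction_before : extinction sessions completed before a
        reinstatement session (sets the extinguished baseline hazard)
    """

    def __init__(self, profile: TraitProfile, session_kind: str,
                 kind_index: int = 0, n_extinction_before: int = 10):
        profile.validate()
        self.p = profile
        self.kind = session_kind
        self.kind_index = kind_index
        self.n_ext = n_extinction_before
        self._quit = False
        self._shocks_seen = 0

    def _active_hazard_per_min(self, state: SessionSnapshot) -> float:
        p = self.p
        rate = p.base_active_rate
        if self.kind in ("FR", "SHOCK", "PR"):
            rate *= learning_multiplier(p.learning_gain, self.kind_index)
        if self.kind == "PR":
            if state.required_ratio is not None and \
                    state.required_ratio > p.motivation:
                return 0.0                      # gave up
        if self.kind == "SHOCK" and self._quit:
            return 0.0
        if self.kind == "EXTINCTION":
            rate *= learning_multiplier(p.learning_gain, self.kind_index + 10)
            rate *= math.exp(-p.extinction_decay * self.kind_index)
            if self.kind_index == 0:
                rate *= p.burst_gain            # extinction burst
        if self.kind == "REINSTATEMENT":
            rate *= learning_multiplier(p.learning_gain, 10)
            rate *= math.exp(-p.extinction_decay * self.n_ext)
            if state.phase == PHASE_CUE:
                rate *= p.cue_gain
        if state.phase == PHASE_TIMEOUT:
            rate *= p.impulsivity
        elif state.phase == PHASE_DRUGFREE:
            rate *= p.perseverance
        return rate

    def next_action(self, state: SessionSnapshot, elapsed_s: float,
                    rng: np.random.Generator):
        if self.kind == "SHOCK" and state.shocks > self._shocks_seen:
            # one continuation draw per shock received since the last call
            for _ in range(state.shocks - self._shocks_seen):
                if rng.random() >= self.p.shock_tolerance:
                    self._quit = True
            self._shocks_seen = state.shocks
        lam_a = self._active_hazard_per_min(state) / 60.0
        lam_i = self.p.base_inactive_rate / 60.0
        total = lam_a + lam_i
        if total <= 1e-12:
            return (math.inf, NONE)
        wait = rng.exponential(1.0 / total)
        hole = ACTIVE if rng.random() < lam_a / total else INACTIVE
        return (wait, hole)


# -- cohort sampling -------------------------------------------------------

#: motivation (give-up) support must come from the PR series
_SERIES_SET = set(PR_RATIO_SERIES)

_DISTRIBUTIONS = ("lognormal", "uniform", "choice", "constant")


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort; the seed fixes everything."""

    n_subjects: int
    fraction_vulnerable: float
    trait_distributions: dict          # label -> trait -> (family, params)
    group_probabilities: dict = field(
        default_factory=lambda: {"saline": 0.5, "treated": 0.5})
    dropout_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if not 0.0 <= self.fraction_vulnerable <= 1.0:
            raise ConfigError("fraction_vulnerable must lie in [0, 1]")
        if abs(sum(self.group_probabilities.values()) - 1.0) > 1e-9:
            raise ConfigError("group probabilities must sum to 1")
        for label in (RESILIENT, VULNERABLE):
            if label not in self.trait_distributions:
                raise ConfigError(f"missing trait distributions for {label!r}")
            for trait, (family, params) in \
                    self.trait_distributions[label].items():
                if family not in _DISTRIBUTIONS:
                    raise ConfigError(
                        f"{label}/{trait}: unknown family {family!r}")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False),
                              encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        raw["trait_distributions"] = {
            label: {trait: (fam, params) for trait, (fam, params)
                    in dists.items()}
            for label, dists in raw["trait_distributions"].items()}
        return cls(**raw)


def _draw(family: str, params: dict, rng: np.random.Generator) -> float:
    if family == "lognormal":
        return float(rng.lognormal(mean=params["mean"],
                                   sigma=params["sigma"]))
    if family == "uniform":
        return float(rng.uniform(params["low"], params["high"]))
    if family == "choice":
        values = params["values"]
        p = params.get("p")
        return float(rng.choice(values, p=p))
    if family == "constant":
        return float(params["value"])
    raise ConfigError(f"unknown distribution family {family!r}")


def default_cohort_spec(n_subjects: int = 60,
                        fraction_vulnerable: float = 0.30,
                        seed: int = 0) -> CohortSpec:
    """The shipped study conditions: a 60-mouse cohort, 30% vulnerable.

    Rates and multipliers are log-normal; vulnerable agents shift
    perseverance, the give-up ratio and shock tolerance upward, giving
    the extreme subpopulations the percentile classifier is meant to
    isolate. Magnitudes are nominal (no empirical response-rate data
    exist to calibrate against) but sit in the range of plausible mouse
    nose-poke output.
    """
    ln = lambda m, s: ("lognormal", {"mean": math.log(m), "sigma": s})
    resilient = {
        "base_active_rate": ln(0.35, 0.25),
        "base_inactive_rate": ln(0.08, 0.5),
        "learning_gain": ln(2.0, 0.2),
        "impulsivity": ln(0.8, 0.3),
        "perseverance": ln(0.30, 0.3),
        "motivation": ("choice", {"values": [5, 12, 21, 33],
                                  "p": [0.25, 0.35, 0.30, 0.10]}),
        "shock_tolerance": ("uniform", {"low": 0.30, "high": 0.60}),
        "extinction_decay": ln(0.35, 0.2),
        "burst_gain": ln(1.6, 0.15),
        "cue_gain": ln(1.3, 0.2),
    }
    vulnerable = {
        "base_active_rate": ln(0.60, 0.25),
        "base_inactive_rate": ln(0.08, 0.5),
        "learning_gain": ln(2.2, 0.2),
        "impulsivity": ln(3.0, 0.3),
        "perseverance": ln(1.2, 0.3),
        "motivation": ("choice", {"values": [75, 90, 120, 155, 180],
                                  "p": [0.30, 0.30, 0.20, 0.15, 0.05]}),
        "shock_tolerance": ("uniform", {"low": 0.88, "high": 0.98}),
        "extinction_decay": ln(0.22, 0.2),
        "burst_gain": ln(2.2, 0.15),
        "cue_gain": ln(2.0, 0.2),
    }
    return CohortSpec(
        n_subjects=n_subjects, fraction_vulnerable=fraction_vulnerable,
        trait_distributions={RESILIENT: resilient, VULNERABLE: vulnerable},
        dropout_rate=0.03, seed=seed)


def sample_cohort(spec: CohortSpec) -> list[TraitProfile]:
    """Draw ``spec.n_subjects`` trait profiles, reproducibly from ``spec.seed``.

    The vulnerable count is the rounded fraction; label positions, group
    assignment, dropout flags and trait values are all drawn from a single
    generator seeded by the spec.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    n_vuln = int(round(n * spec.fraction_vulnerable))
    labels = np.array([VULNERABLE] * n_vuln + [RESILIENT] * (n - n_vuln))
    rng.shuffle(labels)
    groups = list(spec.group_probabilities)
    probs = [spec.group_probabilities[g] for g in groups]
    profiles = []
    for i in range(n):
        label = str(labels[i])
        dists = spec.trait_distributions[label]
        traits = {trait: _draw(fam, params, rng)
                  for trait, (fam, params) in dists.items()}
        motivation = int(round(traits.pop("motivation")))
        if motivation not in _SERIES_SET:
            raise ConfigError(
                f"motivation draw {motivation} outside the PR ratio series")
        profile = TraitProfile(
            subject_id=f"m{i:03d}",
            ground_truth_label=label,
            group=str(rng.choice(groups, p=probs)),
            dropout=bool(rng.random() < spec.dropout_rate),
            motivation=motivation,
            **traits)
        profile.validate()
        profiles.append(profile)
    return profiles


def cohort_to_frame(profiles: list[TraitProfile]) -> pd.DataFrame:
    """Ground-truth table: subject_id, label, group, then trait columns."""
    rows = [dataclasses.asdict(p) for p in profiles]
    df = pd.DataFrame(rows)
    front = ["subject_id", "ground_truth_label", "group", "dropout"]
    df = df[front + [c for c in df.columns if c not in front]]
    return df.rename(columns={"ground_truth_label": "label"})
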