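"""Protocol configuration for the operant self-administration model.

The defaults encode the printed protocol of the mouse WIN 55,212-2
intravenous self-administration paradigm: daily fixed-ratio (FR) sessions
built from two 55-min active periods separated by a 15-min drug-free
period (125 min total), a 10-s post-infusion time-out, a 50-reinforcer
cap, a 4-h progressive-ratio (PR) session with a 1-h inactivity stopping
rule, a 50-min shock (compulsivity) test with a 1-min pairing window,
2-h extinction sessions for 10 days, and a 90-min cue-induced
reinstatement session whose last 30 min restore the drug-paired cues.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .exceptions import ConfigError

#: Response requirements of the progressive-ratio schedule. The k-th
#: infusion requires PR_RATIO_SERIES[k-1] active nose-pokes; the last
#: ratio completed is the breaking point.
PR_RATIO_SERIES: tuple[int, ...] = (
    1, 5, 12, 21, 33, 51, 75, 90, 120, 155,
    180, 225, 260, 300, 350, 410, 465, 540, 630, 730,
    850, 1000, 1200, 1500, 1800, 2100, 2400, 2700, 3000, 3400,
    3800, 4200, 4600, 5000, 5500,
)


@dataclass(frozen=True)
class ProtocolConfig:
    """All tunable parameters of the operant protocol (times in seconds)."""

    fr_value: int = 1                      # responses per infusion (1 or 2)
    n_fr1_sessions: int = 5
    n_fr2_sessions: int = 5
    active_period_s: float = 3300.0        # 55 min
    drugfree_period_s: float = 900.0       # 15 min
    timeout_s: float = 10.0
    max_reinforcers: int = 50
    session_cap_s: float = 7500.0          # 125 min
    pr_ratio_series: tuple[int, ...] = PR_RATIO_SERIES
    pr_cap_s: float = 14400.0              # 4 h
    pr_inactivity_s: float = 3600.0        # 1 h without any nose-poke
    shock_session_s: float = 3000.0        # 50 min
    shock_pair_window_s: float = 60.0
    shock_mA: float = 0.18                 # metadata only; no aversive dynamics here
    extinction_session_s: float = 7200.0   # 2 h
    n_extinction_sessions: int = 10
    reinstatement_total_s: float = 5400.0  # 90 min
    reinstatement_cue_phase_s: float = 1800.0  # final 30 min
    house_light_start_s: float = 3.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.fr_value not in (1, 2):
            raise ConfigError(f"fr_value must be 1 or 2, got {self.fr_value}")
        if self.active_period_s <= 0:
            raise ConfigError("active_period_s must be positive")
        for name in ("drugfree_period_s", "timeout_s", "session_cap_s",
                     "pr_cap_s", "pr_inactivity_s", "shock_session_s",
                     "shock_pair_window_s", "extinction_session_s",
                     "reinstatement_total_s", "reinstatement_cue_phase_s"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.max_reinforcers < 1:
            raise ConfigError("max_reinforcers must be >= 1")
        series = tuple(self.pr_ratio_series)
        if len(series) == 0 or series[0] < 1:
            raise ConfigError("pr_ratio_series must start at >= 1")
        if any(b <= a for a, b in zip(series, series[1:])):
            raise ConfigError("pr_ratio_series must be strictly increasing")
        if not self.reinstatement_cue_phase_s < self.reinstatement_total_s:
            raise ConfigError(
                "reinstatement_cue_phase_s must be shorter than the session")
        object.__setattr__(self, "pr_ratio_series", series)

    def replace(self, **changes) -> "ProtocolConfig":
        """Return a copy with the given fields changed (re-validated)."""
        return dataclasses.replace(self, **changes)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["pr_ratio_series"] = list(d["pr_ratio_series"])
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=False), encoding="utf-8")

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(d) - known
        if bad:
            raise ConfigError(f"unknown protocol config keys: {sorted(bad)}")
        if "pr_ratio_series" in d:
            d = dict(d)
            d["pr_ratio_series"] = tuple(d["pr_ratio_series"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ProtocolConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(raw, dict):
            raise ConfigError(f"{path} does not contain a mapping")
        return cls.from_dict(raw)


DEFAULT_CONFIG = ProtocolConfig()
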