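"""Discrete-event engine for operant self-administration sessions.

The engine implements the contingency rules of the five session types:

* **FR** training: priming infusion at t=0; house light on for the first
  3 s; two 55-min active periods separated by a 15-min drug-free period
  (house light on, responses recorded but never reinforced); every
  ``fr_value``-th eligible active poke delivers an infusion paired with
  the cue light and a 10-s time-out (pokes during time-out recorded,
  never reinforced, never advancing the ratio); the session ends at the
  50th reinforcer or at 125 min, whichever comes first.
* **PR** (progressive ratio): the k-th infusion requires the k-th value
  of the ratio series since the previous infusion (time-out pokes
  excluded); the session ends at 4 h, when a full hour elapses with no
  poke on either hole (sliding window from the last poke, or from
  session start if no poke occurred), or when the series is exhausted.
* **SHOCK** (compulsivity test, 50 min): two-step FR2 — the first
  eligible active poke triggers a foot-shock; a second within 60 s
  triggers shock + infusion + cue; if the window lapses the next
  eligible poke restarts the two-step cycle (and itself draws a shock).
* **EXTINCTION** (2 h): no priming, no infusions, no cues; every poke
  recorded.
* **REINSTATEMENT** (90 min): first 60 min under extinction rules; from
  ``cue_phase_start`` every completed FR2 on the active hole presents
  the drug-paired cues (never the drug), followed by the usual time-out.

Agents supply poke decisions through :class:`AgentInterface`; the engine
works identically with scripted and stochastic agents. Because phase
transitions change the hazard of stochastic agents, the engine re-asks
the agent after every internal transition; agents must therefore answer
as a function of the elapsed time (scripted) or memorylessly
(exponential waits), both of which make the re-ask semantically neutral.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

from .config import ProtocolConfig
from .events import (ACTIVE_POKE, CUE_OFF, CUE_ON, CUE_PHASE_START,
                     DRUGFREE_END, DRUGFREE_START, HOUSE_LIGHT_OFF,
                     HOUSE_LIGHT_ON, INACTIVE_POKE, INFUSION,
                     PRIMING_INFUSION, SESSION_END, SHOCK, TIMEOUT_END,
                     TIMEOUT_START, Event, EventLog, quantize)
from .exceptions import ProtocolError

#: hole identifiers an agent may return
ACTIVE, INACTIVE, NONE = "active", "inactive", "none"

#: phases reported to agents
PHASE_ACTIVE = "active"          # reinforcement available (schedule permitting)
PHASE_TIMEOUT = "timeout"        # post-infusion time-out
PHASE_DRUGFREE = "drugfree"      # mid-session drug-free period
PHASE_PRE_CUE = "pre_cue"        # reinstatement before the cue phase
PHASE_CUE = "cue"                # reinstatement cue-available phase


@dataclass
class SessionSnapshot:
    """Read-only view of the schedule state passed to agents."""

    session_kind: str
    session_index: int           # caller-defined index within the session kind
    phase: str
    elapsed_s: float
    reinforcers: int
    shocks: int
    required_ratio: int | None   # current PR requirement, else None


@runtime_checkable
class AgentInterface(Protocol):
    """Contract for poke-decision sources consumed by the engine."""

    def next_action(self, state: SessionSnapshot, elapsed_s: float,
                    rng: np.random.Generator
                    ) -> tuple[float, str]:
        """Return ``(wait, hole)``: seconds until the next poke (> 0, may be
        ``inf``) and which hole (``"active"``/``"inactive"``/``"none"``)."""
        ...


# --------------------------------------------------------------------------

class _Runner:
    """One session run. Internal; use the run_*_session functions."""

    def __init__(self, kind: str, config: ProtocolConfig,
                 agent: AgentInterface, rng: np.random.Generator,
                 subject_id: str, session_id: str, session_index: int,
                 fr_value: int):
        config.validate()
        if not isinstance(agent, AgentInterface):
            raise ProtocolError("agent does not implement AgentInterface")
        self.kind = kind
        self.cfg = config
        self.agent = agent
        self.rng = rng
        self.session_index = session_index
        self.fr_value = fr_value
        self.log = EventLog(subject_id=subject_id, session_id=session_id,
                            session_kind=kind)
        self.t = 0.0
        self.timeout_until = -math.inf
        self.timeout_end_due: float | None = None
        self.ratio_count = 0
        self.ratio_idx = 0          # PR: index into the ratio series
        self.n_infusions = 0
        self.n_shocks = 0
        self.pending_first: float | None = None   # SHOCK: time of step-1 poke
        self.last_poke = 0.0
        # static schedule
        cfg = config
        if kind == "FR":
            self.end_time = cfg.session_cap_s
            self.drugfree = (cfg.active_period_s,
                             cfg.active_period_s + cfg.drugfree_period_s)
        else:
            self.end_time = {"PR": cfg.pr_cap_s,
                             "SHOCK": cfg.shock_session_s,
                             "EXTINCTION": cfg.extinction_session_s,
                             "REINSTATEMENT": cfg.reinstatement_total_s}[kind]
            self.drugfree = None
        self.cue_phase_at = (cfg.reinstatement_total_s
                             - cfg.reinstatement_cue_phase_s
                             if kind == "REINSTATEMENT" else None)
        self.schedule: list[tuple[float, str]] = [
            (cfg.house_light_start_s, "house_off")]
        if self.drugfree is not None:
            self.schedule += [(self.drugfree[0], "df_start"),
                              (self.drugfree[1], "df_end")]
        if self.cue_phase_at is not None:
            self.schedule.append((self.cue_phase_at, "cue_phase"))
        self.schedule.sort()
        self.end_reason = "cap"

    # -- helpers ----------------------------------------------------------

    def emit(self, t: float, etype: str, meta: dict | None = None) -> None:
        self.log.events.append(Event(quantize(t), etype, meta or {}))

    def in_timeout(self, t: float) -> bool:
        return t < self.timeout_until

    def in_drugfree(self, t: float) -> bool:
        return (self.drugfree is not None
                and self.drugfree[0] <= t < self.drugfree[1])

    def phase(self, t: float) -> str:
        if self.in_timeout(t):
            return PHASE_TIMEOUT
        if self.in_drugfree(t):
            return PHASE_DRUGFREE
        if self.cue_phase_at is not None:
            return PHASE_CUE if t >= self.cue_phase_at else PHASE_PRE_CUE
        return PHASE_ACTIVE

    def required_ratio(self) -> int | None:
        if self.kind != "PR":
            return None
        series = self.cfg.pr_ratio_series
        return series[min(self.ratio_idx, len(series) - 1)]

    def snapshot(self) -> SessionSnapshot:
        return SessionSnapshot(
            session_kind=self.kind, session_index=self.session_index,
            phase=self.phase(self.t), elapsed_s=self.t,
            reinforcers=self.n_infusions, shocks=self.n_shocks,
            required_ratio=self.required_ratio())

    def deliver_infusion(self, t: float, cues_only: bool = False) -> None:
        """Infusion (or, in reinstatement, cues alone) + cue pair + time-out."""
        if self.timeout_end_due is not None and self.timeout_end_due <= t:
            # a poke landing exactly at the end of the previous time-out can
            # itself be reinforced; close that time-out before opening a new one
            self.emit(self.timeout_end_due, TIMEOUT_END)
            self.timeout_end_due = None
        if not cues_only:
            self.n_infusions += 1
            self.emit(t, INFUSION)
        self.emit(t, CUE_ON)
        self.emit(t, CUE_OFF)            # cue light is off during the time-out
        self.emit(t, TIMEOUT_START)
        self.timeout_until = quantize(t + self.cfg.timeout_s)
        self.timeout_end_due = self.timeout_until

    def finish(self, t: float) -> None:
        meta = {"reason": self.end_reason,
                "n_infusions": str(self.n_infusions)}
        if self.kind == "FR":
            meta["fr_value"] = str(self.fr_value)
        if self.kind == "PR":
            series = self.cfg.pr_ratio_series
            last = series[self.ratio_idx - 1] if self.ratio_idx > 0 else 0
            meta["last_ratio"] = str(last)
        if self.kind == "SHOCK":
            meta["n_shocks"] = str(self.n_shocks)
        self.emit(t, SESSION_END, meta)

    # -- main loop --------------------------------------------------------

    def run(self) -> EventLog:
        cfg = self.cfg
        self.emit(0.0, HOUSE_LIGHT_ON)
        if self.kind in ("FR", "PR"):
            self.emit(0.0, PRIMING_INFUSION)
        while True:
            eff_end = self.end_time
            if self.kind == "PR":
                eff_end = min(eff_end, self.last_poke + cfg.pr_inactivity_s)
            wait, hole = self.agent.next_action(self.snapshot(), self.t,
                                                self.rng)
            if hole not in (ACTIVE, INACTIVE, NONE):
                raise ProtocolError(f"agent returned unknown hole {hole!r}")
            if hole == NONE or wait == math.inf:
                poke_t = math.inf
            else:
                if not wait > 0:
                    raise ProtocolError(
                        f"agent returned non-positive wait {wait!r}")
                poke_t = quantize(self.t + wait)
                if poke_t <= self.t:           # sub-millisecond wait
                    poke_t = quantize(self.t + 0.001)
            # Candidate internal events; ties resolved by listed priority.
            # Eligibility of a poke is decided by half-open time intervals,
            # not by processing order, so a poke wins every same-time tie
            # except against the hard session cap: a poke at exactly the cap
            # is lost, while one at exactly the end of a time-out, at a
            # phase boundary, or at the PR inactivity deadline (the poke
            # falls inside the half-open (t - pr_inactivity_s, t] window)
            # still counts. The final precedence sort orders the log.
            inactivity_end = self.kind == "PR" and eff_end < self.end_time
            candidates: list[tuple[float, int, str]] = []
            candidates.append((eff_end, 4 if inactivity_end else 0, "end"))
            candidates.append((poke_t, 1, "poke"))
            if self.schedule:
                candidates.append((self.schedule[0][0], 2, "sched"))
            if self.timeout_end_due is not None:
                candidates.append((self.timeout_end_due, 3, "timeout_end"))
            when, _, what = min(candidates)

            if what == "sched":
                _, tag = self.schedule.pop(0)
                self.t = when
                if tag == "house_off":
                    self.emit(when, HOUSE_LIGHT_OFF)
                elif tag == "df_start":
                    self.emit(when, DRUGFREE_START)
                    self.emit(when, HOUSE_LIGHT_ON)
                elif tag == "df_end":
                    self.emit(when, DRUGFREE_END)
                    self.emit(when, HOUSE_LIGHT_OFF)
                elif tag == "cue_phase":
                    self.emit(when, CUE_PHASE_START)
                    self.ratio_count = 0
                continue
            if what == "end":
                self.t = when
                if self.kind == "PR" and when < self.end_time:
                    self.end_reason = "inactivity"
                self.finish(when)
                break
            if what == "timeout_end":
                self.t = when
                self.emit(when, TIMEOUT_END)
                self.timeout_end_due = None
                continue
            # a poke
            self.t = poke_t
            self.handle_poke(poke_t, hole)
            if self.end_reason in ("max_reinforcers", "series_exhausted"):
                break
        self.log.sort()
        return self.log

    def handle_poke(self, t: float, hole: str) -> None:
        in_to = self.in_timeout(t)
        in_df = self.in_drugfree(t)
        meta: dict[str, str] = {}
        if in_to:
            meta["in_timeout"] = "1"
        if in_df:
            meta["in_drugfree"] = "1"
        self.emit(t, ACTIVE_POKE if hole == ACTIVE else INACTIVE_POKE, meta)
        self.last_poke = t
        if hole != ACTIVE or self.kind == "EXTINCTION":
            return
        if self.kind == "REINSTATEMENT":
            if t < self.cue_phase_at or in_to:
                return
            self.ratio_count += 1
            if self.ratio_count >= self.fr_value:
                self.ratio_count = 0
                self.deliver_infusion(t, cues_only=True)
            return
        if self.kind == "SHOCK":
            if in_to:
                return
            lapsed = (self.pending_first is not None
                      and t - self.pending_first
                      > self.cfg.shock_pair_window_s)
            self.emit(t, SHOCK)
            self.n_shocks += 1
            if self.pending_first is None or lapsed:
                self.pending_first = t      # (re)start the two-step cycle
            else:
                self.deliver_infusion(t)    # shock paired with the drug
                self.pending_first = None
            return
        # FR / PR reinforcement
        if in_to or in_df:
            return
        self.ratio_count += 1
        required = (self.fr_value if self.kind == "FR"
                    else self.cfg.pr_ratio_series[self.ratio_idx])
        if self.ratio_count >= required:
            self.ratio_count = 0
            self.deliver_infusion(t)
            if self.kind == "FR" and self.n_infusions >= self.cfg.max_reinforcers:
                self.end_reason = "max_reinforcers"
                self.finish(t)
            elif self.kind == "PR":
                self.ratio_idx += 1
                if self.ratio_idx >= len(self.cfg.pr_ratio_series):
                    self.end_reason = "series_exhausted"
                    self.finish(t)


# -- public API ------------------------------------------------------------

def _run(kind: str, config: ProtocolConfig, agent: AgentInterface,
         rng: np.random.Generator | None, *, subject_id: str,
         session_id: str, session_index: int, fr_value: int) -> EventLog:
    rng = np.random.default_rng(0) if rng is None else rng
    return _Runner(kind, config, agent, rng, subject_id, session_id,
                   session_index, fr_value).run()


def run_fr_session(config: ProtocolConfig, agent: AgentInterface,
                   rng: np.random.Generator | None = None, *,
                   subject_id: str = "s0", session_id: str = "fr",
                   session_index: int = 0) -> EventLog:
    """Run one fixed-ratio training session (FR1 or FR2 per ``config.fr_value``)."""
    return _run("FR", config, agent, rng, subject_id=subject_id,
                session_id=session_id, session_index=session_index,
                fr_value=config.fr_value)


def run_pr_session(config: ProtocolConfig, agent: AgentInterface,
                   rng: np.random.Generator | None = None, *,
                   subject_id: str = "s0", session_id: str = "pr",
                   session_index: int = 0) -> EventLog:
    """Run the progressive-ratio (motivation / breaking point) session."""
    return _run("PR", config, agent, rng, subject_id=subject_id,
                session_id=session_id, session_index=session_index,
                fr_value=1)


def run_shock_session(config: ProtocolConfig, agent: AgentInterface,
                      rng: np.random.Generator | None = None, *,
                      subject_id: str = "s0", session_id: str = "shock",
                      session_index: int = 0) -> EventLog:
    """Run the 50-min punished (compulsivity) session."""
    return _run("SHOCK", config, agent, rng, subject_id=subject_id,
                session_id=session_id, session_index=session_index,
                fr_value=2)


def run_extinction_session(config: ProtocolConfig, agent: AgentInterface,
                           rng: np.random.Generator | None = None, *,
                           subject_id: str = "s0",
                           session_id: str = "ext",
                           session_index: int = 0) -> EventLog:
    """Run one 2-h extinction session (no drug, no cues)."""
    return _run("EXTINCTION", config, agent, rng, subject_id=subject_id,
                session_id=session_id, session_index=session_index,
                fr_value=1)


def run_reinstatement_session(config: ProtocolConfig, agent: AgentInterface,
                              rng: np.random.Generator | None = None, *,
                              subject_id: str = "s0",
                              session_id: str = "reinstatement",
                              session_index: int = 0) -> EventLog:
    """Run the 90-min cue-induced reinstatement (drug-seeking) session."""
    return _run("REINSTATEMENT", config, agent, rng, subject_id=subject_id,
                session_id=session_id, session_index=session_index,
                fr_value=2)
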