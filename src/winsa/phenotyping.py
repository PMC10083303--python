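"""From event logs to addiction-criteria scores and subject classification.

The three addiction-like criteria are scored per subject:

* **persistence** — mean active pokes during the 15-min drug-free period
  over the three fixed-ratio days preceding the progressive-ratio test;
* **motivation** — the breaking point (last ratio completed) of the
  progressive-ratio session;
* **compulsivity** — total shocks received in the 50-min punished session.

Two craving-related parameters (active pokes in the first extinction
session; active pokes in the 90-min reinstatement session) and two
phenotypic traits (impulsivity = mean time-out active pokes, and reward
sensitivity = mean reinforcers, both over the three pre-PR FR2 days)
complete the per-subject profile.

A subject is positive for a criterion when its score is **equal to or
beyond the 75th percentile** of the reference-group distribution;
subjects meeting 2 or 3 criteria are classified *addicted* (vulnerable),
0 or 1 *non-addicted* (resilient).
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ProtocolConfig
from .events import (ACTIVE_POKE, CUE_PHASE_START, DRUGFREE_END,
                     DRUGFREE_START, INACTIVE_POKE, INFUSION, SESSION_END,
                     SHOCK, TIMEOUT_END, TIMEOUT_START, EventLog)
from .exceptions import ScoringError

CRITERIA = ("persistence", "motivation", "compulsivity")

ADDICTED, NON_ADDICTED = "addicted", "non_addicted"


# -- session summaries -----------------------------------------------------

@dataclass
class SessionSummary:
    subject_id: str
    session_id: str
    session_kind: str
    active_pokes: int = 0
    inactive_pokes: int = 0
    reinforcers: int = 0
    timeout_active_pokes: int = 0
    drugfree_active_pokes: int = 0
    shocks: int = 0
    last_ratio_completed: int = 0
    duration_s: float = 0.0
    fr_value: int | None = None            # FR sessions only
    cue_phase_active_pokes: int = 0        # reinstatement only


def summarize_session(log: EventLog, config: ProtocolConfig | None = None
                      ) -> SessionSummary:
    """Aggregate one event log into counts.

    A single forward scan tracks the open/closed state of the half-open
    time-out and drug-free intervals, so pokes sharing a timestamp with
    an interval boundary are attributed exactly as the engine treated
    them (the log's tie precedence orders boundary markers accordingly).
    """
    log.validate()
    s = SessionSummary(subject_id=log.subject_id, session_id=log.session_id,
                       session_kind=log.session_kind)
    in_timeout = False
    in_drugfree = False
    in_cue_phase = False
    for e in log.events:
        et = e.event_type
        if et == TIMEOUT_START:
            in_timeout = True
        elif et == TIMEOUT_END:
            in_timeout = False
        elif et == DRUGFREE_START:
            in_drugfree = True
        elif et == DRUGFREE_END:
            in_drugfree = False
        elif et == CUE_PHASE_START:
            in_cue_phase = True
        elif et == ACTIVE_POKE:
            s.active_pokes += 1
            if in_timeout:
                s.timeout_active_pokes += 1
            if in_drugfree:
                s.drugfree_active_pokes += 1
            if in_cue_phase:
                s.cue_phase_active_pokes += 1
        elif et == INACTIVE_POKE:
            s.inactive_pokes += 1
        elif et == INFUSION:
            s.reinforcers += 1
        elif et == SHOCK:
            s.shocks += 1
        elif et == SESSION_END:
            s.duration_s = e.t
            if "last_ratio" in e.meta:
                s.last_ratio_completed = int(e.meta["last_ratio"])
            if "fr_value" in e.meta:
                s.fr_value = int(e.meta["fr_value"])
    return s


# -- acquisition criterion -------------------------------------------------

@dataclass
class AcquisitionResult:
    passed: bool
    stable: bool
    discriminates: bool
    enough_reinforcers: bool
    max_relative_deviation: float
    active_fraction: float
    min_reinforcers: int


def check_acquisition(summaries: list[SessionSummary]) -> AcquisitionResult:
    """Evaluate the three acquisition conditions on 3 consecutive sessions.

    1. stability: each day's reinforcer count within 20% of the 3-day mean;
    2. discrimination: pooled active responding >= 75% of all pokes;
    3. a minimum of five reinforcers on each of the three days.
    """
    if len(summaries) != 3:
        raise ScoringError(
            f"acquisition check needs exactly 3 sessions, got {len(summaries)}")
    if len({s.subject_id for s in summaries}) != 1:
        raise ScoringError("acquisition sessions must share one subject")
    r = np.array([s.reinforcers for s in summaries], dtype=float)
    mean = r.mean()
    max_dev = float(np.max(np.abs(r - mean)) / mean) if mean > 0 else np.inf
    stable = mean > 0 and max_dev <= 0.20
    active = sum(s.active_pokes for s in summaries)
    inactive = sum(s.inactive_pokes for s in summaries)
    total = active + inactive
    frac = active / total if total > 0 else 0.0
    discriminates = total > 0 and frac >= 0.75
    min_r = int(r.min())
    enough = min_r >= 5
    return AcquisitionResult(
        passed=bool(stable and discriminates and enough),
        stable=bool(stable), discriminates=bool(discriminates),
        enough_reinforcers=bool(enough),
        max_relative_deviation=max_dev, active_fraction=frac,
        min_reinforcers=min_r)


# -- criterion scores ------------------------------------------------------

@dataclass
class CriterionScores:
    subject_id: str
    group: str = ""
    persistence: float = np.nan
    motivation: float = np.nan
    compulsivity: float = np.nan
    impulsivity: float = np.nan
    reward_sensitivity: float = np.nan
    resistance_to_extinction: float | None = None
    drug_seeking: float | None = None
    drug_seeking_cue_phase: float | None = None


def compute_scores(summaries: list[SessionSummary], group: str = ""
                   ) -> CriterionScores:
    """Score one subject from its ordered session summaries.

    Requires >= 3 FR2 sessions before the PR session, one PR and one
    shock session; extinction and reinstatement sessions are optional
    and their absence leaves the craving fields ``None`` (not zero).
    """
    if not summaries:
        raise ScoringError("no sessions supplied")
    subject = summaries[0].subject_id
    if any(s.subject_id != subject for s in summaries):
        raise ScoringError("sessions from more than one subject")
    kinds = [s.session_kind for s in summaries]
    missing = []
    pr_idx = kinds.index("PR") if "PR" in kinds else None
    if pr_idx is None:
        missing.append("PR session")
        pre_fr2: list[SessionSummary] = []
    else:
        pre_fr2 = [s for s in summaries[:pr_idx]
                   if s.session_kind == "FR" and s.fr_value == 2]
        if len(pre_fr2) < 3:
            missing.append(f"3 FR2 sessions before the PR (found {len(pre_fr2)})")
    shock = next((s for s in summaries if s.session_kind == "SHOCK"), None)
    if shock is None:
        missing.append("shock session")
    if missing:
        raise ScoringError(f"subject {subject}: missing {'; '.join(missing)}")

    last3 = pre_fr2[-3:]
    scores = CriterionScores(subject_id=subject, group=group)
    scores.persistence = float(np.mean(
        [s.drugfree_active_pokes for s in last3]))
    scores.impulsivity = float(np.mean(
        [s.timeout_active_pokes for s in last3]))
    scores.reward_sensitivity = float(np.mean([s.reinforcers for s in last3]))
    scores.motivation = float(summaries[pr_idx].last_ratio_completed)
    scores.compulsivity = float(shock.shocks)
    ext = [s for s in summaries if s.session_kind == "EXTINCTION"]
    if ext:
        scores.resistance_to_extinction = float(ext[0].active_pokes)
    rein = next((s for s in summaries
                 if s.session_kind == "REINSTATEMENT"), None)
    if rein is not None:
        scores.drug_seeking = float(rein.active_pokes)
        scores.drug_seeking_cue_phase = float(rein.cue_phase_active_pokes)
    return scores


# -- thresholds and classification ----------------------------------------

@dataclass
class Thresholds:
    persistence: float
    motivation: float
    compulsivity: float
    method: str
    reference_group: str
    reference_n: int

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.persistence, self.motivation, self.compulsivity)


def percentile_75(values, method: str = "empirical") -> float:
    """75th percentile of a reference score distribution.

    ``empirical`` interpolates linearly between order statistics (the
    common "type 7" convention). ``normal`` instead fits a Gaussian and
    returns mean + z(0.75) * sd, the parametric reading of a percentile
    of "the normal distribution" of the reference group.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ScoringError("empty reference sample")
    if method == "empirical":
        return float(np.percentile(x, 75))
    if method == "normal":
        z75 = 0.6744897501960817
        return float(x.mean() + z75 * x.std(ddof=1))
    raise ScoringError(f"unknown percentile method {method!r}")


def compute_thresholds(reference: list[CriterionScores],
                       method: str = "empirical",
                       reference_group: str = "") -> Thresholds:
    """Per-criterion 75th-percentile thresholds from the reference group."""
    if not reference:
        raise ScoringError("reference group is empty")
    if len(reference) < 4:
        warnings.warn(
            f"only {len(reference)} reference subjects; the 75th percentile "
            "is poorly resolved", stacklevel=2)
    vals = {c: [getattr(s, c) for s in reference] for c in CRITERIA}
    for c, v in vals.items():
        if any(not np.isfinite(x) for x in v):
            raise ScoringError(f"non-finite {c} score in reference group")
    return Thresholds(
        persistence=percentile_75(vals["persistence"], method),
        motivation=percentile_75(vals["motivation"], method),
        compulsivity=percentile_75(vals["compulsivity"], method),
        method=method, reference_group=reference_group,
        reference_n=len(reference))


@dataclass
class ClassificationResult:
    subject_id: str
    criterion_flags: tuple[bool, bool, bool]
    n_criteria: int
    label: str
    thresholds_used: tuple[float, float, float]
    reference_group: str


def classify(scores: CriterionScores, thresholds: Thresholds
             ) -> ClassificationResult:
    """Apply the 2-of-3 rule: flags are 'equal to or beyond' the threshold."""
    values = (scores.persistence, scores.motivation, scores.compulsivity)
    if any(not np.isfinite(v) for v in values):
        raise ScoringError(
            f"subject {scores.subject_id}: criterion score absent")
    flags = tuple(bool(v >= thr)
                  for v, thr in zip(values, thresholds.as_tuple()))
    n = sum(flags)
    return ClassificationResult(
        subject_id=scores.subject_id, criterion_flags=flags, n_criteria=n,
        label=ADDICTED if n >= 2 else NON_ADDICTED,
        thresholds_used=thresholds.as_tuple(),
        reference_group=thresholds.reference_group)


# -- extinction criterion --------------------------------------------------

def check_extinction(baseline: list[float], extinction_counts: list[float]
                     ) -> tuple[bool, int | None]:
    """Extinction is reached on the third of the first run of 3 consecutive
    sessions each with active pokes strictly below 35% of the baseline mean
    (baseline = active pokes on the last 3 self-administration days).

    Returns ``(reached, session_reached)`` with a 1-based session index.
    """
    if len(baseline) != 3:
        raise ScoringError("baseline must contain exactly 3 session counts")
    mean = float(np.mean(baseline))
    if mean <= 0:
        raise ScoringError("extinction criterion undefined for zero baseline")
    cutoff = 0.35 * mean
    run = 0
    for i, c in enumerate(extinction_counts):
        run = run + 1 if c < cutoff else 0
        if run == 3:
            return True, i + 1
    return False, None


# -- tabular export --------------------------------------------------------

SCORES_COLUMNS = ["subject_id", "group", "persistence", "motivation",
                  "compulsivity", "impulsivity", "reward_sensitivity",
                  "resistance_to_extinction", "drug_seeking",
                  "drug_seeking_cue_phase", "n_criteria", "label"]


def scores_to_frame(scores: list[CriterionScores],
                    results: list[ClassificationResult] | None = None
                    ) -> pd.DataFrame:
    """Per-subject scores (+ optional classification) as a DataFrame.

    Missing optional fields stay as NA and serialize to empty CSV cells.
    """
    rows = []
    by_id = {r.subject_id: r for r in (results or [])}
    for s in scores:
        row = dataclasses.asdict(s)
        cls = by_id.get(s.subject_id)
        row["n_criteria"] = cls.n_criteria if cls else pd.NA
        row["label"] = cls.label if cls else pd.NA
        rows.append(row)
    df = pd.DataFrame(rows)
    return df[[c for c in SCORES_COLUMNS if c in df.columns]]
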