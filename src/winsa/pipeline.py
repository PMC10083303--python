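"""End-to-end orchestration: simulate a cohort through the full protocol,
phenotype the resulting event logs, and run the statistical analyses.

The full protocol sequence per subject is 5 FR1 + 5 FR2 training
sessions, the progressive-ratio test, one FR2 stabilizer, the 50-min
shock test, 10 extinction sessions and the cue-induced reinstatement
session (24 sessions). Every stage is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agents import (CohortSpec, TraitAgent, TraitProfile, cohort_to_frame,
                     sample_cohort)
from .config import ProtocolConfig
from .engine import (run_extinction_session, run_fr_session, run_pr_session,
                     run_reinstatement_session, run_shock_session)
from .events import EventLog, read_event_log, write_event_log
from .exceptions import ScoringError
from .phenotyping import (ADDICTED, ClassificationResult, CriterionScores,
                          SessionSummary, check_acquisition, classify,
                          compute_scores, compute_thresholds, scores_to_frame,
                          summarize_session)
from .stats import (chi_square_2x2, compare_groups, pca_varimax,
                    pearson_correlation_matrix)

log = logging.getLogger("winsa")

#: protocol phases in order; each expands to one or more sessions
PHASES = ("fr1", "fr2", "pr", "stabilizer", "shock", "extinction",
          "reinstatement")

SCORE_VARIABLES = ["persistence", "motivation", "compulsivity",
                   "resistance_to_extinction", "drug_seeking",
                   "impulsivity", "reward_sensitivity"]


def protocol_sessions(config: ProtocolConfig,
                      phases: tuple[str, ...] = PHASES
                      ) -> list[dict]:
    """Ordered session plan. Each entry: kind, session_id, fr_value,
    kind_index (training index for FR learning, extinction day, ...)."""
    plan: list[dict] = []
    fr_idx = 0
    if "fr1" in phases:
        for _ in range(config.n_fr1_sessions):
            plan.append({"kind": "FR", "fr_value": 1, "kind_index": fr_idx})
            fr_idx += 1
    else:
        fr_idx = config.n_fr1_sessions
    if "fr2" in phases:
        for _ in range(config.n_fr2_sessions):
            plan.append({"kind": "FR", "fr_value": 2, "kind_index": fr_idx})
            fr_idx += 1
    if "pr" in phases:
        plan.append({"kind": "PR", "fr_value": 1, "kind_index": fr_idx})
    if "stabilizer" in phases:
        plan.append({"kind": "FR", "fr_value": 2, "kind_index": fr_idx})
    if "shock" in phases:
        plan.append({"kind": "SHOCK", "fr_value": 2, "kind_index": fr_idx})
    if "extinction" in phases:
        for d in range(config.n_extinction_sessions):
            plan.append({"kind": "EXTINCTION", "fr_value": 1, "kind_index": d})
    if "reinstatement" in phases:
        plan.append({"kind": "REINSTATEMENT", "fr_value": 2, "kind_index": 0})
    for i, entry in enumerate(plan):
        tag = entry["kind"].lower()
        if entry["kind"] == "FR":
            tag = f"fr{entry['fr_value']}"
        entry["session_id"] = f"{i:02d}_{tag}"
    return plan


_RUNNERS = {"FR": run_fr_session, "PR": run_pr_session,
            "SHOCK": run_shock_session, "EXTINCTION": run_extinction_session,
            "REINSTATEMENT": run_reinstatement_session}


def run_subject_protocol(profile: TraitProfile, config: ProtocolConfig,
                         rng: np.random.Generator,
                         phases: tuple[str, ...] = PHASES
                         ) -> list[EventLog]:
    """Simulate one subject through the protocol, one agent per session."""
    logs = []
    for entry in protocol_sessions(config, phases):
        kind = entry["kind"]
        agent = TraitAgent(profile, kind, kind_index=entry["kind_index"],
                           n_extinction_before=config.n_extinction_sessions)
        cfg = config.replace(fr_value=entry["fr_value"]) \
            if kind == "FR" else config
        logs.append(_RUNNERS[kind](
            cfg, agent, rng, subject_id=profile.subject_id,
            session_id=entry["session_id"],
            session_index=entry["kind_index"]))
    return logs


# -- simulate --------------------------------------------------------------

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def simulate_cohort(spec: CohortSpec, config: ProtocolConfig,
                    out_dir: str | Path, seed: int | None = None,
                    phases: tuple[str, ...] = PHASES) -> dict:
    """Sample a cohort, run the full protocol, write one event-log CSV per
    subject-session plus the ground-truth table and a run manifest."""
    t0 = time.perf_counter()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seed is not None:
        spec = dataclasses.replace(spec, seed=seed)
    profiles = sample_cohort(spec)
    root_ss = np.random.SeedSequence(spec.seed)
    files = []
    for profile, child in zip(profiles, root_ss.spawn(len(profiles))):
        rng = np.random.default_rng(child)
        for elog in run_subject_protocol(profile, config, rng, phases):
            path = out / f"{profile.subject_id}__{elog.session_id}.csv"
            write_event_log(elog, path)
            files.append(path)
    truth = cohort_to_frame(profiles)
    truth_path = out / "ground_truth.csv"
    truth.to_csv(truth_path, index=False)
    files.append(truth_path)
    config_path = out / "protocol_config.yaml"
    config.to_yaml(config_path)
    files.append(config_path)
    manifest = {
        "package_version": __version__,
        "seed": spec.seed,
        "n_subjects": spec.n_subjects,
        "phases": list(phases),
        "created_unix": time.time(),
        "checksums": {f.name: _sha256(f) for f in sorted(files)},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2),
                                       encoding="utf-8")
    log.info("simulate: %d subjects, %d files, %.1f s", len(profiles),
             len(files), time.perf_counter() - t0)
    return manifest


# -- phenotype -------------------------------------------------------------

@dataclass
class PhenotypeReport:
    scores: list[CriterionScores]
    classifications: list[ClassificationResult]
    thresholds: object
    exclusions: dict[str, str]            # subject_id -> reason
    table: pd.DataFrame


def load_event_logs(log_dir: str | Path) -> dict[str, list[EventLog]]:
    """Read all per-session CSVs in a directory, grouped and ordered by
    the zero-padded session index embedded in the file name."""
    logs: dict[str, list[EventLog]] = {}
    for path in sorted(Path(log_dir).glob("*__*.csv")):
        elog = read_event_log(path)
        logs.setdefault(elog.subject_id, []).append(elog)
    return logs


def phenotype_cohort(logs_by_subject: dict[str, list[EventLog]],
                     config: ProtocolConfig,
                     groups: dict[str, str] | None = None,
                     dropouts: set[str] | None = None,
                     reference_group: str | None = "saline",
                     threshold_method: str = "empirical") -> PhenotypeReport:
    """Score, filter and classify a cohort of event logs.

    Subjects flagged as dropouts (failed catheter patency) or failing the
    acquisition criteria on the three pre-PR FR2 sessions are excluded
    before thresholds are computed. Thresholds come from the designated
    reference group, or from the whole classified population when
    ``reference_group`` is None or absent from the data.
    """
    groups = groups or {}
    dropouts = dropouts or set()
    scores: list[CriterionScores] = []
    exclusions: dict[str, str] = {}
    for subject, logs in logs_by_subject.items():
        if subject in dropouts:
            exclusions[subject] = "catheter patency failure"
            continue
        summaries = [summarize_session(l, config) for l in logs]
        try:
            subj_scores = compute_scores(summaries,
                                         group=groups.get(subject, ""))
        except ScoringError as err:
            exclusions[subject] = str(err)
            continue
        pr_idx = [s.session_kind for s in summaries].index("PR")
        pre_fr2 = [s for s in summaries[:pr_idx]
                   if s.session_kind == "FR" and s.fr_value == 2][-3:]
        acq = check_acquisition(pre_fr2)
        if not acq.passed:
            reasons = [name for ok, name in [
                (acq.stable, "stability"),
                (acq.discriminates, "discrimination"),
                (acq.enough_reinforcers, "min reinforcers")] if not ok]
            exclusions[subject] = f"acquisition failed ({', '.join(reasons)})"
            continue
        scores.append(subj_scores)
    if not scores:
        raise ScoringError("no subjects survived exclusion")
    reference = [s for s in scores if s.group == reference_group]
    if not reference:
        reference = scores
        reference_group = "all"
    thresholds = compute_thresholds(reference, method=threshold_method,
                                    reference_group=str(reference_group))
    classifications = [classify(s, thresholds) for s in scores]
    return PhenotypeReport(scores=scores, classifications=classifications,
                           thresholds=thresholds, exclusions=exclusions,
                           table=scores_to_frame(scores, classifications))


# -- analyze ---------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="split"))
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def analyze_scores(table: pd.DataFrame, out_dir: str | Path | None = None,
                   figures: bool = True) -> dict:
    """Population-level analysis of a per-subject scores table.

    Produces treatment-group and addicted/non-addicted comparisons for
    every score, a chi-square on addiction prevalence, criterion versus
    n_criteria correlations, the 7-variable Pearson correlation matrix
    (overall and per classification label where sample size allows),
    and the varimax-rotated PCA.
    """
    report: dict = {"n_subjects": int(len(table))}
    variables = [v for v in SCORE_VARIABLES if v in table.columns]
    groups = sorted(g for g in table["group"].dropna().unique() if g != "")

    if len(groups) == 2:
        g1 = table[table["group"] == groups[0]]
        g2 = table[table["group"] == groups[1]]
        comps = {}
        for v in variables:
            x, y = g1[v].dropna(), g2[v].dropna()
            if len(x) >= 3 and len(y) >= 3:
                comps[v] = _jsonable(compare_groups(x, y))
        report["group_comparisons"] = {"groups": groups, "tests": comps}
        tab = pd.crosstab(table["group"], table["label"] == ADDICTED)
        if tab.shape == (2, 2) and (tab.to_numpy() >= 0).all() \
                and (tab.sum(0) > 0).all() and (tab.sum(1) > 0).all():
            stat, p = chi_square_2x2(tab.to_numpy())
            report["addiction_prevalence_chi2"] = {
                "table": tab.to_numpy().tolist(), "statistic": stat, "p": p}
    else:
        log.warning("fewer than 2 treatment groups: group tests skipped")

    addicted = table[table["label"] == ADDICTED]
    non_add = table[table["label"] != ADDICTED]
    if len(addicted) >= 3 and len(non_add) >= 3:
        report["addicted_vs_non"] = {
            v: _jsonable(compare_groups(addicted[v].dropna(),
                                        non_add[v].dropna()))
            for v in variables
            if addicted[v].notna().sum() >= 3
            and non_add[v].notna().sum() >= 3}

    if "n_criteria" in table.columns:
        crit_corr = {}
        for v in ("persistence", "motivation", "compulsivity"):
            sub = table[[v, "n_criteria"]].dropna()
            if len(sub) >= 3 and sub[v].nunique() > 1 \
                    and sub["n_criteria"].nunique() > 1:
                from scipy import stats as sps
                res = sps.pearsonr(sub[v], sub["n_criteria"])
                crit_corr[v] = {"r": float(res.statistic),
                                "p": float(res.pvalue)}
        report["criterion_vs_n_criteria"] = crit_corr

    corr = pearson_correlation_matrix(table[variables])
    report["correlations"] = {"overall": _jsonable(corr)}
    for lbl, sub in table.groupby("label", observed=True):
        if len(sub) >= 4:
            report["correlations"][str(lbl)] = _jsonable(
                pearson_correlation_matrix(sub[variables]))

    complete = table[variables].dropna()
    if len(complete) >= len(variables) + 2:
        pca = pca_varimax(complete)
        report["pca"] = _jsonable(pca)
    else:
        pca = None
        log.warning("too few complete subjects for PCA")

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "stats_report.json").write_text(
            json.dumps(_jsonable(report), indent=2), encoding="utf-8")
        corr.r.to_csv(out / "correlation_r.csv")
        corr.p.to_csv(out / "correlation_p.csv")
        if pca is not None:
            pca.loadings.to_csv(out / "pca_loadings.csv")
        if figures:
            _write_figures(corr, pca, out)
    return report


def _write_figures(corr, pca, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(corr.r.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(corr.variables)))
    ax.set_xticklabels(corr.variables, rotation=45, ha="right")
    ax.set_yticks(range(len(corr.variables)))
    ax.set_yticklabels(corr.variables)
    fig.colorbar(im, ax=ax, label="Pearson r")
    ax.set_title("Correlation heatmap")
    fig.tight_layout()
    fig.savefig(out / "correlation_heatmap.png", dpi=150)
    plt.close(fig)

    if pca is not None:
        k = pca.retained_components
        fig, axes = plt.subplots(1, k, figsize=(4 * k, 4), squeeze=False)
        for j in range(k):
            ax = axes[0, j]
            col = pca.loadings.iloc[:, j].sort_values()
            ax.barh(range(len(col)), col.to_numpy())
            ax.set_yticks(range(len(col)))
            ax.set_yticklabels(col.index)
            ax.axvline(0.7, ls="--", c="k", lw=0.8)
            ax.set_title(f"{pca.loadings.columns[j]} "
                         f"({pca.explained_variance_pct[j]:.1f}% var)")
        fig.tight_layout()
        fig.savefig(out / "pca_loadings.png", dpi=150)
        plt.close(fig)
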