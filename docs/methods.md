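# Methods

## Scope and design

`winsa` models the *behavioral* layer of a mouse cannabinoid
self-administration protocol: schedules, contingencies, event logging,
criterion scoring, classification and statistics. It deliberately
excludes pharmacokinetics (doses are metadata), hardware file formats,
and any surgical or chemogenetic manipulation. Inputs are either
synthetic event logs from the cohort simulator or user-supplied logs in
the package's CSV event-log format.

## Session engine

The engine is a discrete-event scheduler driven by an agent that
returns `(wait, hole)` decisions. Time is continuous seconds
internally, quantized to milliseconds at event creation so that logs
serialize (3-decimal timestamps, LF endings) and round-trip bit-exactly.

Contingency rules per session type:

- **FR** (125 min cap): priming infusion at t = 0 (logged as its own
  event type; it never counts toward the 50-reinforcer cap or any
  score, being non-contingent); house light on for the first 3 s and
  during the drug-free period; every `fr_value`-th *eligible* active
  poke triggers infusion + cue + 10-s time-out. Pokes during time-out
  or the drug-free period (default [3300 s, 4200 s)) are logged with
  flags but never reinforced and do not advance the ratio counter —
  counting them would make the time-out meaningless. The session ends
  at the 50th reinforcer or the cap, whichever is first.
- **PR** (4 h cap): the k-th infusion requires the k-th series value of
  eligible active pokes since the previous infusion. Stopping rules:
  cap; series exhaustion; or a sliding inactivity window — the session
  ends at the first instant `t` with no poke on either hole in
  `(t - 1 h, t]`. The breaking point (last ratio completed) is recorded
  in the `session_end` metadata.
- **SHOCK** (50 min): two-step FR2. First eligible active poke: shock.
  Second within 60 s (inclusive): shock + infusion + cue + time-out.
  If the window lapses, the next eligible poke restarts the cycle and
  itself draws a shock. The "different operant box" of the original
  procedure has no behavioral consequence here and is not modeled.
- **EXTINCTION** (2 h): no priming, no infusion, no cues; everything
  logged.
- **REINSTATEMENT** (90 min): extinction rules for 60 min; from
  `cue_phase_start`, completed FR2 sequences on the active hole present
  the cues only (never drug), with the usual time-out. Pokes before the
  phase boundary never advance the ratio.

**Tie-breaking.** Events sharing a timestamp sort by a fixed
precedence: phase transitions and `timeout_end` first, then priming,
pokes, shock, infusion, cue on/off, `timeout_start`, and `session_end`
always last. Intervals are half-open `[start, end)`; a poke at exactly
`timeout_end` is eligible for reinforcement. Placing `timeout_end`
*before* coincident pokes (rather than grouping all time-out markers
after cue events) is required for a single forward scan of the log to
classify boundary pokes exactly as the engine did; it is the one place
where self-consistency forced a specific precedence choice.

**Re-asking.** After every internal transition the engine discards the
agent's pending decision and asks again. Scripted agents answer as a
pure function of elapsed time; stochastic agents use exponential
(memoryless) waits, so the re-ask leaves their law unchanged. A poke
wins every same-time tie except against the hard session cap (a poke at
exactly the cap is lost; a poke at exactly the PR inactivity deadline
falls inside the half-open window and keeps the session alive).

**Edge cases.** The drug-free period is consumed, never paused: the
session ends strictly by the two printed rules (cap time or reinforcer
count). The cue light's off-time during the time-out is represented by
emitting `cue_off` at `timeout_start` (cue duration is not otherwise
specified). Agents returning non-positive waits raise a protocol error;
a zero-hazard agent returns an infinite-wait sentinel and the session
runs to its scheduled end.

## Synthetic cohorts

`TraitAgent` is a renewal process: total poke hazard =
active + inactive hazard, hole chosen proportionally, waits exponential.
The active hazard (pokes/min) is assembled multiplicatively:

| trait | role | default (resilient / vulnerable) |
|---|---|---|
| `base_active_rate` | baseline active hazard | LogN(ln 0.35, 0.25) / LogN(ln 0.60, 0.25) |
| `base_inactive_rate` | inactive hazard | LogN(ln 0.08, 0.5) both |
| `learning_gain` | asymptote of the saturating acquisition curve `g - (g-1)e^{-s/2}` over FR training sessions *s* | LogN(ln 2.0, 0.2) / LogN(ln 2.2, 0.2) |
| `impulsivity` | multiplier during time-outs | LogN(ln 0.8, 0.3) / LogN(ln 3.0, 0.3) |
| `perseverance` | multiplier during the drug-free period | LogN(ln 0.30, 0.3) / LogN(ln 1.2, 0.3) |
| `motivation` | hard give-up threshold on the PR requirement | choice{5..33} / choice{75..180} |
| `shock_tolerance` | P(continue) per shock received | U(0.30, 0.60) / U(0.88, 0.98) |
| `extinction_decay` | per-session hazard decay `e^{-δ·day}` without reinforcement | LogN(ln 0.35, 0.2) / LogN(ln 0.22, 0.2) |
| `burst_gain` | extra hazard on extinction day 1 (extinction burst) | LogN(ln 1.6, 0.15) / LogN(ln 2.2, 0.15) |
| `cue_gain` | extra hazard in the reinstatement cue phase | LogN(ln 1.3, 0.2) / LogN(ln 2.0, 0.2) |

Design choices: exponential inter-poke intervals keep every oracle
check analytic; the PR give-up is a hard threshold rather than a
stochastic softmax so breaking-point recovery is exact; acquisition
learning is a saturating per-session multiplier so early FR1 sessions
show a progressive increase in active responding. The default cohort is
60 subjects, 30% vulnerable, two treatment-style groups assigned
50/50, and a 3% catheter-failure (dropout) rate. No empirical
response-rate statistics exist to calibrate against, so the magnitudes
are nominal; the *separations* between phenotypes are what the defaults
encode, mirroring the finding that compulsivity-type measures separate
addicted from non-addicted subjects.

What the simulator does **not** emulate: within-session satiation or
drug accumulation, circadian or inter-day variability beyond the
learning curve, response bursts/pauses (non-exponential interval
structure), or any interaction between traits and treatment group.
Passing recovery tests therefore shows the pipeline's statistical
machinery is sound under the stated generative assumptions — not that
real mice satisfy them.

## Phenotyping

Summaries are derived from events alone by one forward scan (interval
flags from the boundary markers). Scores: persistence and impulsivity
are **means** over the three FR2 sessions immediately preceding the PR
(an aggregator consistent with the reward-sensitivity definition, which
is explicitly a mean over the same window); motivation is the PR
breaking point; compulsivity the shock count; resistance to extinction
the first extinction session's active pokes; drug seeking the active
pokes over the whole 90-min reinstatement session, with the 30-min
cue-phase count exported alongside. Missing optional sessions yield
absent (None/empty) values, never zero. Reward sensitivity uses the
same pre-PR window as the other two trait scores ("the last three
consecutive FR2 conditioning sessions"), not the post-PR stabilizer.

Acquisition requires, over three consecutive sessions: every day's
reinforcer count within 20% of the 3-day mean ("80% stability"), pooled
active responding ≥ 75%, and ≥ 5 reinforcers each day. Subjects failing
acquisition or flagged as catheter dropouts are excluded *before*
thresholds are computed.

Thresholds are the 75th percentile of the reference group's empirical
score distribution with linear interpolation between order statistics
(NumPy's default, the "type 7" convention). Because the source
procedure invokes the percentile "of the normal distribution" of the
reference group without a parametric recipe, a Gaussian alternative
(mean + 0.6745·SD) is available behind `threshold_method="normal"`.
The reference group defaults to the designated control ("saline")
group and is configurable, including thresholding within each group —
descriptions of the procedure support either reading, so both are
implemented and neither is presented as definitive. Flags use ≥
("equal to or beyond"); 2-of-3 flags ⇒ addicted.

The extinction criterion is strict: reached when three *consecutive*
extinction sessions each fall below 35% of the mean of the last three
self-administration days (a count equal to 35% of baseline does not
qualify). A zero baseline makes the criterion undefined and raises.

## Statistics

- Normality gate: Lilliefors-form Kolmogorov-Smirnov (estimated mean
  and SD) at α = 0.05; samples with n < 4 or zero variance are treated
  as non-normal. Both samples normal ⇒ Student's t (equal variances);
  otherwise two-sided Mann-Whitney U, reported as min(U1, U2), exact
  when both n ≤ 12 without ties, normal approximation with tie
  correction otherwise. SPSS provenance is matched in convention, not
  bit-exactly.
- Chi-square: Pearson, df = 1, no continuity correction by default
  (Yates available by flag).
- Pearson correlations: pairwise-complete, two-sided p, pairs with
  n < 3 or zero variance reported absent. No multiple-testing
  correction anywhere (matching the analysis style being modeled; a
  caveat, not an endorsement).
- Repeated-measures ANOVA: balanced two-way mixed design (between =
  group, within = session) by direct sums-of-squares decomposition;
  F(group) against subjects-within-groups, F(session) and
  F(interaction) against the within error. Zero-variance data yield
  F = 0, p = 1 by convention. Fisher LSD: unadjusted pairwise t-tests
  on cell means, using the within error term for same-group
  comparisons and the between-subject error term otherwise. Verified
  against an independent mixed-ANOVA implementation in the test suite.
- PCA: z-scored variables, eigendecomposition of the correlation
  matrix, eigenvalue > 1 retention (at least one component kept),
  loadings = eigenvectors × √eigenvalues. Varimax is the SVD-update
  algorithm with Kaiser normalization, tolerance 1e-8, ≤ 1000 sweeps;
  rotation is orthogonal so per-variable communalities are preserved
  (checked to 1e-9). Components are sign-fixed so the
  largest-magnitude loading is positive. Explained-variance
  percentages are reported from the unrotated eigenvalues; post-
  rotation sums of squared loadings are exported as well, since either
  convention may be wanted when comparing to published variance
  figures. Variables with |loading| > 0.7 are the annotated "main
  contributors" of a component.

## Determinism and problem sizes

Every stochastic path flows from one integer seed through
`numpy.random.SeedSequence` spawning (one child per subject), so
simulate → phenotype → analyze reproduces identical output files and
checksums. The shipped recovery analysis uses 20 seeds × 60 subjects
through the full 24-session protocol (a few seconds per seed); the
acceptance script's quantities are all scripted-agent worked examples
and boundary probes that run in under a minute in total.

## Known limitations

- The agent model is memoryless; burst-pause microstructure and
  within-session dynamics are absent by design.
- Acquisition-failure exclusions depend on the synthetic rates (about
  5–15% of a default cohort); real attrition structure is unknown.
- The mixed ANOVA requires complete, balanced data (no imputation).
- The Mann-Whitney exact path is only used without ties; tied small
  samples fall back to the corrected normal approximation.
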