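"""Statistical layer: normality-gated two-group tests, chi-square,
Pearson correlation matrices, mixed-design repeated-measures ANOVA with
Fisher LSD post hoc, and PCA with varimax rotation.

Conventions follow common practice for behavioral data analyzed in SPSS:
the two-group test is Student's t when both samples pass a
Kolmogorov-Smirnov normality check (Lilliefors form, i.e. with estimated
mean and SD) and the Mann-Whitney U otherwise, with U reported as the
smaller of U1/U2; the 2x2 chi-square is Pearson's without continuity
correction unless requested; PCA retains components with eigenvalue > 1
from the correlation matrix and rotates the retained loadings with
Kaiser-normalized varimax.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

from .exceptions import StatsError


# -- two-group comparison --------------------------------------------------

@dataclass
class GroupComparison:
    test_name: str                 # "student_t" | "mann_whitney_u"
    statistic: float
    p_value: float
    n1: int
    n2: int
    normality_p_values: tuple[float, float]


def _normality_p(x: np.ndarray) -> float:
    """Lilliefors-style KS normality p-value; degenerate samples -> 0."""
    if len(x) < 4 or np.ptp(x) == 0:
        return 0.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, p = lilliefors(x, dist="norm")
    return float(p)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; U is the smaller of U1 and U2.

    Exact null distribution when both n <= 12 and there are no ties,
    normal approximation with tie correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    method = "exact" if (len(x) <= 12 and len(y) <= 12 and not ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = min(u1, len(x) * len(y) - u1)
    return u, float(res.pvalue)


def compare_groups(x, y, alpha_normality: float = 0.05) -> GroupComparison:
    """Student's t if both samples pass the KS normality gate, else U test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise StatsError("need at least 2 observations per group")
    degenerate = np.ptp(x) == 0 or np.ptp(y) == 0
    if degenerate:
        warnings.warn("zero-variance sample routed to Mann-Whitney U",
                      stacklevel=2)
    p_norm = (_normality_p(x), _normality_p(y))
    if not degenerate and min(p_norm) >= alpha_normality:
        stat, p = sps.ttest_ind(x, y, equal_var=True)
        if np.allclose(x.mean(), y.mean()) and np.isnan(p):
            stat, p = 0.0, 1.0     # identical constant samples
        return GroupComparison("student_t", float(stat), float(p),
                               len(x), len(y), p_norm)
    u, p = mann_whitney_u(x, y)
    return GroupComparison("mann_whitney_u", u, p, len(x), len(y), p_norm)


# -- chi-square ------------------------------------------------------------

def chi_square_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 count table, df = 1.

    Continuity (Yates) correction is off by default and available by flag.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise StatsError(f"expected a 2x2 table, got shape {t.shape}")
    if (t < 0).any():
        raise StatsError("counts must be non-negative")
    if (t.sum(axis=0) <= 0).any() or (t.sum(axis=1) <= 0).any():
        raise StatsError("both margins must be positive")
    stat, p, _, _ = sps.chi2_contingency(t, correction=correction)
    return float(stat), float(p)


# -- correlations ----------------------------------------------------------

@dataclass
class CorrelationMatrix:
    variables: list[str]
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame


def pearson_correlation_matrix(data: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise-complete Pearson r with two-sided p per variable pair.

    Pairs with fewer than 3 complete observations, or involving a
    zero-variance variable, are reported as missing (NaN).
    """
    cols = list(data.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i, k):
            pair = data[[cols[i], cols[j]]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if i == j:
                if len(pair) and pair.iloc[:, 0].nunique() > 1:
                    r[i, i], p[i, i] = 1.0, 0.0
                continue
            if len(pair) < 3:
                continue
            xi = pair.iloc[:, 0].to_numpy(float)
            yj = pair.iloc[:, 1].to_numpy(float)
            if np.ptp(xi) == 0 or np.ptp(yj) == 0:
                continue
            res = sps.pearsonr(xi, yj)
            r[i, j] = r[j, i] = float(res.statistic)
            p[i, j] = p[j, i] = float(res.pvalue)
    return CorrelationMatrix(
        variables=cols,
        r=pd.DataFrame(r, index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols),
        n=pd.DataFrame(n, index=cols, columns=cols))


# -- mixed-design repeated-measures ANOVA ---------------------------------

@dataclass
class MixedAnovaResult:
    table: pd.DataFrame            # F, df, p per effect (group/session/interaction)
    post_hoc: pd.DataFrame         # Fisher LSD pairwise cell comparisons


def _f_p(ss_effect, df_effect, ss_error, df_error) -> tuple[float, float]:
    if df_effect <= 0 or df_error <= 0:
        return np.nan, np.nan
    ms_e = ss_error / df_error
    ms_f = ss_effect / df_effect
    if ms_e <= 1e-300:
        if ms_f <= 1e-12:
            return 0.0, 1.0        # no variance anywhere
        return np.inf, 0.0
    f = ms_f / ms_e
    return float(f), float(sps.f.sf(f, df_effect, df_error))


def rm_anova(data: pd.DataFrame, dv: str = "value", subject: str = "subject",
             within: str = "session", between: str = "group"
             ) -> MixedAnovaResult:
    """Balanced mixed-design ANOVA (between-subject group, within-subject
    session) by direct sums-of-squares decomposition, plus Fisher LSD.

    The Fisher LSD table holds unadjusted pairwise t-tests on all
    group x session cell means, using the within-subject error term for
    comparisons at matched group and the between-subject error term
    otherwise (no pooling across error strata).
    """
    df = data[[subject, between, within, dv]].copy()
    if df[dv].isna().any():
        raise StatsError("missing cells are not supported (no imputation)")
    counts = df.groupby([subject, within], observed=True).size()
    if (counts != 1).any():
        raise StatsError("each subject needs exactly one value per session")
    sessions_per_subject = df.groupby(subject, observed=True)[within].nunique()
    if sessions_per_subject.nunique() != 1:
        raise StatsError("unbalanced design: missing sessions for some subjects")
    groups = df[between].unique()
    if any(df[df[between] == g][subject].nunique() < 2 for g in groups):
        raise StatsError("need >= 2 subjects per group")

    y = df[dv].to_numpy(float)
    grand = y.mean()
    n_sess = df[within].nunique()
    subj_means = df.groupby(subject, observed=True)[dv].mean()
    subj_group = df.groupby(subject, observed=True)[between].first()
    group_means = df.groupby(between, observed=True)[dv].mean()
    sess_means = df.groupby(within, observed=True)[dv].mean()
    cell_means = df.groupby([between, within], observed=True)[dv].mean()
    n_per_group = subj_group.value_counts()

    ss_total = float(((y - grand) ** 2).sum())
    ss_between_subj = float(n_sess * ((subj_means - grand) ** 2).sum())
    ss_group = float(n_sess * sum(n_per_group[g]
                                  * (group_means[g] - grand) ** 2
                                  for g in groups))
    ss_subj_within = ss_between_subj - ss_group
    ss_session = float(len(subj_means)
                       * ((sess_means - grand) ** 2).sum())
    ss_cells = float(sum(n_per_group[g] * (cell_means[(g, s)] - grand) ** 2
                         for g, s in cell_means.index))
    ss_interaction = ss_cells - ss_group - ss_session
    ss_error_within = ss_total - ss_between_subj - ss_session - ss_interaction

    n_subj = len(subj_means)
    n_grp = len(groups)
    df_group = n_grp - 1
    df_subj_within = n_subj - n_grp
    df_session = n_sess - 1
    df_inter = df_group * df_session
    df_err_within = df_subj_within * df_session

    rows = []
    for name, ss, dfe, ss_err, df_err in [
            ("group", ss_group, df_group, ss_subj_within, df_subj_within),
            ("session", ss_session, df_session, ss_error_within,
             df_err_within),
            ("interaction", ss_interaction, df_inter, ss_error_within,
             df_err_within)]:
        f, p = _f_p(ss, dfe, ss_err, df_err)
        rows.append({"effect": name, "SS": ss, "df": dfe,
                     "error_SS": ss_err, "error_df": df_err, "F": f, "p": p})
    table = pd.DataFrame(rows)

    # Fisher LSD on cell means
    ms_w = ss_error_within / df_err_within if df_err_within > 0 else np.nan
    ms_b = ss_subj_within / df_subj_within if df_subj_within > 0 else np.nan
    cells = list(cell_means.index)
    ph = []
    for a in range(len(cells)):
        for b in range(a + 1, len(cells)):
            (g1, s1), (g2, s2) = cells[a], cells[b]
            n1, n2 = n_per_group[g1], n_per_group[g2]
            same_group = g1 == g2
            mse, dfe = (ms_w, df_err_within) if same_group \
                else (ms_b, df_subj_within)
            diff = cell_means[cells[a]] - cell_means[cells[b]]
            se = np.sqrt(mse * (1 / n1 + 1 / n2))
            if se <= 1e-300:
                t_stat = 0.0 if abs(diff) <= 1e-12 else np.inf
            else:
                t_stat = diff / se
            p_val = float(2 * sps.t.sf(abs(t_stat), dfe)) \
                if np.isfinite(t_stat) else 0.0
            if t_stat == 0.0 and se <= 1e-300:
                p_val = 1.0
            ph.append({"group_1": g1, "session_1": s1, "group_2": g2,
                       "session_2": s2, "mean_diff": float(diff),
                       "t": float(t_stat), "df": dfe, "p": p_val})
    return MixedAnovaResult(table=table, post_hoc=pd.DataFrame(ph))


# -- PCA with varimax ------------------------------------------------------

@dataclass
class PcaResult:
    variables: list[str]
    eigenvalues: np.ndarray               # all components, descending
    explained_variance_pct: np.ndarray    # pre-rotation, sums to 100
    retained_components: int
    loadings: pd.DataFrame                # variables x retained, varimax-rotated
    unrotated_loadings: pd.DataFrame
    rotated_variance_pct: np.ndarray      # post-rotation sums of squared loadings


def varimax(loadings: np.ndarray, kaiser_normalize: bool = True,
            tol: float = 1e-8, max_iter: int = 1000) -> np.ndarray:
    """Varimax rotation of a loading matrix (SVD-update algorithm).

    Maximizes the variance of squared loadings per component under an
    orthogonal rotation; Kaiser normalization divides rows by their
    communalities before rotating and restores them after, so per-variable
    communalities are preserved exactly.
    """
    L = np.asarray(loadings, dtype=float).copy()
    p, k = L.shape
    if k < 2:
        return L
    if kaiser_normalize:
        h = np.sqrt((L ** 2).sum(axis=1))
        h[h == 0] = 1.0
        L /= h[:, None]
    R = np.eye(k)
    var = 0.0
    for _ in range(max_iter):
        Lr = L @ R
        u, s, vt = np.linalg.svd(
            L.T @ (Lr ** 3 - Lr @ np.diag((Lr ** 2).sum(axis=0)) / p))
        R = u @ vt
        new_var = s.sum()
        if new_var < var * (1 + tol):
            break
        var = new_var
    L = L @ R
    if kaiser_normalize:
        L *= h[:, None]
    return L


def _fix_signs(L: np.ndarray) -> np.ndarray:
    """Flip each component so its largest-magnitude loading is positive."""
    L = L.copy()
    for j in range(L.shape[1]):
        i = np.argmax(np.abs(L[:, j]))
        if L[i, j] < 0:
            L[:, j] = -L[:, j]
    return L


def pca_varimax(data: pd.DataFrame, eigenvalue_cutoff: float = 1.0
                ) -> PcaResult:
    """Correlation-matrix PCA with eigenvalue > 1 retention and varimax.

    Variables are z-scored; explained-variance percentages come from the
    unrotated eigenvalues; the retained loadings are varimax-rotated and
    sign-fixed; post-rotation variance sums are also reported.
    """
    df = data.dropna()
    X = df.to_numpy(float)
    n, p = X.shape
    if n < p + 2:
        raise StatsError(f"need at least {p + 2} complete subjects for "
                         f"{p} variables, got {n}")
    sd = X.std(axis=0, ddof=1)
    dead = [c for c, s in zip(df.columns, sd) if s == 0]
    if dead:
        raise StatsError(f"zero-variance variables: {dead}")
    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    retained = int(np.sum(eigval > eigenvalue_cutoff))
    if retained == 0:
        retained = 1
    L = eigvec[:, :retained] * np.sqrt(eigval[:retained])
    L = _fix_signs(L)
    Lrot = _fix_signs(varimax(L))
    comp_names = [f"PC{i + 1}" for i in range(retained)]
    cols = list(df.columns)
    return PcaResult(
        variables=cols,
        eigenvalues=eigval,
        explained_variance_pct=eigval / p * 100.0,
        retained_components=retained,
        loadings=pd.DataFrame(Lrot, index=cols, columns=comp_names),
        unrotated_loadings=pd.DataFrame(L, index=cols, columns=comp_names),
        rotated_variance_pct=(Lrot ** 2).sum(axis=0) / p * 100.0)


#: loading magnitude above which a variable is annotated as a main
#: contributor to a component
STRONG_LOADING = 0.7
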