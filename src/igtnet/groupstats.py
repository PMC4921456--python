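"""Group-level inference.

Two tools: balanced fully-within-subject repeated-measures ANOVA (one-way
and two-way, e.g. 2 condition x 4 session) with partial eta-squared effect
sizes, and a linear mixed model predicting task performance from regional
network metrics with a subject random intercept and AR(1) within-subject
error correlation, estimated by REML.

The ANOVA uses the classical sums-of-squares decomposition in which each
within-subject effect is tested against its own subject-by-effect
interaction stratum; partial eta^2 = SS_effect / (SS_effect + SS_error).
Degrees of freedom are reported uncorrected by default, with a
Greenhouse-Geisser sphericity correction available by flag.

No general mixed-model routine available to the package supports a random
intercept combined with AR(1) residual correlation, so the REML objective
is implemented directly: per-subject marginal covariance
V_i = sigma_b^2 J + sigma_e^2 R(rho), R_jk = rho^|t_j - t_k|, with the
fixed effects profiled out by GLS and the variance parameters optimized
numerically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Per-effect F tests from a within-subject decomposition."""

    effects: pd.DataFrame  # effect, F, df_num, df_den, p, partial_eta_sq
    design: str = ""

    def effect(self, name: str) -> pd.Series:
        row = self.effects[self.effects["effect"] == name]
        if row.empty:
            raise KeyError(name)
        return row.iloc[0]


def _cell_table(
    table: pd.DataFrame, subject: str, factors: list[str], value: str
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Pivot a balanced long table into an (n_subjects, l1, l2, ...) array."""
    levels = [np.sort(table[f].unique()) for f in factors]
    subjects = np.sort(table[subject].unique())
    pivot = table.set_index([subject, *factors])[value]
    if pivot.index.has_duplicates:
        dupes = pivot.index[pivot.index.duplicated()].tolist()[:5]
        raise ValueError(f"duplicate design cells: {dupes}")
    shape = (len(subjects), *(len(lv) for lv in levels))
    expected = math.prod(shape)
    if len(pivot) != expected:
        full = pd.MultiIndex.from_product([subjects, *levels])
        missing = full.difference(pivot.index).tolist()[:10]
        raise ValueError(f"unbalanced design; missing cells: {missing}")
    full = pd.MultiIndex.from_product([subjects, *levels])
    data = pivot.reindex(full).to_numpy().reshape(shape)
    return data, levels


def _f_and_p(ss_eff, df_eff, ss_err, df_err, tol=0.0):
    # sums of squares below tol (relative to the data's total SS) are treated
    # as exact zeros, so constant data yields F = 0 instead of a 0/0 artifact
    ss_eff = 0.0 if ss_eff <= tol else ss_eff
    ss_err = 0.0 if ss_err <= tol else ss_err
    if ss_err == 0.0:
        f = 0.0 if ss_eff == 0.0 else np.inf
    else:
        f = (ss_eff / df_eff) / (ss_err / df_err)
    p = 1.0 if not np.isfinite(f) else float(stats.f.sf(f, df_eff, df_err))
    if f == 0.0:
        p = 1.0
    eta = 0.0 if (ss_eff + ss_err) == 0.0 else ss_eff / (ss_eff + ss_err)
    return float(f), float(p), float(eta)


def _ss_tol(data: np.ndarray) -> float:
    """Numerical-zero threshold for sums of squares, scaled to the data.

    Marginal means of constant data differ from the grand mean by reduction-
    order float noise (~1e-16 relative), so SS below (1e-10 * |data|)^2 per
    cell are indistinguishable from zero.
    """
    scale = float(np.abs(data).max())
    return data.size * (1e-10 * max(scale, 1e-30)) ** 2


def _gg_epsilon(cells: np.ndarray, C: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon for the contrast C over per-subject cells."""
    S = np.cov(cells, rowvar=False, ddof=1)
    M = C @ np.atleast_2d(S) @ C.T
    k = M.shape[0]
    tr = np.trace(M)
    denom = k * np.trace(M @ M)
    if denom <= 0:
        return 1.0
    return float(min(1.0, max(1.0 / k, tr**2 / denom)))


def _helmert(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix."""
    H = np.zeros((k - 1, k))
    for i in range(1, k):
        H[i - 1, :i] = 1.0
        H[i - 1, i] = -i
        H[i - 1] /= np.linalg.norm(H[i - 1])
    return H


def rm_anova_oneway(
    table: pd.DataFrame,
    subject: str = "subject",
    factor: str = "session",
    value: str = "value",
    gg_correction: bool = False,
) -> AnovaResult:
    """One-way fully within-subject ANOVA."""
    data, (levels,) = _cell_table(table, subject, [factor], value)
    n, k = data.shape
    grand = data.mean()
    m_t = data.mean(axis=0)
    m_s = data.mean(axis=1)
    ss_t = n * ((m_t - grand) ** 2).sum()
    resid = data - m_s[:, None] - m_t[None, :] + grand
    ss_err = (resid**2).sum()
    df_t, df_err = k - 1, (k - 1) * (n - 1)
    f, p, eta = _f_and_p(ss_t, df_t, ss_err, df_err, tol=_ss_tol(data))
    row = {"effect": factor, "F": f, "df_num": float(df_t),
           "df_den": float(df_err), "p": p, "partial_eta_sq": eta}
    if gg_correction:
        eps = _gg_epsilon(data, _helmert(k))
        row["gg_epsilon"] = eps
        row["p_gg"] = float(stats.f.sf(f, df_t * eps, df_err * eps)) if f > 0 else 1.0
    return AnovaResult(effects=pd.DataFrame([row]), design=f"1-way ({k} levels)")


def rm_anova_2x4(
    table: pd.DataFrame,
    subject: str = "subject",
    factor_a: str = "condition",
    factor_b: str = "session",
    value: str = "value",
    gg_correction: bool = False,
) -> AnovaResult:
    """Two-way fully within-subject ANOVA (e.g. 2 condition x 4 session).

    Each effect (A, B, A x B) is tested against its subject-by-effect
    interaction stratum.  Works for any level counts, not just 2 x 4.
    """
    data, (la, lb) = _cell_table(table, subject, [factor_a, factor_b], value)
    n, a, b = data.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    grand = data.mean()
    m_a = data.mean(axis=(0, 2))
    m_b = data.mean(axis=(0, 1))
    m_ab = data.mean(axis=0)
    m_s = data.mean(axis=(1, 2))
    m_sa = data.mean(axis=2)
    m_sb = data.mean(axis=1)

    ss_a = n * b * ((m_a - grand) ** 2).sum()
    ss_b = n * a * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_sa = b * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum()
    ss_sb = a * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum()
    resid = (
        data
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_sab = (resid**2).sum()

    specs = [
        (factor_a, ss_a, a - 1, ss_sa, (a - 1) * (n - 1), _helmert(a), None),
        (factor_b, ss_b, b - 1, ss_sb, (b - 1) * (n - 1), None, _helmert(b)),
        (
            f"{factor_a}:{factor_b}",
            ss_ab,
            (a - 1) * (b - 1),
            ss_sab,
            (a - 1) * (b - 1) * (n - 1),
            _helmert(a),
            _helmert(b),
        ),
    ]
    cells = data.reshape(n, a * b)
    tol = _ss_tol(data)
    rows = []
    for name, ss_e, df_e, ss_err, df_err, Ca, Cb in specs:
        f, p, eta = _f_and_p(ss_e, df_e, ss_err, df_err, tol=tol)
        row = {"effect": name, "F": f, "df_num": float(df_e),
               "df_den": float(df_err), "p": p, "partial_eta_sq": eta}
        if gg_correction:
            if Ca is None:
                C = np.kron(np.full((1, a), 1 / a), Cb)
            elif Cb is None:
                C = np.kron(Ca, np.full((1, b), 1 / b))
            else:
                C = np.kron(Ca, Cb)
            eps = _gg_epsilon(cells, C)
            row["gg_epsilon"] = eps
            row["p_gg"] = (
                float(stats.f.sf(f, df_e * eps, df_err * eps))
                if np.isfinite(f) and f > 0 else 1.0
            )
        rows.append(row)
    return AnovaResult(effects=pd.DataFrame(rows), design=f"{a}x{b} within")


def behavioral_anova(
    scores: pd.DataFrame,
    subject: str = "subject",
    block: str = "session",
    value: str = "igt_score",
    gg_correction: bool = False,
) -> AnovaResult:
    """One-way RM-ANOVA on net-advantageous scores across task blocks."""
    return rm_anova_oneway(scores, subject=subject, factor=block, value=value,
                           gg_correction=gg_correction)


# ---------------------------------------------------------------------------
# linear mixed model with AR(1) errors
# ---------------------------------------------------------------------------

@dataclass
class MixedModelResult:
    """REML fit of y ~ X with subject random intercept and AR(1) errors."""

    fixed_effects: pd.DataFrame  # term, B, SE, t, p
    sigma_subject: float
    sigma_resid: float
    ar1_rho: float
    loglik_reml: float
    converged: bool
    n_obs: int
    diagnostics: dict = field(default_factory=dict)

    def coef(self, term: str) -> pd.Series:
        row = self.fixed_effects[self.fixed_effects["term"] == term]
        if row.empty:
            raise KeyError(term)
        return row.iloc[0]


def _neg2_reml(theta, y_groups, X_groups, lag_groups):
    log_sb, log_se, z = theta
    sb2, se2 = math.exp(2 * log_sb), math.exp(2 * log_se)
    rho = math.tanh(z)
    logdet = 0.0
    p = X_groups[0].shape[1]
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    pieces = []
    for y, X, lags in zip(y_groups, X_groups, lag_groups):
        R = rho ** np.abs(lags[:, None] - lags[None, :])
        V = sb2 + se2 * R
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e12
        logdet += 2.0 * np.log(np.diag(L)).sum()
        Vi_y = np.linalg.solve(V, y)
        Vi_X = np.linalg.solve(V, X)
        XtVX += X.T @ Vi_X
        XtVy += X.T @ Vi_y
        pieces.append((y, X, Vi_y, Vi_X))
    sign, logdet_X = np.linalg.slogdet(XtVX)
    if sign <= 0:
        return 1e12
    beta = np.linalg.solve(XtVX, XtVy)
    quad = 0.0
    for y, X, Vi_y, Vi_X in pieces:
        r = y - X @ beta
        quad += r @ (Vi_y - Vi_X @ beta)
    return logdet + logdet_X + quad


def fit_lmm_ar1(
    y: np.ndarray,
    X: np.ndarray,
    subject: np.ndarray,
    time: np.ndarray,
    term_names: list[str] | None = None,
) -> MixedModelResult:
    """REML fit of the random-intercept + AR(1)-error mixed model.

    ``time`` indexes the within-subject ordering (e.g. session number);
    the residual correlation between observations j, k of the same subject
    is rho^|t_j - t_k|.  Raises on non-convergence, with diagnostics.
    """
    y = np.asarray(y, float)
    X = np.atleast_2d(np.asarray(X, float))
    subject = np.asarray(subject)
    time = np.asarray(time, float)
    n, p = X.shape
    if term_names is None:
        term_names = [f"x{j}" for j in range(p)]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("fixed-effect design is rank deficient")

    y_groups, X_groups, lag_groups = [], [], []
    for s in np.unique(subject):
        rows = np.flatnonzero(subject == s)
        rows = rows[np.argsort(time[rows])]
        if len(rows) < 2:
            raise ValueError(f"subject {s!r} has fewer than 2 observations")
        y_groups.append(y[rows])
        X_groups.append(X[rows])
        lag_groups.append(time[rows])

    sd0 = max(y.std(), 1e-3)
    starts = [
        (math.log(sd0 / 2), math.log(sd0 / 2), 0.0),
        (math.log(sd0 / 10), math.log(sd0), 0.3),
        (math.log(sd0), math.log(sd0 / 10), -0.3),
    ]
    best = None
    for x0 in starts:
        res = optimize.minimize(
            _neg2_reml,
            x0=np.asarray(x0),
            args=(y_groups, X_groups, lag_groups),
            method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 4000},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise RuntimeError(
            f"mixed-model REML failed to converge: {getattr(best, 'message', '')}"
        )

    log_sb, log_se, z = best.x
    sb2, se2, rho = math.exp(2 * log_sb), math.exp(2 * log_se), math.tanh(z)
    XtVX = np.zeros((p, p))
    XtVy = np.zeros(p)
    for yg, Xg, lags in zip(y_groups, X_groups, lag_groups):
        R = rho ** np.abs(lags[:, None] - lags[None, :])
        V = sb2 + se2 * R
        XtVX += Xg.T @ np.linalg.solve(V, Xg)
        XtVy += Xg.T @ np.linalg.solve(V, yg)
    cov_beta = np.linalg.inv(XtVX)
    beta = cov_beta @ XtVy
    se = np.sqrt(np.diag(cov_beta))
    df = max(n - p, 1)
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    fixed = pd.DataFrame(
        {"term": term_names, "B": beta, "SE": se, "t": tvals, "p": pvals}
    )
    return MixedModelResult(
        fixed_effects=fixed,
        sigma_subject=math.sqrt(sb2),
        sigma_resid=math.sqrt(se2),
        ar1_rho=float(rho),
        loglik_reml=float(-0.5 * best.fun),
        converged=bool(best.success),
        n_obs=n,
        diagnostics={"optimizer": "Nelder-Mead", "n2ll": float(best.fun),
                     "message": str(best.message)},
    )


def fit_performance_model(
    table: pd.DataFrame,
    network: str,
    score: str = "igt_score",
    metrics: tuple[str, ...] = ("K", "E_loc", "E_glob"),
    subject: str = "subject",
    session: str = "session",
) -> MixedModelResult:
    """Predict task performance from one network's metrics.

    ``table`` is long over (subject, session) with one column per metric for
    the requested network (either bare metric names or ``{network}_{metric}``)
    and the performance score.  Fits score ~ intercept + K + E_loc + E_glob
    with subject random intercept and AR(1) errors over sessions.
    """
    cols = []
    for m in metrics:
        for cand in (f"{network}_{m}", m):
            if cand in table.columns:
                cols.append(cand)
                break
        else:
            raise KeyError(f"metric column for {m!r} not found")
    X = np.column_stack(
        [np.ones(len(table)), *(table[c].to_numpy(float) for c in cols)]
    )
    return fit_lmm_ar1(
        y=table[score].to_numpy(float),
        X=X,
        subject=table[subject].to_numpy(),
        time=table[session].to_numpy(float),
        term_names=["intercept", *metrics],
    )
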