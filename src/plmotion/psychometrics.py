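"""Psychometric analysis of ordinal adjustment responses.

The response in each trial is an ordinal profile index 0-20.  The analysis
follows the cumulative-response probit approach: for every participant and
condition the responses are expanded into binomial "CDF observations"
(successes = number of responses <= i out of the cell's trials, for each index
i), and a probit regression of these cumulative proportions on the index
yields the population psychometric function

    Phi^-1( P(response <= i) ) = beta0 + beta1 * i .

From the coefficients, the point of subjective equality (PSE, the index at
which the fitted CDF crosses 0.5) is -beta0/beta1 and the just-noticeable
difference (JND, distance from the PSE to the 0.75 point) is
Phi^-1(0.75)/beta1; standard errors and 95% confidence intervals follow by the
first-order delta method.

Two fitting routes are provided:

* :func:`fit_probit` -- pooled maximum-likelihood probit (statsmodels GLM) of
  all CDF observations, the population-level analysis.  The 21 cumulative
  indicators per trial are treated as independent binomial observations; they
  are not, so the resulting standard errors are approximate (the parametric
  bootstrap check in the test suite quantifies the delta-method part).
* :func:`fit_mixed_probit` -- a probit generalized linear mixed model with
  orientation dummies and per-participant random coefficients, fitted by
  maximum likelihood with a Laplace approximation to the random-effects
  integral (the clustered, per-participant analysis).  Wald statistics
  z = beta/SE with two-sided normal p-values assess the fixed effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import log_ndtr
from scipy.stats import kruskal, ks_2samp, norm

from .observer import N_LEVELS

__all__ = [
    "EmpiricalSummary",
    "ProbitFit",
    "MixedProbitFit",
    "FitError",
    "summarize",
    "build_cdf_observations",
    "fit_probit",
    "fit_mixed_probit",
    "pse_jnd_ci",
    "compare_distributions",
    "report_table",
]

_Z75 = float(norm.ppf(0.75))
_Z95 = 1.96  # normal quantile for the 95% confidence intervals


class FitError(RuntimeError):
    """Model fitting failed (degenerate data or non-convergence)."""


# ---------------------------------------------------------------------------
# Empirical summaries
# ---------------------------------------------------------------------------


@dataclass
class EmpiricalSummary:
    """Histogram / median / IQR summary of the ordinal responses in one condition."""

    condition: str
    n_trials: int
    histogram: np.ndarray  # counts per index 0..20
    median: float
    iqr: float
    per_start_medians: dict[int, float]
    start_median_range: float

    def cdf(self) -> np.ndarray:
        """Empirical CDF over the index grid (non-decreasing, ends at 1)."""
        return np.cumsum(self.histogram) / self.histogram.sum()


def summarize(table: pd.DataFrame, condition: str | None = None) -> EmpiricalSummary:
    """Population-level summary (responses pooled over participants/starts/reps)."""
    if condition is not None:
        table = table[table["condition"].astype(str) == str(condition)]
    if len(table) == 0:
        raise ValueError(f"no trials selected for condition {condition!r}")
    resp = table["response_index"].to_numpy()
    hist = np.bincount(resp, minlength=N_LEVELS).astype(int)
    q25, q75 = np.percentile(resp, [25, 75])
    per_start = {
        int(s): float(np.median(grp["response_index"]))
        for s, grp in table.groupby("starting_index")
    }
    rng = max(per_start.values()) - min(per_start.values()) if per_start else 0.0
    return EmpiricalSummary(
        condition=str(condition),
        n_trials=len(table),
        histogram=hist,
        median=float(np.median(resp)),
        iqr=float(q75 - q25),
        per_start_medians=per_start,
        start_median_range=float(rng),
    )


def build_cdf_observations(table: pd.DataFrame) -> pd.DataFrame:
    """Expand ordinal responses into per-cell binomial CDF observations.

    For each participant x condition and every index i in 0..20, the
    observation is (successes = #responses <= i, size = #trials in the cell).
    Successes are non-decreasing in i and reach size at i = 20.
    """
    rows = []
    grid = np.arange(N_LEVELS)
    for (p, c), grp in table.groupby(["participant", "condition"], sort=True):
        resp = grp["response_index"].to_numpy()
        successes = (resp[None, :] <= grid[:, None]).sum(axis=1)
        for i in grid:
            rows.append(
                {
                    "participant": p,
                    "condition": str(c),
                    "index": int(i),
                    "successes": int(successes[i]),
                    "size": len(resp),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Pooled probit
# ---------------------------------------------------------------------------


@dataclass
class ProbitFit:
    """Pooled probit regression of cumulative proportions on the index."""

    beta0: float
    beta1: float
    vcov: np.ndarray  # 2x2
    deviance: float
    df_resid: int
    pse: float
    jnd: float
    se_pse: float
    se_jnd: float
    ci_pse: tuple[float, float]
    ci_jnd: tuple[float, float]

    @property
    def pse_out_of_range(self) -> bool:
        return not (0.0 <= self.pse <= N_LEVELS - 1)


def _delta_pse_jnd(b0: float, b1: float, vcov: np.ndarray):
    """PSE/JND point estimates with delta-method SEs from a 2x2 covariance."""
    if b1 <= 0:
        raise FitError(f"non-positive psychometric slope ({b1:.4g}); PSE/JND undefined")
    pse = -b0 / b1
    jnd = _Z75 / b1
    g_pse = np.array([-1.0 / b1, b0 / b1**2])
    g_jnd = np.array([0.0, -_Z75 / b1**2])
    se_pse = float(np.sqrt(g_pse @ vcov @ g_pse))
    se_jnd = float(np.sqrt(g_jnd @ vcov @ g_jnd))
    return pse, jnd, se_pse, se_jnd


def fit_probit(cdf_obs: pd.DataFrame) -> ProbitFit:
    """Maximum-likelihood probit of CDF observations on the ordinal index.

    All rows are pooled regardless of participant (the population analysis);
    pass a single condition's observations for a per-condition fit.
    """
    idx = cdf_obs["index"].to_numpy(dtype=float)
    succ = cdf_obs["successes"].to_numpy(dtype=float)
    size = cdf_obs["size"].to_numpy(dtype=float)
    prop = succ / size
    if len(np.unique(idx[(prop > 0) & (prop < 1)])) < 2:
        raise FitError(
            "degenerate CDF observations: fewer than two indices with "
            "non-degenerate proportions"
        )
    exog = sm.add_constant(idx)
    endog = np.column_stack([succ, size - succ])
    model = sm.GLM(endog, exog, family=sm.families.Binomial(sm.families.links.Probit()))
    try:
        res = model.fit()
    except Exception as exc:  # pragma: no cover - statsmodels failure detail
        raise FitError(f"probit fit failed: {exc}") from exc
    b0, b1 = float(res.params[0]), float(res.params[1])
    vcov = np.asarray(res.cov_params())
    pse, jnd, se_pse, se_jnd = _delta_pse_jnd(b0, b1, vcov)
    return ProbitFit(
        beta0=b0,
        beta1=b1,
        vcov=vcov,
        deviance=float(res.deviance),
        df_resid=int(res.df_resid),
        pse=pse,
        jnd=jnd,
        se_pse=se_pse,
        se_jnd=se_jnd,
        ci_pse=(pse - _Z95 * se_pse, pse + _Z95 * se_pse),
        ci_jnd=(jnd - _Z95 * se_jnd, jnd + _Z95 * se_jnd),
    )


# ---------------------------------------------------------------------------
# Mixed-effects probit (Laplace maximum likelihood)
# ---------------------------------------------------------------------------


@dataclass
class MixedProbitFit:
    """Probit GLMM with condition dummies and per-participant random coefficients.

    Fixed effects (for three conditions with reference first):
    intercept, index slope, per-non-reference intercept shifts, and
    index-by-condition slope shifts.  Random effects are per-participant
    coefficients on the same design columns (independent/diagonal covariance
    by default).
    """

    term_names: list[str]
    beta: np.ndarray
    fixed_vcov: np.ndarray
    sigma_u: np.ndarray  # random-effect SDs per random term
    random_terms: list[str]
    random_modes: pd.DataFrame  # posterior modes of u_j per participant
    reference_level: str
    conditions: list[str]
    loglik: float
    converged: bool
    singular: bool
    n_participants: int

    def wald(self) -> pd.DataFrame:
        """Wald statistics z = beta/SE with two-sided normal p per fixed effect."""
        se = np.sqrt(np.diag(self.fixed_vcov))
        z = self.beta / se
        p = 2.0 * norm.sf(np.abs(z))
        return pd.DataFrame(
            {"estimate": self.beta, "se": se, "z": z, "p": p}, index=self.term_names
        )

    def condition_selectors(self, condition: str) -> tuple[np.ndarray, np.ndarray]:
        """Selection vectors (a, b) with beta0_c = a@beta, beta1_c = b@beta."""
        condition = str(condition)
        if condition not in self.conditions:
            raise ValueError(f"unknown condition {condition!r}")
        k = len(self.beta)
        a = np.zeros(k)
        b = np.zeros(k)
        a[0] = 1.0
        b[1] = 1.0
        if condition != self.reference_level:
            others = [c for c in self.conditions if c != self.reference_level]
            j = others.index(condition)
            a[2 + 2 * j] = 1.0
            b[3 + 2 * j] = 1.0
        return a, b

    def condition_coefficients(self, condition: str):
        """(beta0_c, beta1_c, 2x2 vcov) for one condition, composed across dummies."""
        a, b = self.condition_selectors(condition)
        b0 = float(a @ self.beta)
        b1 = float(b @ self.beta)
        V = self.fixed_vcov
        vv = np.array(
            [[a @ V @ a, a @ V @ b], [b @ V @ a, b @ V @ b]], dtype=float
        )
        return b0, b1, vv


def _term_design(
    idx: np.ndarray, cond: np.ndarray, conditions: list[str], reference: str
) -> tuple[np.ndarray, list[str]]:
    """Fixed-effects design matrix: [1, I, D_c, I*D_c ...] vs the reference level."""
    cols = [np.ones_like(idx), idx]
    names = ["intercept", "index"]
    for c in conditions:
        if c == reference:
            continue
        d = (cond == c).astype(float)
        cols.append(d)
        names.append(f"d_{c}")
        cols.append(idx * d)
        names.append(f"index:d_{c}")
    return np.column_stack(cols), names


_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _binom_probit_ll_batch(eta, Y, Nn):
    """Batched (J, M) binomial-probit log-likelihood and eta-derivatives."""
    logp = log_ndtr(eta)
    logq = log_ndtr(-eta)
    ll = np.sum(Y * logp + (Nn - Y) * logq, axis=1)
    logpdf = -0.5 * eta * eta - _LOG_SQRT_2PI
    a = np.exp(logpdf - logp)
    b = np.exp(logpdf - logq)
    g = Y * a - (Nn - Y) * b
    h = -eta * g - Y * a**2 - (Nn - Y) * b**2
    return ll, g, h


def _laplace_loglik(theta, X, Z_idx, Y, Nn, u_cache):
    """Negative marginal log-likelihood under the Laplace approximation.

    theta = (beta, log sigma_u); X is the shared fixed design, Z the subset of
    columns carrying random effects, Y/Nn the (J, M) binomial data of all J
    participants on the same rows.  ``u_cache`` (J, q) holds warm-start
    posterior modes; the inner Newton maximization runs batched across
    participants.
    """
    k = X.shape[1]
    q = len(Z_idx)
    beta = theta[:k]
    sig = np.exp(theta[k:])
    Z = X[:, Z_idx]
    d_inv = 1.0 / sig**2
    eta_fix = X @ beta
    U = u_cache.copy()
    for _ in range(80):
        eta = eta_fix[None, :] + U @ Z.T
        _, g1, h2 = _binom_probit_ll_batch(eta, Y, Nn)
        grad = g1 @ Z - U * d_inv  # (J, q)
        H = np.einsum("jm,ma,mb->jab", h2, Z, Z)
        H[:, np.arange(q), np.arange(q)] -= d_inv
        try:
            step = np.linalg.solve(H, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            return 1e10
        U_new = U - step
        bad = ~np.all(np.isfinite(U_new), axis=1)
        if np.any(bad):
            U_new[bad] = 0.0
        if np.max(np.abs(U_new - U)) < 1e-10:
            U = U_new
            break
        U = U_new
    u_cache[:] = U
    eta = eta_fix[None, :] + U @ Z.T
    ll, g1, h2 = _binom_probit_ll_batch(eta, Y, Nn)
    neg_H = -np.einsum("jm,ma,mb->jab", h2, Z, Z)
    neg_H[:, np.arange(q), np.arange(q)] += d_inv
    sign, logdet = np.linalg.slogdet(neg_H)
    if np.any(sign <= 0):
        return 1e10
    total = float(
        np.sum(ll)
        - 0.5 * np.sum(U * U * d_inv)
        - len(U) * np.sum(np.log(sig))
        - 0.5 * np.sum(logdet)
    )
    if not np.isfinite(total):
        return 1e10
    return -total


def fit_mixed_probit(
    cdf_obs: pd.DataFrame,
    reference_level: str | None = None,
    random_structure: str = "diagonal",
    min_sigma: float = 1e-3,
    max_sigma: float = 10.0,
) -> MixedProbitFit:
    """Fit the probit GLMM to per-participant CDF observations.

    Parameters
    ----------
    cdf_obs : DataFrame
        Output of :func:`build_cdf_observations` (columns participant,
        condition, index, successes, size).  All participants must share the
        same condition x index grid.
    reference_level : str
        Condition coded as the baseline for the dummies (default: first
        condition in sorted order).  Refitting with a different reference
        reparameterizes the fixed effects but leaves per-condition PSE/JND
        unchanged.
    random_structure : {"diagonal", "intercept", "intercept_slope"}
        Which design columns carry per-participant random coefficients.
        "diagonal" puts independent random effects on every fixed-effect
        column; a full covariance is not estimable from typical panel sizes
        (around twelve participants) and is not offered.

    Notes
    -----
    The marginal likelihood integrates the random effects per participant by
    a Laplace approximation around the posterior mode (inner Newton
    iterations); the outer optimization is quasi-Newton over the fixed
    effects and log random-effect SDs.  Variance components shrinking to the
    lower bound are flagged ``singular`` (a warning, not an error).
    """
    conditions = sorted(cdf_obs["condition"].astype(str).unique())
    if reference_level is None:
        reference_level = conditions[0]
    reference_level = str(reference_level)
    if reference_level not in conditions:
        raise ValueError(f"reference level {reference_level!r} not among {conditions}")
    participants = sorted(cdf_obs["participant"].unique())
    if len(participants) < 2:
        raise ValueError("mixed model requires at least two participants")

    # shared row grid: condition x index in fixed order
    pivot = cdf_obs.copy()
    pivot["condition"] = pivot["condition"].astype(str)
    grid = (
        pivot[["condition", "index"]]
        .drop_duplicates()
        .sort_values(["condition", "index"])
        .reset_index(drop=True)
    )
    idx = grid["index"].to_numpy(dtype=float)
    cond = grid["condition"].to_numpy()
    X, names = _term_design(idx, cond, conditions, reference_level)
    k = X.shape[1]

    y_rows, n_rows = [], []
    for p in participants:
        sub = pivot[pivot["participant"] == p].set_index(["condition", "index"])
        try:
            cells = sub.loc[list(zip(grid["condition"], grid["index"]))]
        except KeyError as exc:
            raise ValueError(
                f"participant {p} is missing cells of the condition x index grid"
            ) from exc
        y_rows.append(cells["successes"].to_numpy(dtype=float))
        n_rows.append(cells["size"].to_numpy(dtype=float))
    Y = np.vstack(y_rows)
    Nn = np.vstack(n_rows)

    structures = {
        "diagonal": list(range(k)),
        "intercept": [0],
        "intercept_slope": [0, 1],
    }
    if random_structure not in structures:
        raise ValueError(f"unknown random_structure {random_structure!r}")
    Z_idx = structures[random_structure]
    q = len(Z_idx)

    # starting values: pooled per-condition probit composed into dummy coding
    beta0 = np.zeros(k)
    try:
        pooled = {}
        for c in conditions:
            obs_c = pivot[pivot["condition"] == c]
            pooled[c] = fit_probit(obs_c)
        beta0[0] = pooled[reference_level].beta0
        beta0[1] = pooled[reference_level].beta1
        others = [c for c in conditions if c != reference_level]
        for j, c in enumerate(others):
            beta0[2 + 2 * j] = pooled[c].beta0 - beta0[0]
            beta0[3 + 2 * j] = pooled[c].beta1 - beta0[1]
    except FitError:
        pass
    theta0 = np.concatenate([beta0, np.full(q, np.log(0.3))])

    u_cache = np.zeros((len(participants), q))
    bounds = [(None, None)] * k + [(np.log(min_sigma), np.log(max_sigma))] * q
    res = minimize(
        _laplace_loglik,
        theta0,
        args=(X, Z_idx, Y, Nn, u_cache),
        method="L-BFGS-B",
        jac=None,
        bounds=bounds,
        options={"maxiter": 500, "ftol": 1e-11, "gtol": 1e-7},
    )
    if not res.success and not np.isfinite(res.fun):
        raise FitError(f"mixed probit did not converge: {res.message}")
    theta_hat = res.x

    # Newton polish: quasi-Newton with numeric gradients stalls slightly short
    # of the optimum, which breaks exact reparameterization invariance; a few
    # damped Newton steps on the smooth Laplace objective fix that.
    obj = lambda th: _laplace_loglik(th, X, Z_idx, Y, Nn, u_cache)
    lo = np.concatenate([np.full(k, -np.inf), np.full(q, np.log(min_sigma))])
    hi = np.concatenate([np.full(k, np.inf), np.full(q, np.log(max_sigma))])
    f_cur = obj(theta_hat)
    H = _numeric_hessian(obj, theta_hat)
    for _ in range(6):
        g = _numeric_gradient(obj, theta_hat)
        free = ~(
            ((theta_hat <= lo + 1e-9) & (g > 0)) | ((theta_hat >= hi - 1e-9) & (g < 0))
        )
        if np.max(np.abs(g[free])) < 1e-6:
            break
        step = np.zeros_like(theta_hat)
        Hf = H[np.ix_(free, free)]
        try:
            step[free] = np.linalg.solve(Hf, g[free])
        except np.linalg.LinAlgError:
            break
        improved = False
        for damp in (1.0, 0.5, 0.25, 0.1):
            cand = np.clip(theta_hat - damp * step, lo, hi)
            f_new = obj(cand)
            if f_new < f_cur:
                theta_hat, f_cur, improved = cand, f_new, True
                break
        if not improved:
            break
        H = _numeric_hessian(obj, theta_hat)

    beta_hat = theta_hat[:k]
    sig_hat = np.exp(theta_hat[k:])
    singular = bool(np.any(sig_hat <= min_sigma * 1.0001))
    try:
        cov_all = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_all = np.linalg.pinv(H)
    fixed_vcov = cov_all[:k, :k]
    if np.any(np.diag(fixed_vcov) < 0):
        fixed_vcov = np.linalg.pinv(H[:k, :k])

    # posterior modes at the optimum
    _laplace_loglik(theta_hat, X, Z_idx, Y, Nn, u_cache)
    modes = pd.DataFrame(
        u_cache.copy(),
        index=pd.Index(participants, name="participant"),
        columns=[names[i] for i in Z_idx],
    )
    return MixedProbitFit(
        term_names=names,
        beta=beta_hat,
        fixed_vcov=fixed_vcov,
        sigma_u=sig_hat,
        random_terms=[names[i] for i in Z_idx],
        random_modes=modes,
        reference_level=reference_level,
        conditions=conditions,
        loglik=-float(res.fun),
        converged=bool(res.success),
        singular=singular,
        n_participants=len(participants),
    )


def _numeric_gradient(f, x, eps: float = 1e-6) -> np.ndarray:
    g = np.empty_like(x)
    for i in range(len(x)):
        xp = x.copy(); xp[i] += eps
        xm = x.copy(); xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
    return g


def _numeric_hessian(f, x, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    H = np.empty((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            xpp = x.copy(); xpp[i] += eps; xpp[j] += eps
            xpm = x.copy(); xpm[i] += eps; xpm[j] -= eps
            xmp = x.copy(); xmp[i] -= eps; xmp[j] += eps
            xmm = x.copy(); xmm[i] -= eps; xmm[j] -= eps
            H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * eps**2)
    return H


@dataclass
class PsychometricEstimate:
    """Estimate / SE / 95% CI rows for PSE and JND in one condition."""

    condition: str
    pse: float
    se_pse: float
    ci_pse: tuple[float, float]
    jnd: float
    se_jnd: float
    ci_jnd: tuple[float, float]


def pse_jnd_ci(fit, condition: str | None = None) -> PsychometricEstimate:
    """PSE and JND with delta-method SEs and 95% CIs for one condition.

    Accepts a :class:`ProbitFit` (condition ignored) or a
    :class:`MixedProbitFit` (condition required), composing the intercept and
    slope across the dummy coding and propagating the relevant covariance
    block.
    """
    if isinstance(fit, ProbitFit):
        return PsychometricEstimate(
            condition=str(condition) if condition is not None else "pooled",
            pse=fit.pse,
            se_pse=fit.se_pse,
            ci_pse=fit.ci_pse,
            jnd=fit.jnd,
            se_jnd=fit.se_jnd,
            ci_jnd=fit.ci_jnd,
        )
    if condition is None:
        raise ValueError("condition is required for a mixed fit")
    b0, b1, vv = fit.condition_coefficients(condition)
    pse, jnd, se_pse, se_jnd = _delta_pse_jnd(b0, b1, vv)
    return PsychometricEstimate(
        condition=str(condition),
        pse=pse,
        se_pse=se_pse,
        ci_pse=(pse - _Z95 * se_pse, pse + _Z95 * se_pse),
        jnd=jnd,
        se_jnd=se_jnd,
        ci_jnd=(jnd - _Z95 * se_jnd, jnd + _Z95 * se_jnd),
    )


def report_table(fit: MixedProbitFit) -> pd.DataFrame:
    """Per-condition PSE/JND table: Estimate, SE, Inferior CI, Superior CI."""
    rows = []
    for c in fit.conditions:
        est = pse_jnd_ci(fit, c)
        rows.append(
            {
                "condition": c,
                "parameter": "median",
                "Estimate": est.pse,
                "SE": est.se_pse,
                "Inferior CI": est.ci_pse[0],
                "Superior CI": est.ci_pse[1],
            }
        )
        rows.append(
            {
                "condition": c,
                "parameter": "jnd",
                "Estimate": est.jnd,
                "SE": est.se_jnd,
                "Inferior CI": est.ci_jnd[0],
                "Superior CI": est.ci_jnd[1],
            }
        )
    return pd.DataFrame(rows)


def compare_distributions(
    table_a: pd.DataFrame, table_b: pd.DataFrame | None = None, test: str = "ks", groups=None
):
    """Simple distribution comparisons of response indices for pipeline reports.

    ``test="ks"`` runs the two-sample Kolmogorov-Smirnov test (asymptotic
    p-value) between ``table_a`` and ``table_b``; ``test="kruskal_wallis"``
    runs Kruskal-Wallis across two or more samples (pass extras via
    ``groups``).  Returns (statistic, p).
    """
    a = table_a["response_index"].to_numpy()
    if test == "ks":
        if table_b is None:
            raise ValueError("KS test needs two samples")
        b = table_b["response_index"].to_numpy()
        if len(a) == 0 or len(b) == 0:
            raise ValueError("samples must be non-empty")
        if np.array_equal(np.sort(a), np.sort(b)):
            return 0.0, 1.0
        res = ks_2samp(a, b, method="asymp")
        return float(res.statistic), float(res.pvalue)
    if test == "kruskal_wallis":
        samples = [a]
        if table_b is not None:
            samples.append(table_b["response_index"].to_numpy())
        if groups is not None:
            samples.extend(np.asarray(g["response_index"]) for g in groups)
        if len(samples) < 2:
            raise ValueError("Kruskal-Wallis needs at least two samples")
        if all(np.array_equal(np.sort(samples[0]), np.sort(s)) for s in samples[1:]) and len(
            np.unique(samples[0])
        ) == 1:
            return 0.0, 1.0
        res = kruskal(*samples)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")
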