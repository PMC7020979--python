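"""Linear mixed-effects model for longitudinal contour-similarity metrics.

Model: for metric value ``y_{ijk}`` of subject *i*, series *k* (one
algorithm's trajectory over fractions), fraction ``f_j``,

    y = X beta + b_i + e,   b_i ~ N(0, sigma_b^2),
    Corr(e_j, e_j') = rho^|f_j - f_j'|  within a series, 0 across series
    (given the subject intercept), Var(e) = sigma^2.

The AR(1) correlation is indexed by fraction lag, so unbalanced schedules
(e.g. first five fractions then weekly) need no imputation. When a subject
contributes several algorithm series, serial correlation applies within each
series; series share only the subject intercept (a literal lag-0 correlation
across series would make the covariance singular).

Fitting is maximum likelihood (REML optional). The total variance scale is
profiled out analytically, leaving a 2-parameter search over
(log variance ratio, atanh rho) run from three fixed starting points with a
deterministic simplex — results are reproducible bit-for-bit. Inference on
the fixed effects is Wald-type: z = beta / SE, two-sided p, CI = beta
+/- 1.96 SE.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import solve_triangular

from .errors import ConvergenceError

Z_95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class LMESpec:
    """Model description for :func:`fit_lme`.

    ``fixed`` are numeric columns entering the design matrix alongside the
    intercept. ``fraction`` is centered internally when included. ``series``
    names the column defining within-subject longitudinal series for the
    AR(1) structure (``None`` = one series per subject).
    """

    response: str
    fixed: tuple[str, ...] = ()
    subject: str = "patient_id"
    fraction: str = "fraction"
    series: str | None = None
    reml: bool = False
    fix_rho: float | None = None
    fix_gamma: float | None = None  # variance ratio sigma_b^2/sigma^2; 0 = no intercept

    def __post_init__(self) -> None:
        if self.fix_rho is not None and not (-1.0 < self.fix_rho < 1.0):
            raise ValueError("|rho| must be < 1")
        if self.fix_gamma is not None and self.fix_gamma < 0:
            raise ValueError("variance ratio must be >= 0")


@dataclass
class LMEFit:
    """Fitted model: fixed effects with Wald inference plus variance components."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    sigma2_subject: float
    sigma2_resid: float
    rho: float
    loglik: float
    n_obs: int
    n_subjects: int
    converged: bool = True

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.se > 0, self.beta / self.se, np.inf * np.sign(self.beta))

    @property
    def p_values(self) -> np.ndarray:
        return 2.0 * stats.norm.sf(np.abs(self.z))

    @property
    def conf_int(self) -> np.ndarray:
        """(p, 2) array of 95% Wald intervals, estimate +/- 1.96 SE."""
        return np.stack([self.beta - Z_95 * self.se, self.beta + Z_95 * self.se], axis=1)

    def coefficient(self, name: str) -> dict[str, float]:
        i = self.names.index(name)
        lo, hi = self.conf_int[i]
        return {
            "estimate": float(self.beta[i]),
            "se": float(self.se[i]),
            "z": float(self.z[i]),
            "p": float(self.p_values[i]),
            "ci_low": float(lo),
            "ci_high": float(hi),
        }

    def summary(self) -> pd.DataFrame:
        ci = self.conf_int
        return pd.DataFrame(
            {
                "term": self.names,
                "estimate": self.beta,
                "se": self.se,
                "z": self.z,
                "p": self.p_values,
                "ci_low": ci[:, 0],
                "ci_high": ci[:, 1],
            }
        )


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------


def _subject_blocks(
    df: pd.DataFrame, spec: LMESpec, x: np.ndarray, y: np.ndarray
) -> dict[tuple, tuple[np.ndarray, np.ndarray]]:
    """Group per-subject design/response blocks by AR(1) pattern.

    Subjects sharing a (fraction schedule, series layout) pattern share a
    covariance matrix, so their GLS solves are batched into one triangular
    solve per pattern — the dominant cost in balanced simulation studies.
    """
    raw: dict[tuple, list[tuple[np.ndarray, np.ndarray]]] = {}
    for _, idx in df.groupby(spec.subject, sort=True).indices.items():
        idx = np.sort(np.asarray(idx))
        fr = df[spec.fraction].to_numpy(dtype=float)[idx]
        if spec.series is not None:
            ser = pd.factorize(df[spec.series].to_numpy()[idx])[0]
        else:
            ser = np.zeros(len(idx), dtype=int)
        key = (tuple(fr), tuple(ser))
        raw.setdefault(key, []).append((x[idx], y[idx]))
    return {
        key: (np.stack([b[0] for b in group]), np.stack([b[1] for b in group]))
        for key, group in raw.items()
    }


def _correlation_matrix(key: tuple, rho: float) -> np.ndarray:
    fr = np.asarray(key[0], dtype=float)
    ser = np.asarray(key[1], dtype=int)
    lag = np.abs(fr[:, None] - fr[None, :])
    same = ser[:, None] == ser[None, :]
    with np.errstate(invalid="ignore"):
        r = np.where(same, np.sign(rho) ** lag * np.abs(rho) ** lag, 0.0)
    if rho == 0.0:
        r = np.where(same & (lag == 0), 1.0, 0.0)
    np.fill_diagonal(r, 1.0)
    return r


def _profiled_negloglik(theta, blocks, p, reml, fix_rho, fix_gamma) -> float:
    return _fit_given_theta(theta, blocks, p, reml, fix_rho, fix_gamma)[0]


def _fit_given_theta(
    theta: np.ndarray,
    blocks: dict,
    p: int,
    reml: bool,
    fix_rho: float | None,
    fix_gamma: float | None,
):
    if fix_gamma is not None:
        gamma = float(fix_gamma)
    else:
        gamma = float(np.exp(np.clip(theta[0], -12.0, 12.0)))  # sigma_b^2/sigma^2
    rho = fix_rho if fix_rho is not None else float(np.tanh(theta[1]))

    xtwx = np.zeros((p, p))
    xtwy = np.zeros(p)
    n_total = 0
    logdet_sum = 0.0
    whitened: list[tuple[np.ndarray, np.ndarray]] = []
    for key, (xs, ys) in blocks.items():
        n_sub, n_b, _ = xs.shape
        w = gamma * np.ones((n_b, n_b)) + _correlation_matrix(key, rho)
        try:
            chol = np.linalg.cholesky(w)
        except np.linalg.LinAlgError:
            return np.inf, None
        # one triangular solve for every subject sharing this pattern
        rhs = np.concatenate(
            [np.moveaxis(xs, 0, 1).reshape(n_b, -1), ys.T], axis=1
        )
        sol = solve_triangular(chol, rhs, lower=True)
        lx = np.moveaxis(sol[:, : n_sub * p].reshape(n_b, n_sub, p), 0, 1)
        ly = sol[:, n_sub * p :].T
        xtwx += np.einsum("sij,sik->jk", lx, lx)
        xtwy += np.einsum("sij,si->j", lx, ly)
        whitened.append((lx, ly))
        n_total += n_sub * n_b
        logdet_sum += n_sub * 2.0 * float(np.log(np.diag(chol)).sum())

    try:
        xtwx_inv = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        return np.inf, None
    beta = xtwx_inv @ xtwy

    rss = 0.0
    for lx, ly in whitened:
        lr = ly - lx @ beta
        rss += float((lr**2).sum())

    dof = n_total - p if reml else n_total
    if rss <= 0:
        return np.inf, None
    sigma2 = rss / dof
    nll = 0.5 * (dof * np.log(2.0 * np.pi * sigma2) + logdet_sum + dof)
    if reml:
        sign, logdet_x = np.linalg.slogdet(xtwx / sigma2)
        if sign <= 0:
            return np.inf, None
        nll += 0.5 * logdet_x
    extras = (beta, xtwx_inv, sigma2, gamma, rho, n_total)
    return nll, extras


_STARTS = (
    np.array([np.log(0.5), 0.0]),
    np.array([np.log(2.0), np.arctanh(0.5)]),
    np.array([np.log(0.1), np.arctanh(-0.3)]),
)


def fit_lme(records: pd.DataFrame, spec: LMESpec) -> LMEFit:
    """Fit the mixed model by (RE)ML. Deterministic given data and spec.

    Requires >= 2 subjects and no missing response values. Raises
    :class:`ConvergenceError` if no starting point yields a finite optimum.
    """
    df = records.reset_index(drop=True)
    y = df[spec.response].to_numpy(dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("response contains missing/non-finite values")
    if df[spec.subject].nunique() < 2:
        raise ValueError("need at least 2 subjects")

    names = ["intercept"]
    cols = [np.ones(len(df))]
    for term in spec.fixed:
        v = df[term].to_numpy(dtype=float)
        if term == spec.fraction:
            v = v - v.mean()
            term = f"{term}_centered"
        names.append(term)
        cols.append(v)
    x = np.stack(cols, axis=1)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise np.linalg.LinAlgError("singular fixed-effects design")
    p = x.shape[1]

    # degenerate data: (near-)perfectly explained response -> zero-variance fit
    resid_ols = y - x @ np.linalg.lstsq(x, y, rcond=None)[0]
    scale = max(float(np.abs(y).max()), 1.0)
    if float(resid_ols @ resid_ols) <= (1e-10 * scale) ** 2 * len(y):
        beta = np.linalg.lstsq(x, y, rcond=None)[0]
        return LMEFit(
            names=names,
            beta=beta,
            se=np.zeros(p),
            sigma2_subject=0.0,
            sigma2_resid=0.0,
            rho=0.0,
            loglik=np.inf,
            n_obs=len(y),
            n_subjects=df[spec.subject].nunique(),
        )

    dup_cols = [spec.subject, spec.fraction] + (
        [spec.series] if spec.series is not None else []
    )
    if df.duplicated(subset=dup_cols).any():
        raise ValueError(
            "duplicate observations within a longitudinal series: the AR(1) "
            "correlation would be singular; split them into distinct series"
        )

    blocks = _subject_blocks(df, spec, x, y)

    # free parameters: log variance ratio (unless fixed), atanh rho (unless fixed)
    free = [i for i, fx in enumerate((spec.fix_gamma, spec.fix_rho)) if fx is None]

    def expand(t: np.ndarray) -> np.ndarray:
        theta = np.zeros(2)
        for j, i in enumerate(free):
            theta[i] = t[j]
        return theta

    if not free:
        best_theta = np.zeros(2)
        success = True
    else:
        best = None
        for start in _STARTS:
            res = optimize.minimize(
                lambda t: _profiled_negloglik(
                    expand(t), blocks, p, spec.reml, spec.fix_rho, spec.fix_gamma
                ),
                start[free],
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 400},
            )
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        if best is None:
            raise ConvergenceError("mixed-model likelihood optimization failed")
        best_theta = expand(best.x)
        success = bool(best.success)

    nll, extras = _fit_given_theta(
        best_theta, blocks, p, spec.reml, spec.fix_rho, spec.fix_gamma
    )
    beta, xtwx_inv, sigma2, gamma, rho, n_total = extras
    se = np.sqrt(np.diag(xtwx_inv) * sigma2)
    return LMEFit(
        names=names,
        beta=beta,
        se=se,
        sigma2_subject=float(gamma * sigma2),
        sigma2_resid=float(sigma2),
        rho=float(rho),
        loglik=float(-nll),
        n_obs=int(n_total),
        n_subjects=df[spec.subject].nunique(),
        converged=bool(success or np.isfinite(nll)),
    )


# ---------------------------------------------------------------------------
# High-level comparisons and summaries
# ---------------------------------------------------------------------------


@dataclass
class ComparisonResult:
    fit: LMEFit
    term: str
    significant: bool
    alpha: float

    @property
    def effect(self) -> dict[str, float]:
        return self.fit.coefficient(self.term)


def compare_algorithms(
    records: pd.DataFrame,
    algorithm_a: str,
    algorithm_b: str,
    metric: str,
    alpha: float = 0.05,
    include_modality: bool = False,
    reml: bool = False,
) -> ComparisonResult:
    """Test metric differences between two algorithms with the mixed model.

    Fits ``metric ~ intercept + 1[algorithm == b] + fraction`` (optionally a
    CBCT indicator) with subject random intercept and AR(1)-by-fraction
    errors, each algorithm forming its own longitudinal series. The verdict
    is a two-sided Wald test of the algorithm coefficient at ``alpha``.
    """
    sub = records[records["algorithm"].isin([algorithm_a, algorithm_b])].copy()
    if sub.empty:
        raise ValueError("no records for the requested algorithms")
    term = f"is_{algorithm_b}"
    sub[term] = (sub["algorithm"] == algorithm_b).astype(float)
    fixed = [term, "fraction"]
    if include_modality:
        sub["is_cbct"] = (sub["modality"] == "CBCT").astype(float)
        fixed.append("is_cbct")
    # each organ trajectory is its own AR(1) series; otherwise two organs
    # observed at the same fraction would imply a singular correlation
    sub["_series"] = sub["algorithm"].astype(str)
    if "organ" in sub.columns:
        sub["_series"] = sub["_series"] + "/" + sub["organ"].astype(str)
    spec = LMESpec(
        response=metric, fixed=tuple(fixed), series="_series", reml=reml
    )
    fit = fit_lme(sub, spec)
    eff = fit.coefficient(term)
    return ComparisonResult(
        fit=fit, term=term, significant=bool(eff["p"] < alpha), alpha=alpha
    )


def subfactor_analysis(
    records: pd.DataFrame,
    algorithms: Sequence[str],
    metrics: Sequence[str] = ("hd_mm", "mda_mm", "dsc", "jaccard"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """P-value grid for modality (CTOR vs CBCT) and fraction subfactors.

    For every algorithm x organ x metric, fits the mixed model with a CBCT
    indicator and the fraction covariate and reports both Wald p-values —
    the same layout as a per-comparison subfactor table.
    """
    rows = []
    for algorithm in algorithms:
        sub_a = records[records["algorithm"] == algorithm]
        for organ in sorted(sub_a["organ"].unique()):
            sub = sub_a[sub_a["organ"] == organ].copy()
            sub["is_cbct"] = (sub["modality"] == "CBCT").astype(float)
            for metric in metrics:
                fixed = ["fraction"]
                two_modalities = sub["is_cbct"].nunique() > 1
                if two_modalities:
                    fixed = ["is_cbct", "fraction"]
                fit = fit_lme(sub, LMESpec(response=metric, fixed=tuple(fixed)))
                p_mod = (
                    fit.coefficient("is_cbct")["p"] if two_modalities else np.nan
                )
                p_frac = fit.coefficient("fraction_centered")["p"]
                rows.append(
                    {
                        "algorithm": algorithm,
                        "organ": organ,
                        "metric": metric,
                        "p_modality": p_mod,
                        "p_fraction": p_frac,
                    }
                )
    return pd.DataFrame(rows)


def summarize_estimates(
    records: pd.DataFrame,
    grouping: Sequence[str] = ("organ", "algorithm"),
    metrics: Sequence[str] = ("hd_mm", "mda_mm", "dsc", "jaccard"),
) -> pd.DataFrame:
    """Model-based point estimates with 95% CIs per group.

    For each group (e.g. organ x algorithm), fits an intercept + fraction
    mixed model per metric; the intercept at the mean fraction is the point
    estimate shown as a bar, the Wald interval its error bar.
    """
    rows = []
    for key, sub in records.groupby(list(grouping), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        for metric in metrics:
            if sub["patient_id"].nunique() < 2:
                est = float(sub[metric].mean())
                lo = hi = est
            else:
                fit = fit_lme(sub, LMESpec(response=metric, fixed=("fraction",)))
                coef = fit.coefficient("intercept")
                est, lo, hi = coef["estimate"], coef["ci_low"], coef["ci_high"]
            rows.append(
                dict(zip(grouping, key))
                | {
                    "metric": metric,
                    "estimate": est,
                    "ci_low": lo,
                    "ci_high": hi,
                    "n": len(sub),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Simulation (calibration utility)
# ---------------------------------------------------------------------------


def simulate_longitudinal(
    n_subjects: int,
    fractions: Sequence[int],
    beta_intercept: float,
    beta_algorithm: float,
    beta_fraction: float,
    sigma_subject: float,
    sigma_resid: float,
    rho: float,
    rng: np.random.Generator,
    algorithms: tuple[str, str] = ("A", "B"),
) -> pd.DataFrame:
    """Draw one synthetic two-algorithm study from the model's own assumptions.

    Used for parameter-recovery, type-I-error and CI-coverage calibration.
    The fraction covariate enters centered, matching the fitting convention.
    """
    fractions = np.asarray(sorted(fractions), dtype=float)
    fc = fractions - fractions.mean()
    rows = []
    for i in range(n_subjects):
        b_i = rng.normal(0.0, sigma_subject)
        for algo_idx, algo in enumerate(algorithms):
            e = _draw_ar1(len(fractions), fractions, rho, sigma_resid, rng)
            mu = beta_intercept + beta_algorithm * algo_idx + beta_fraction * fc
            for j, f in enumerate(fractions):
                rows.append(
                    {
                        "patient_id": f"S{i:03d}",
                        "fraction": int(f),
                        "algorithm": algo,
                        "value": mu[j] + b_i + e[j],
                    }
                )
    return pd.DataFrame(rows)


def _draw_ar1(
    n: int, fractions: np.ndarray, rho: float, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Stationary AR(1)-by-fraction-lag noise along a (possibly gappy) schedule."""
    e = np.empty(n)
    e[0] = rng.normal(0.0, sigma)
    for j in range(1, n):
        lag = fractions[j] - fractions[j - 1]
        r = rho**lag
        e[j] = r * e[j - 1] + rng.normal(0.0, sigma * np.sqrt(max(1.0 - r**2, 0.0)))
    return e
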