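"""Causal-effect estimators for two-sample Mendelian randomization.

Per-SNP Wald ratios with delta-method standard errors; inverse-variance
weighted (IVW) and maximum-likelihood combining of a multi-allelic
instrument; the pleiotropy-robust MR-Egger and weighted-median estimators;
Cochran's Q / I² heterogeneity; leave-one-out sensitivity analysis.

Inference convention
--------------------
Combined estimates are tested against a Student t reference with L − 1
degrees of freedom (L − 2 for the MR-Egger slope and intercept), and
confidence intervals use the same t quantile.  Under the ``random`` effects
model the fixed-effects SE is scaled by sqrt(Q / (L − 1)) — multiplicative
overdispersion *without* a floor, which is exactly the scaling that makes the
t reference correct: for homogeneous normal ratio estimates the combined
z-statistic and Q are independent, so z / sqrt(Q / (L − 1)) ~ t(L − 1).
The ``auto`` model applies that scaling only when Q exceeds its degrees of
freedom (i.e. when I² > 0) and otherwise keeps the fixed-effects SE, which
matches the common fixed-effects choice when I² = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .sumstats import HarmonizedSnp

__all__ = [
    "RatioEstimate",
    "MrResult",
    "EggerResult",
    "HeterogeneityStats",
    "wald_ratio",
    "ratio_estimates",
    "combine_ivw",
    "combine_max_likelihood",
    "MlConvergenceError",
    "egger_regression",
    "weighted_median",
    "heterogeneity_stats",
    "leave_one_out",
    "scale_estimate",
    "confidence_and_p",
]


@dataclass(frozen=True)
class RatioEstimate:
    """Per-SNP Wald-ratio causal estimate (log-OR per 1 SD exposure)."""

    rsid: str
    beta: float
    se: float

    def __post_init__(self):
        if not (self.se > 0):
            raise ValueError(f"{self.rsid}: ratio se must be > 0")

    @property
    def weight(self) -> float:
        """Inverse-variance weight 1/se²."""
        return self.se ** -2


@dataclass(frozen=True)
class MrResult:
    """A combined causal estimate on the log-OR scale.

    ``ci_low``/``ci_high`` are on the OR scale (exponentiated);  ``df`` is
    the degrees of freedom of the t reference used for the p-value and CI
    (L − 1 for combined estimates, L − 2 for the Egger slope).
    """

    method: str
    effects_model: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    df: int
    n_snps: int

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    def summary_row(self) -> dict:
        return {"method": self.method, "effects_model": self.effects_model,
                "n_snps": self.n_snps, "beta": self.beta, "se": self.se,
                "or": self.odds_ratio, "ci_low": self.ci_low,
                "ci_high": self.ci_high, "pvalue": self.pvalue,
                "df": self.df}


@dataclass(frozen=True)
class EggerResult:
    """MR-Egger slope (causal estimate under InSIDE) and intercept (average
    directional-pleiotropy effect, log-odds per allele)."""

    slope: MrResult
    intercept: float
    intercept_se: float
    intercept_pvalue: float

    def __post_init__(self):
        if not (0 < self.intercept_pvalue <= 1):
            raise ValueError("intercept p-value must be in (0,1]")


@dataclass(frozen=True)
class HeterogeneityStats:
    """Cochran's Q with its chi-square p-value and the I² percentage."""

    q: float
    df: int
    pvalue: float
    i2: float


def confidence_and_p(beta: float, se: float, df: int,
                     level: float = 0.95) -> tuple[float, float, float]:
    """t-based two-sided p-value and CI bounds (log scale) for beta/se.

    With ``df < 1`` (single-SNP instrument) the p-value and CI are undefined
    and returned as NaN.
    """
    if df < 1 or se == 0:
        return math.nan, math.nan, math.nan
    q = stats.t.ppf(1 - (1 - level) / 2, df)
    p = 2 * stats.t.sf(abs(beta / se), df)
    return beta - q * se, beta + q * se, float(p)


def _result(method, effects_model, beta, se, df, n_snps, level=0.95):
    lo, hi, p = confidence_and_p(beta, se, df, level)
    return MrResult(method=method, effects_model=effects_model, beta=beta,
                    se=se, ci_low=math.exp(lo) if not math.isnan(lo) else math.nan,
                    ci_high=math.exp(hi) if not math.isnan(hi) else math.nan,
                    pvalue=p, df=df, n_snps=n_snps)


# ---------------------------------------------------------------------------
# per-SNP ratios


def wald_ratio(snp: HarmonizedSnp, order: str = "first") -> RatioEstimate:
    """Wald ratio beta_outcome / beta_exposure with delta-method SE.

    ``order="first"`` ignores exposure-side noise (se = se_Y/|beta_X|);
    ``order="second"`` adds the beta_Y² se_X² / beta_X⁴ term.
    """
    bx, by = snp.beta_exposure, snp.beta_outcome
    if bx == 0:
        raise ZeroDivisionError(f"{snp.rsid}: beta_exposure is zero, Wald "
                                "ratio undefined")
    beta = by / bx
    if order == "first":
        se = snp.se_outcome / abs(bx)
    elif order == "second":
        se = math.sqrt(snp.se_outcome ** 2 / bx ** 2
                       + by ** 2 * snp.se_exposure ** 2 / bx ** 4)
    else:
        raise ValueError(f"unknown delta-method order {order!r}")
    return RatioEstimate(rsid=snp.rsid, beta=beta, se=se)


def ratio_estimates(snps, order: str = "first"):
    return [wald_ratio(s, order) for s in snps]


# ---------------------------------------------------------------------------
# combining


def combine_ivw(ratios, effects_model: str = "auto",
                level: float = 0.95) -> MrResult:
    """Inverse-variance weighted combination of per-SNP ratio estimates.

    beta = Σ wᵢβᵢ / Σ wᵢ with wᵢ = 1/seᵢ².  See the module docstring for the
    fixed / random / auto SE conventions.  p and CI use t with L − 1 df;
    a single-ratio input returns that ratio with df 0 and NaN p/CI.
    """
    ratios = list(ratios)
    if not ratios:
        raise ValueError("combine_ivw needs at least one ratio estimate")
    b = np.array([r.beta for r in ratios])
    w = np.array([r.weight for r in ratios])
    beta = float(np.sum(w * b) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    n = len(ratios)
    df = n - 1
    q = float(np.sum(w * (b - beta) ** 2))
    if effects_model not in ("fixed", "random", "auto"):
        raise ValueError(f"unknown effects model {effects_model!r}")
    model = effects_model
    if effects_model == "auto":
        model = "random" if q > df else "fixed"
    if model == "random" and df >= 1:
        se = se_fixed * math.sqrt(q / df)
    else:
        se = se_fixed
    return _result("ivw", model, beta, se, df, n, level)


class MlConvergenceError(RuntimeError):
    """Maximum-likelihood combining failed to converge; carries the IVW
    fallback estimate in ``ivw_fallback``."""

    def __init__(self, message, ivw_fallback: MrResult):
        super().__init__(message)
        self.ivw_fallback = ivw_fallback


def combine_max_likelihood(snps, effects_model: str = "auto",
                           level: float = 0.95, tol: float = 1e-10,
                           max_iter: int = 200) -> MrResult:
    """Maximum-likelihood causal estimate from a multi-allelic instrument.

    Maximizes the independent bivariate-normal likelihood

        Π_j N(beta_Xj; γ_j, se_Xj²) · N(beta_Yj; θ γ_j, se_Yj²)

    over the L nuisance exposure effects γ and the causal effect θ, by exact
    coordinate ascent: given θ the optimal γ_j is a precision-weighted blend
    of beta_Xj and beta_Yj/θ, and given γ the optimal θ is a weighted
    regression through the origin.  θ is initialized at the IVW estimate and
    γ at beta_X.  The SE comes from the observed information matrix,
    inverting its arrowhead structure analytically.  Inference uses t with
    L − 1 df; under ``random``/``auto`` the same multiplicative
    overdispersion as :func:`combine_ivw` is applied, computed from the
    ratio-level Q.
    """
    snps = list(snps)
    if len(snps) < 2:
        raise ValueError("combine_max_likelihood needs at least 2 SNPs")
    bx = np.array([s.beta_exposure for s in snps], dtype=float)
    by = np.array([s.beta_outcome for s in snps], dtype=float)
    vx = np.array([s.se_exposure for s in snps], dtype=float) ** 2
    vy = np.array([s.se_outcome for s in snps], dtype=float) ** 2

    ivw = combine_ivw(ratio_estimates(snps), effects_model, level)
    theta = ivw.beta
    gamma = bx.copy()
    converged = False
    for _ in range(max_iter):
        gamma = (bx / vx + theta * by / vy) / (1 / vx + theta ** 2 / vy)
        theta_new = float(np.sum(gamma * by / vy) / np.sum(gamma ** 2 / vy))
        if abs(theta_new - theta) < tol:
            theta = theta_new
            converged = True
            break
        theta = theta_new
    if not converged:
        raise MlConvergenceError(
            f"ML combining did not converge in {max_iter} iterations "
            f"(last θ = {theta:.6g}); IVW fallback attached", ivw)

    gamma = (bx / vx + theta * by / vy) / (1 / vx + theta ** 2 / vy)
    # observed information: arrowhead matrix, block-invert for the θθ element
    h_tt = float(np.sum(gamma ** 2 / vy))
    h_gg = 1 / vx + theta ** 2 / vy
    h_gt = -(by - 2 * theta * gamma) / vy
    info = h_tt - float(np.sum(h_gt ** 2 / h_gg))
    if info <= 0:
        raise MlConvergenceError("observed information not positive at the "
                                 "ML optimum; IVW fallback attached", ivw)
    se = info ** -0.5
    n = len(snps)
    df = n - 1
    het = heterogeneity_stats(ratio_estimates(snps))
    model = effects_model
    if effects_model == "auto":
        model = "random" if het.q > het.df else "fixed"
    if model == "random":
        se *= math.sqrt(het.q / het.df)
    return _result("max_likelihood", model, theta, se, df, n, level)


def egger_regression(snps, level: float = 0.95,
                     _force_zero_intercept: bool = False) -> EggerResult:
    """MR-Egger: weighted regression of outcome betas on exposure betas with
    an unconstrained intercept.

    Weights are 1/se_Yj²; exposure betas must already be oriented
    non-negative.  Standard errors use multiplicative overdispersion floored
    at the homoscedastic value (scaled by max(1, residual SE)); slope and
    intercept are tested on t with L − 2 df.  The intercept estimates the
    average directional-pleiotropy effect; the slope is the causal estimate
    under the InSIDE assumption.

    ``_force_zero_intercept`` is a test hook: the through-origin weighted
    regression is algebraically identical to fixed-effects IVW.
    """
    import statsmodels.api as sm

    snps = list(snps)
    if len(snps) < 3 and not _force_zero_intercept:
        raise ValueError("egger_regression needs at least 3 SNPs")
    bx = np.array([s.beta_exposure for s in snps], dtype=float)
    by = np.array([s.beta_outcome for s in snps], dtype=float)
    w = np.array([s.se_outcome for s in snps], dtype=float) ** -2.0
    if np.any(bx < 0):
        raise ValueError("exposure betas must be oriented >= 0 before Egger "
                         "regression (harmonize first)")
    if np.allclose(bx, bx[0]):
        raise ValueError("all exposure betas identical: Egger design matrix "
                         "is rank-deficient")

    X = bx[:, None] if _force_zero_intercept else sm.add_constant(bx)
    fit = sm.WLS(by, X, weights=w).fit()
    n = len(snps)
    dof = n - X.shape[1]
    # multiplicative overdispersion floored at 1: homoscedastic (unscaled)
    # SEs times max(1, residual SE) — never deflated below the homoscedastic
    # value even when the fit is better than its weights predict
    xtwx_inv = np.linalg.inv(X.T @ (w[:, None] * X))
    rse = math.sqrt(fit.scale) if dof > 0 else 1.0
    bse = np.sqrt(np.diag(xtwx_inv)) * max(1.0, rse)

    if _force_zero_intercept:
        slope = _result("egger_slope", "fixed", float(fit.params[0]),
                        float(bse[0]), max(dof, 0), n, level)
        return EggerResult(slope=slope, intercept=0.0, intercept_se=0.0,
                           intercept_pvalue=1.0)
    slope = _result("egger_slope", "multiplicative", float(fit.params[1]),
                    float(bse[1]), dof, n, level)
    ic, ic_se = float(fit.params[0]), float(bse[0])
    if ic_se == 0:
        ic_p = 1.0 if ic == 0 else np.nextafter(0, 1)
    else:
        ic_p = float(2 * stats.t.sf(abs(ic / ic_se), dof))
    return EggerResult(slope=slope, intercept=ic, intercept_se=ic_se,
                       intercept_pvalue=max(ic_p, np.nextafter(0, 1)))


def _weighted_median_point(betas: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median: percentile positions are the cumulative
    normalized weights minus half each weight."""
    order = np.argsort(betas, kind="stable")
    b, w = betas[order], weights[order]
    w = w / w.sum()
    s = np.cumsum(w) - w / 2
    return float(np.interp(0.5, s, b))


def weighted_median(snps, n_boot: int = 10_000, seed: int = 1,
                    level: float = 0.95) -> MrResult:
    """Weighted-median causal estimate (consistent while valid instruments
    carry > 50% of the weight).

    Ratio estimates are sorted ascending (ties broken by rsid), weighted by
    inverse variance, and the estimate is linearly interpolated at the 50th
    weighted percentile.  The SE comes from a parametric bootstrap: each
    ratio is resampled from N(βᵢ, seᵢ²) ``n_boot`` times under the given
    seed.  Inference uses t with L − 1 df.
    """
    snps = list(snps)
    if len(snps) < 3:
        raise ValueError("weighted_median needs at least 3 SNPs")
    if n_boot < 100:
        raise ValueError(f"n_boot must be >= 100, got {n_boot}")
    ratios = ratio_estimates(snps)
    ratios.sort(key=lambda r: (r.beta, r.rsid))
    b = np.array([r.beta for r in ratios])
    se = np.array([r.se for r in ratios])
    w = np.array([r.weight for r in ratios])
    est = _weighted_median_point(b, w)

    rng = np.random.default_rng(seed)
    draws = rng.normal(b, se, size=(n_boot, len(b)))
    boot = np.array([_weighted_median_point(d, w) for d in draws])
    se_boot = float(np.std(boot, ddof=1))
    n = len(snps)
    return _result("weighted_median", "bootstrap", est, se_boot, n - 1, n,
                   level)


def heterogeneity_stats(ratios) -> HeterogeneityStats:
    """Cochran's Q over per-SNP ratios, its chi-square p-value and I²
    (percentage of heterogeneity beyond chance, clamped at 0)."""
    ratios = list(ratios)
    if len(ratios) < 2:
        raise ValueError("heterogeneity needs at least 2 ratio estimates")
    b = np.array([r.beta for r in ratios])
    w = np.array([r.weight for r in ratios])
    beta = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - beta) ** 2))
    df = len(ratios) - 1
    p = float(stats.chi2.sf(q, df))
    i2 = max(0.0, (q - df) / q) * 100 if q > 0 else 0.0
    return HeterogeneityStats(q=q, df=df, pvalue=p, i2=i2)


def leave_one_out(snps, estimator):
    """Re-estimate with each SNP excluded in turn.

    ``estimator`` is a callable taking a list of HarmonizedSnp (e.g.
    ``lambda s: combine_ivw(ratio_estimates(s), "fixed")``).  Returns a list
    of ``(excluded_rsid, MrResult)`` pairs, one per SNP; estimator failures
    propagate with the excluded rsid attached.
    """
    snps = list(snps)
    if len(snps) < 2:
        raise ValueError("leave_one_out needs at least 2 SNPs")
    out = []
    for i, excluded in enumerate(snps):
        subset = snps[:i] + snps[i + 1:]
        try:
            out.append((excluded.rsid, estimator(subset)))
        except Exception as exc:
            raise RuntimeError(
                f"estimator failed with {excluded.rsid} excluded: {exc}"
            ) from exc
    return out


def scale_estimate(result: MrResult, factor: float,
                   level: float = 0.95) -> MrResult:
    """Rescale a causal estimate to a different exposure unit.

    beta and se are multiplied by ``factor`` (> 0); the CI is recomputed and
    the t statistic — hence the p-value — is unchanged.
    """
    if not factor > 0:
        raise ValueError(f"scale factor must be > 0, got {factor}")
    if factor == 1:
        return result
    return _result(result.method, result.effects_model,
                   result.beta * factor, result.se * factor,
                   result.df, result.n_snps, level)
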