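"""Synthetic two-sample GWAS summary statistics and calibration studies.

The generator draws L independent instrument SNPs with true exposure effects
γ_j, then reports noisy study-level associations

    beta_Xj ~ N(γ_j, se_Xj²)        (exposure study, SD units)
    beta_Yj ~ N(θ γ_j + α_j, se_Yj²)  (outcome study, log-odds)

where θ is the causal effect and α_j a per-SNP horizontal-pleiotropy effect.
Pleiotropy regimes: none; balanced (mean-zero α, preserving IVW consistency);
directional (nonzero-mean α — biases IVW, recovered by the Egger intercept
under InSIDE); and an InSIDE-violating regime in which α is correlated with
instrument strength γ.  Only a fraction ``prop_invalid`` of SNPs receive
pleiotropy.  Pleiotropy enters at the summary level (outcome side only);
individual-level confounding is not simulated.

Default effect and SE ranges are chosen so per-SNP first-stage F statistics
(γ/se_X)² span roughly 10–100, straddling the conventional weak-instrument
boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .sumstats import HarmonizedSnp
from . import estimators as est

__all__ = [
    "Pleiotropy",
    "SimulationConfig",
    "simulate_summary_stats",
    "run_calibration",
    "CalibrationReport",
]


@dataclass(frozen=True)
class Pleiotropy:
    """Horizontal-pleiotropy regime for the outcome-side effects α_j."""

    kind: str = "none"          # none | balanced | directional | inside_violating
    mean: float = 0.0
    sd: float = 0.0
    rho: float = 0.0            # correlation with γ (inside_violating only)

    @classmethod
    def none(cls):
        return cls("none")

    @classmethod
    def balanced(cls, sd: float):
        return cls("balanced", 0.0, sd)

    @classmethod
    def directional(cls, mean: float, sd: float = 0.0):
        return cls("directional", mean, sd)

    @classmethod
    def inside_violating(cls, rho: float, sd: float):
        return cls("inside_violating", 0.0, sd, rho)

    def __post_init__(self):
        if self.kind not in ("none", "balanced", "directional",
                             "inside_violating"):
            raise ValueError(f"unknown pleiotropy kind {self.kind!r}")
        if self.sd < 0:
            raise ValueError("pleiotropy sd must be >= 0")
        if not (-1 <= self.rho <= 1):
            raise ValueError("rho must be in [-1,1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for synthetic two-sample summary statistics.

    ``gamma_dist`` is ("uniform", lo, hi) or ("normal", mean, sd) for the
    true per-SNP exposure effects (SD units per allele); ``se_*_dist`` are
    (lo, hi) uniform ranges for per-SNP reported standard errors.  With
    ``noiseless=True`` the reported SEs are still drawn but no sampling
    noise is added — the exact-recovery regime used by analytic tests.
    """

    n_snps: int = 50
    theta: float = 0.0
    gamma_dist: tuple = ("uniform", 0.04, 0.10)
    se_exposure_dist: tuple = (0.009, 0.013)
    se_outcome_dist: tuple = (0.05, 0.15)
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy.none)
    prop_invalid: float = 0.0
    noiseless: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 2:
            raise ValueError("n_snps must be >= 2")
        if not (0 <= self.prop_invalid <= 1):
            raise ValueError("prop_invalid must be in [0,1]")
        kind = self.gamma_dist[0]
        if kind == "uniform":
            lo, hi = self.gamma_dist[1:]
            if lo == hi == 0:
                raise ValueError("degenerate gamma distribution: all true "
                                 "exposure effects would be zero")
        elif kind == "normal":
            mean, sd = self.gamma_dist[1:]
            if sd < 0:
                raise ValueError("gamma sd must be >= 0")
            if mean == 0 and sd == 0:
                raise ValueError("degenerate gamma distribution: all true "
                                 "exposure effects would be zero")
        else:
            raise ValueError(f"unknown gamma distribution {kind!r}")
        for name in ("se_exposure_dist", "se_outcome_dist"):
            lo, hi = getattr(self, name)
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")


def _draw_gamma(cfg: SimulationConfig, rng) -> np.ndarray:
    kind = cfg.gamma_dist[0]
    if kind == "uniform":
        return rng.uniform(cfg.gamma_dist[1], cfg.gamma_dist[2], cfg.n_snps)
    return rng.normal(cfg.gamma_dist[1], cfg.gamma_dist[2], cfg.n_snps)


def _draw_alpha(cfg: SimulationConfig, gamma: np.ndarray, rng) -> np.ndarray:
    """Per-SNP pleiotropy, zero for the valid fraction."""
    L = cfg.n_snps
    p = cfg.pleiotropy
    alpha = np.zeros(L)
    if p.kind == "none" or cfg.prop_invalid == 0:
        return alpha
    n_invalid = int(round(cfg.prop_invalid * L))
    invalid = rng.choice(L, size=n_invalid, replace=False)
    if p.kind == "balanced":
        alpha[invalid] = rng.normal(0.0, p.sd, n_invalid)
    elif p.kind == "directional":
        alpha[invalid] = rng.normal(p.mean, p.sd, n_invalid)
    else:  # inside_violating: α correlated with instrument strength γ
        g = gamma[invalid]
        gs = np.std(g)
        z = (g - np.mean(g)) / gs if gs > 0 else np.zeros_like(g)
        alpha[invalid] = p.sd * (p.rho * z + math.sqrt(1 - p.rho ** 2)
                                 * rng.standard_normal(n_invalid))
    return alpha


def simulate_summary_stats(config: SimulationConfig):
    """Draw one synthetic harmonized two-sample dataset.

    Returns a list of :class:`HarmonizedSnp` with the exposure-orientation
    convention (beta_exposure >= 0) applied, exactly as real data leave
    :func:`mrinfer.sumstats.harmonize`.  Byte-identical across runs for a
    fixed config (including seed).
    """
    rng = np.random.default_rng(config.seed)
    gamma = _draw_gamma(config, rng)
    alpha = _draw_alpha(config, gamma, rng)
    sx = rng.uniform(*config.se_exposure_dist, config.n_snps)
    sy = rng.uniform(*config.se_outcome_dist, config.n_snps)
    if config.noiseless:
        bx = gamma.copy()
        by = config.theta * gamma + alpha
    else:
        bx = gamma + rng.normal(0.0, 1.0, config.n_snps) * sx
        by = config.theta * gamma + alpha + rng.normal(
            0.0, 1.0, config.n_snps) * sy
    # orientation convention: flip both betas so beta_exposure >= 0
    flip = bx < 0
    bx = np.abs(bx)
    by = np.where(flip, -by, by)
    eaf = rng.uniform(0.1, 0.9, config.n_snps)
    return [HarmonizedSnp(
        rsid=f"rs{j + 1:06d}", effect_allele="G", other_allele="A",
        beta_exposure=float(bx[j]), se_exposure=float(sx[j]),
        beta_outcome=float(by[j]), se_outcome=float(sy[j]),
        eaf=float(eaf[j])) for j in range(config.n_snps)]


# ---------------------------------------------------------------------------
# calibration


_ESTIMATORS = {
    "ivw": lambda snps, opt: est.combine_ivw(
        est.ratio_estimates(snps), opt.get("effects", "random")),
    "ml": lambda snps, opt: est.combine_max_likelihood(
        snps, opt.get("effects", "random")),
    "egger": lambda snps, opt: est.egger_regression(snps).slope,
    "wme": lambda snps, opt: est.weighted_median(
        snps, n_boot=opt.get("n_boot", 200), seed=opt.get("boot_seed", 1)),
}


@dataclass(frozen=True)
class CalibrationReport:
    """Monte-Carlo operating characteristics of the estimators under one
    generative configuration."""

    config: SimulationConfig
    n_reps: int
    alpha: float
    metrics: dict  # estimator -> {bias, mc_se_bias, empirical_se, rmse,
    #                              coverage, rejection_rate, mc_se_rejection,
    #                              n_failures}

    def to_dict(self) -> dict:
        cfg = asdict(self.config)
        cfg["pleiotropy"] = asdict(self.config.pleiotropy)
        return {"config": cfg, "n_reps": self.n_reps, "alpha": self.alpha,
                "metrics": self.metrics}


def run_calibration(config: SimulationConfig, estimators=("ivw",),
                    n_reps: int = 1000, seed: int | None = None,
                    alpha: float = 0.05, **options) -> CalibrationReport:
    """Repeated simulate→estimate loop.

    Per-replicate seeds are spawned from one master ``seed`` (defaults to
    the config seed) via :class:`numpy.random.SeedSequence`, so each
    replicate is independently reproducible.  Estimator failures are
    counted and excluded from the aggregates, never silently dropped.
    Coverage and rejection use each estimator's own t-based CI/p-value.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    unknown = [e for e in estimators if e not in _ESTIMATORS]
    if unknown:
        raise ValueError(f"unknown estimator(s) {unknown}; "
                         f"choose from {sorted(_ESTIMATORS)}")
    master = config.seed if seed is None else seed
    child_seeds = np.random.SeedSequence(master).generate_state(n_reps) % (2 ** 31)

    results = {e: {"beta": [], "se": [], "df": [], "p": [], "fail": 0}
               for e in estimators}
    for r in range(n_reps):
        cfg = SimulationConfig(**{**asdict(config),
                                  "pleiotropy": config.pleiotropy,
                                  "seed": int(child_seeds[r])})
        snps = simulate_summary_stats(cfg)
        for name in estimators:
            try:
                res = _ESTIMATORS[name](snps, options)
            except Exception:
                results[name]["fail"] += 1
                continue
            results[name]["beta"].append(res.beta)
            results[name]["se"].append(res.se)
            results[name]["df"].append(res.df)
            results[name]["p"].append(res.pvalue)

    metrics = {}
    for name, r in results.items():
        b = np.asarray(r["beta"])
        se = np.asarray(r["se"])
        df = np.asarray(r["df"], dtype=float)
        p = np.asarray(r["p"])
        n = len(b)
        if n == 0:
            metrics[name] = {"n_failures": r["fail"], "n_ok": 0}
            continue
        bias = float(np.mean(b) - config.theta)
        emp_se = float(np.std(b, ddof=1)) if n > 1 else math.nan
        tq = stats.t.ppf(1 - alpha / 2, df)
        cover = float(np.mean((b - tq * se <= config.theta)
                              & (config.theta <= b + tq * se)))
        rej = float(np.mean(p < alpha))
        metrics[name] = {
            "bias": bias,
            "mc_se_bias": emp_se / math.sqrt(n) if n > 1 else math.nan,
            "empirical_se": emp_se,
            "rmse": float(np.sqrt(np.mean((b - config.theta) ** 2))),
            "coverage": cover,
            "rejection_rate": rej,
            "mc_se_rejection": math.sqrt(rej * (1 - rej) / n),
            "mean_estimated_se": float(np.mean(se)),
            "n_failures": r["fail"],
            "n_ok": n,
        }
    return CalibrationReport(config=config, n_reps=n_reps, alpha=alpha,
                             metrics=metrics)
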