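"""Instrument-strength, NOME, pleiotropy-screening and power diagnostics.

A genetic instrument is only as good as the variance it explains: R² and the
first-stage F-statistic quantify strength (weak instruments attenuate
two-sample estimates toward the null), I²GX quantifies the expected
regression dilution of MR-Egger from noisy exposure effects (the NOME
assumption), and the closed-form power approximation for a binary outcome
says what effect sizes an analysis of a given size can hope to detect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "InstrumentDiagnostics",
    "PowerSpec",
    "variance_explained",
    "f_statistic",
    "i2_gx",
    "power_binary_outcome",
    "detectable_or",
    "bonferroni_screen",
    "instrument_diagnostics",
]


@dataclass(frozen=True)
class InstrumentDiagnostics:
    """Summary instrument-strength block: R², F, I²GX, SNP count."""

    r2: float
    f_stat: float
    i2_gx: float
    n_snps: int


@dataclass(frozen=True)
class PowerSpec:
    """Inputs to the binary-outcome power approximation.

    ``n_total`` combined cases + controls, ``case_fraction`` their ratio,
    ``r2`` instrument variance explained in the exposure, ``odds_ratio`` the
    causal OR per 1 SD exposure, ``alpha`` the two-sided test size.
    """

    n_total: float
    case_fraction: float
    r2: float
    odds_ratio: float = math.nan
    alpha: float = 0.05

    def __post_init__(self):
        if not self.n_total > 0:
            raise ValueError("n_total must be positive")
        if not (0 < self.case_fraction < 1):
            raise ValueError("case_fraction must be in (0,1)")
        if not (0 <= self.r2 < 1):
            raise ValueError("r2 must be in [0,1)")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0,1)")
        if not math.isnan(self.odds_ratio) and not self.odds_ratio > 0:
            raise ValueError("odds_ratio must be positive")


def variance_explained(snps) -> float:
    """Exposure variance explained by independent SNPs: Σ 2 p (1 − p) β².

    Assumes the exposure is standardized (unit variance) and betas are per
    allele in SD units.  Every SNP must carry an effect-allele frequency.
    """
    total = 0.0
    for s in snps:
        p = s.eaf
        if p is None or math.isnan(p):
            raise ValueError(f"{s.rsid}: effect-allele frequency required "
                             "for variance explained")
        beta = getattr(s, "beta_exposure", getattr(s, "beta", None))
        total += 2 * p * (1 - p) * beta ** 2
    return total


def f_statistic(r2: float, n: float, k: int) -> float:
    """First-stage F for an instrument of k SNPs explaining r2 of the
    exposure variance in a sample of n:  F = (r2/(1−r2)) · ((n−k−1)/k)."""
    if not (0 <= r2 < 1):
        raise ValueError("r2 must be in [0,1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if not n > k + 1:
        raise ValueError(f"n must exceed k+1 = {k + 1}")
    return (r2 / (1 - r2)) * ((n - k - 1) / k)


def i2_gx(snps, weighting: str = "egger") -> float:
    """NOME dilution statistic for MR-Egger, in [0, 1).

    An I²-type statistic for the exposure effects treated as a
    meta-analysis: values near 1 mean exposure-side measurement error is
    negligible and the Egger slope suffers little regression dilution.
    ``weighting="exposure"`` uses the raw beta_X with precision 1/se_X²;
    ``weighting="egger"`` evaluates the statistic on the Egger-weighted
    scale, beta_X/se_Y with measurement SE se_X/se_Y.
    """
    snps = list(snps)
    if len(snps) < 2:
        raise ValueError("i2_gx needs at least 2 SNPs")
    bx = np.array([s.beta_exposure for s in snps], dtype=float)
    sx = np.array([s.se_exposure for s in snps], dtype=float)
    if weighting == "exposure":
        x, s = bx, sx
    elif weighting == "egger":
        sy = np.array([s.se_outcome for s in snps], dtype=float)
        x, s = bx / sy, sx / sy
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    v = s ** -2.0
    xbar = np.sum(v * x) / np.sum(v)
    q = float(np.sum(v * (x - xbar) ** 2))
    df = len(snps) - 1
    return max(0.0, (q - df) / q) if q > 0 else 0.0


def power_binary_outcome(spec: PowerSpec) -> float:
    """Closed-form normal approximation of two-sample MR power for a binary
    outcome:

        power = Φ( √(n · r2 · K(1−K)) · |ln OR| − z_{1−α/2} )

    with K the case fraction.  At OR = 1 this returns α/2 (the upper
    rejection tail; the full two-sided rejection probability is α).
    """
    if math.isnan(spec.odds_ratio):
        raise ValueError("PowerSpec.odds_ratio is required for power")
    k = spec.case_fraction
    ncp = math.sqrt(spec.n_total * spec.r2 * k * (1 - k)) * abs(
        math.log(spec.odds_ratio))
    z = stats.norm.ppf(1 - spec.alpha / 2)
    return float(stats.norm.cdf(ncp - z))


def detectable_or(spec: PowerSpec, target_power: float,
                  tol: float = 1e-6) -> tuple[float, float]:
    """Smallest OR > 1 detectable at ``target_power`` (bisection on ln OR),
    with its reciprocal as the protective-direction bound."""
    if not (0 < target_power < 1):
        raise ValueError("target_power must be in (0,1)")
    if target_power <= spec.alpha:
        raise ValueError(f"target power {target_power} must exceed alpha "
                         f"{spec.alpha}: no solution")

    def power_at(log_or):
        return power_binary_outcome(
            PowerSpec(spec.n_total, spec.case_fraction, spec.r2,
                      math.exp(log_or), spec.alpha))

    lo, hi = 0.0, 1e-6
    while power_at(hi) < target_power:
        hi *= 2
        if hi > 1e3:
            raise ValueError("no detectable OR below exp(1000); check inputs")
    while hi - lo > tol:
        mid = (lo + hi) / 2
        if power_at(mid) < target_power:
            lo = mid
        else:
            hi = mid
    log_or = (lo + hi) / 2
    return math.exp(log_or), math.exp(-log_or)


def bonferroni_screen(lookups: pd.DataFrame, n_lookups_per_snp,
                      alpha: float = 0.05, exposure_traits=()):
    """Phenome-lookup pleiotropy screen with per-SNP Bonferroni thresholds.

    ``lookups`` has columns (rsid, trait, pvalue) — one row per cross-trait
    look-up; ``n_lookups_per_snp`` maps rsid to the number of look-ups
    performed for it.  Each SNP's threshold is alpha / count; a SNP is
    flagged when any association with a non-exposure trait falls below its
    threshold.  Returns ``(thresholds, flagged)``.
    """
    counts = dict(n_lookups_per_snp)
    for bad, c in counts.items():
        if c < 1:
            raise ValueError(f"{bad}: look-up count must be >= 1")
    missing = sorted(set(lookups["rsid"]) - set(counts))
    if missing:
        raise ValueError(f"no look-up count for SNP(s): {missing}")
    thresholds = {rsid: alpha / c for rsid, c in counts.items()}
    flagged = set()
    exposure_traits = set(exposure_traits)
    for _, row in lookups.iterrows():
        if row["trait"] in exposure_traits:
            continue
        if float(row["pvalue"]) < thresholds[row["rsid"]]:
            flagged.add(row["rsid"])
    return thresholds, flagged


def instrument_diagnostics(snps, n_exposure: float,
                           r2: float | None = None) -> InstrumentDiagnostics:
    """Convenience block: R² (computed from eaf/beta unless supplied),
    F-statistic at the exposure-study sample size, and Egger-weighted I²GX."""
    snps = list(snps)
    if r2 is None:
        r2 = variance_explained(snps)
    return InstrumentDiagnostics(
        r2=r2, f_stat=f_statistic(r2, n_exposure, len(snps)),
        i2_gx=i2_gx(snps, "egger"), n_snps=len(snps))
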