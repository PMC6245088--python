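"""Model / results interface for two-sample Mendelian randomization.

:class:`TwoSampleMR` is constructed from harmonized summary statistics
(directly, from a DataFrame, or from raw exposure/outcome tables which it
harmonizes); ``fit()`` dispatches to the estimators and returns a results
object carrying the estimate, its uncertainty, the heterogeneity block and a
``summary()`` table.

>>> model = TwoSampleMR(snps)
>>> res = model.fit(method="ivw", effects="auto")
>>> print(res.summary())
"""

from __future__ import annotations

import json
import math

import pandas as pd

from . import estimators as est
from . import diagnostics as diag
from .sumstats import (harmonize, harmonized_to_frame, frame_to_harmonized)

__all__ = ["TwoSampleMR", "MRResults", "EggerResults"]

_METHOD_LABELS = {
    "ivw": "Inverse-variance weighted",
    "ml": "Maximum likelihood",
    "max_likelihood": "Maximum likelihood",
    "egger": "MR-Egger",
    "egger_slope": "MR-Egger slope",
    "wme": "Weighted median",
    "weighted_median": "Weighted median",
    "wald": "Wald ratio",
}


class TwoSampleMR:
    """Two-sample MR model for one exposure/outcome pair.

    Parameters
    ----------
    snps : sequence of HarmonizedSnp
        Harmonized instrument (effect alleles oriented to the
        exposure-increasing allele).
    exposure_name, outcome_name : str
        Labels used in summaries.
    """

    def __init__(self, snps, exposure_name: str = "exposure",
                 outcome_name: str = "outcome"):
        self.snps = list(snps)
        if not self.snps:
            raise ValueError("instrument is empty")
        self.exposure_name = exposure_name
        self.outcome_name = outcome_name

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "TwoSampleMR":
        """Build from a harmonized table with columns beta_exposure,
        se_exposure, beta_outcome, se_outcome (plus rsid etc.)."""
        return cls(frame_to_harmonized(df), **kwargs)

    @classmethod
    def from_summary_tables(cls, exposure, outcome, proxy_map=None,
                            palindromic_eaf_limit: float = 0.08,
                            **kwargs) -> "TwoSampleMR":
        """Harmonize raw exposure/outcome association tables and build the
        model; dropped SNPs are kept on the instance as ``dropped``."""
        snps, dropped = harmonize(exposure, outcome, proxy_map,
                                  palindromic_eaf_limit)
        model = cls(snps, **kwargs)
        model.dropped = dropped
        return model

    # -- estimation ---------------------------------------------------------

    def ratios(self, order: str = "first"):
        """Per-SNP Wald-ratio estimates."""
        return est.ratio_estimates(self.snps, order)

    def fit(self, method: str = "ivw", effects: str = "auto",
            n_boot: int = 10_000, seed: int = 1, level: float = 0.95):
        """Fit one estimator and return a results object.

        ``method`` is one of ``"ivw"``, ``"ml"``, ``"egger"``, ``"wme"``
        (weighted median) or ``"wald"`` (single-SNP instrument).
        """
        if method == "ivw":
            r = est.combine_ivw(self.ratios(), effects, level)
        elif method == "ml":
            r = est.combine_max_likelihood(self.snps, effects, level)
        elif method == "egger":
            e = est.egger_regression(self.snps, level)
            return EggerResults(self, e)
        elif method == "wme":
            r = est.weighted_median(self.snps, n_boot, seed, level)
        elif method == "wald":
            if len(self.snps) != 1:
                raise ValueError("wald method requires a single-SNP "
                                 "instrument")
            w = est.wald_ratio(self.snps[0])
            r = est.combine_ivw([w], "fixed", level)
        else:
            raise ValueError(f"unknown method {method!r}")
        return MRResults(self, r)

    def fit_all(self, effects: str = "auto", n_boot: int = 10_000,
                seed: int = 1) -> dict:
        """Fit IVW, ML, Egger and weighted median; returns
        ``{method: results}``."""
        return {m: self.fit(m, effects=effects, n_boot=n_boot, seed=seed)
                for m in ("ivw", "ml", "egger", "wme")}

    # -- diagnostics --------------------------------------------------------

    def heterogeneity(self) -> est.HeterogeneityStats:
        return est.heterogeneity_stats(self.ratios())

    def leave_one_out(self, method: str = "ivw", effects: str = "fixed",
                      **kw):
        """Leave-one-out sensitivity analysis; list of (rsid, MrResult)."""
        if method == "ivw":
            f = lambda s: est.combine_ivw(est.ratio_estimates(s), effects)
        elif method == "ml":
            f = lambda s: est.combine_max_likelihood(s, effects)
        elif method == "wme":
            f = lambda s: est.weighted_median(s, **kw)
        else:
            raise ValueError(f"unsupported leave-one-out method {method!r}")
        return est.leave_one_out(self.snps, f)

    def diagnostics(self, n_exposure: float,
                    r2: float | None = None) -> diag.InstrumentDiagnostics:
        """Instrument strength (R², F) and NOME (I²GX) block."""
        return diag.instrument_diagnostics(self.snps, n_exposure, r2)

    def to_frame(self) -> pd.DataFrame:
        return harmonized_to_frame(self.snps)

    # -- plotting -----------------------------------------------------------

    def plot_effects(self, ax=None, fits=()):
        """Scatter of SNP-outcome vs SNP-exposure effects with 1-SE bars;
        optional fitted lines from results objects."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        f = self.to_frame()
        ax.errorbar(f.beta_exposure, f.beta_outcome, xerr=f.se_exposure,
                    yerr=f.se_outcome, fmt="o", capsize=2, color="0.3")
        xs = [0, f.beta_exposure.max() * 1.05]
        for res in fits:
            if isinstance(res, EggerResults):
                ys = [res.intercept + res.beta * x for x in xs]
            else:
                ys = [res.beta * x for x in xs]
            ax.plot(xs, ys, label=_METHOD_LABELS.get(res.method, res.method))
        ax.axhline(0, lw=0.5, color="0.7")
        ax.set_xlabel(f"SNP effect on {self.exposure_name} (SD units)")
        ax.set_ylabel(f"SNP effect on {self.outcome_name} (log odds)")
        if fits:
            ax.legend(frameon=False)
        return ax


class MRResults:
    """Results wrapper: point estimate, uncertainty, heterogeneity and a
    text summary."""

    def __init__(self, model: TwoSampleMR, result: est.MrResult):
        self.model = model
        self._result = result

    # delegate the MrResult fields
    def __getattr__(self, name):
        return getattr(self._result, name)

    @property
    def result(self) -> est.MrResult:
        return self._result

    def conf_int(self) -> tuple[float, float]:
        """CI on the OR scale."""
        return self._result.ci_low, self._result.ci_high

    def heterogeneity(self) -> est.HeterogeneityStats:
        return self.model.heterogeneity()

    def scaled(self, factor: float) -> "MRResults":
        """Rescale to a different exposure unit (see
        :func:`mrinfer.estimators.scale_estimate`)."""
        return MRResults(self.model, est.scale_estimate(self._result, factor))

    def to_dict(self) -> dict:
        d = self._result.summary_row()
        if self._result.n_snps >= 2:
            het = self.heterogeneity()
            d["heterogeneity"] = {"q": het.q, "df": het.df,
                                  "pvalue": het.pvalue, "i2": het.i2}
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def summary(self) -> str:
        r = self._result
        lines = [
            "Two-sample Mendelian randomization",
            f"  exposure: {self.model.exposure_name}    "
            f"outcome: {self.model.outcome_name}",
            f"  method: {_METHOD_LABELS.get(r.method, r.method)} "
            f"({r.effects_model})    SNPs: {r.n_snps}",
            "-" * 64,
            f"  beta = {r.beta:+.4f}  se = {r.se:.4f}  "
            f"OR = {r.odds_ratio:.3f} ({r.ci_low:.3f}, {r.ci_high:.3f})",
            f"  t({r.df}) p = {_fmt_p(r.pvalue)}",
        ]
        if r.n_snps >= 2:
            het = self.heterogeneity()
            lines.append(f"  Cochran's Q = {het.q:.3f} (df {het.df}, "
                         f"p = {_fmt_p(het.pvalue)})   I² = {het.i2:.1f}%")
        return "\n".join(lines)

    def __repr__(self):
        r = self._result
        return (f"<MRResults {r.method} OR={r.odds_ratio:.3f} "
                f"CI=({r.ci_low:.3f},{r.ci_high:.3f}) p={_fmt_p(r.pvalue)}>")


class EggerResults(MRResults):
    """MR-Egger results: slope (causal estimate under InSIDE) plus the
    directional-pleiotropy intercept test."""

    def __init__(self, model: TwoSampleMR, egger: est.EggerResult):
        super().__init__(model, egger.slope)
        self.egger = egger

    @property
    def intercept(self) -> float:
        return self.egger.intercept

    @property
    def intercept_se(self) -> float:
        return self.egger.intercept_se

    @property
    def intercept_pvalue(self) -> float:
        return self.egger.intercept_pvalue

    def to_dict(self) -> dict:
        d = super().to_dict()
        d["intercept"] = {"estimate": self.intercept,
                          "se": self.intercept_se,
                          "or": math.exp(self.intercept),
                          "pvalue": self.intercept_pvalue}
        return d

    def summary(self) -> str:
        return (super().summary() + "\n"
                f"  intercept = {self.intercept:+.5f} "
                f"(se {self.intercept_se:.5f}, "
                f"p = {_fmt_p(self.intercept_pvalue)}) "
                "— test for directional pleiotropy")


def _fmt_p(p) -> str:
    if p is None or (isinstance(p, float) and math.isnan(p)):
        return "NA"
    return f"{p:.2e}" if p < 1e-3 else f"{p:.3f}"
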