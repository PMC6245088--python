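"""GWAS summary-statistic data model, TSV I/O, OR↔log-OR conversion and
two-sample harmonization.

Two-sample Mendelian randomization consumes one association table per trait
(exposure and outcome), one row per SNP.  Before any causal estimation the two
tables must be *harmonized*: each exposure SNP matched to its outcome row
(directly or through a proxy), effect alleles aligned — flipping the outcome
beta when the studies reported opposite alleles — and every row oriented so
that the effect allele is the exposure-increasing allele (``beta_exposure >=
0``).  Palindromic variants (A/T, C/G) whose strand cannot be resolved from
allele frequency are dropped with an explicit reason rather than silently
mis-aligned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SnpAssociation",
    "HarmonizedSnp",
    "OrCi",
    "beta_se_from_or_ci",
    "or_ci_from_beta_se",
    "harmonize",
    "HarmonizationError",
    "read_summary_table",
    "write_summary_table",
    "harmonized_to_frame",
    "frame_to_harmonized",
    "read_proxy_map",
]

_BASES = {"A", "C", "G", "T"}
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical TSV headers for a summary-association table
CANONICAL_COLUMNS = ("rsid", "chr", "effect_allele", "other_allele",
                     "eaf", "beta", "se", "pval", "n")
_REQUIRED = ("rsid", "effect_allele", "other_allele", "beta", "se")


class HarmonizationError(ValueError):
    """Raised when exposure/outcome alleles at a matched rsid cannot be
    reconciled by flipping or strand complement."""


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's association with one trait in one study.

    ``beta`` is per copy of ``effect_allele``: SD units for a continuous
    exposure, log-odds for a binary outcome.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    chromosome: str = ""
    eaf: float = math.nan
    pvalue: float = math.nan
    n: float = math.nan

    def __post_init__(self):
        ea = self.effect_allele.upper()
        oa = self.other_allele.upper()
        object.__setattr__(self, "effect_allele", ea)
        object.__setattr__(self, "other_allele", oa)
        if ea not in _BASES or oa not in _BASES:
            raise ValueError(f"{self.rsid}: alleles must be one of A/C/G/T, "
                             f"got {ea}/{oa}")
        if ea == oa:
            raise ValueError(f"{self.rsid}: effect and other allele identical")
        if not (self.se > 0):
            raise ValueError(f"{self.rsid}: se must be > 0, got {self.se}")
        if not _is_missing(self.eaf) and not (0 < self.eaf < 1):
            raise ValueError(f"{self.rsid}: eaf must be in (0,1), got {self.eaf}")
        if not _is_missing(self.pvalue) and not (0 < self.pvalue <= 1):
            raise ValueError(f"{self.rsid}: pvalue must be in (0,1]")

    @property
    def is_palindromic(self) -> bool:
        return _COMPLEMENT[self.effect_allele] == self.other_allele


@dataclass(frozen=True)
class HarmonizedSnp:
    """Exposure and outcome effects for one SNP on a shared effect allele.

    The effect allele is oriented to the exposure-increasing allele, hence
    ``beta_exposure >= 0``.  ``proxy_of`` carries the original exposure rsid
    when the outcome row came from a proxy SNP.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    eaf: float = math.nan
    proxy_of: str = ""
    flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.beta_exposure < 0:
            raise ValueError(f"{self.rsid}: beta_exposure must be >= 0 after "
                             "orientation")
        if not (self.se_exposure > 0 and self.se_outcome > 0):
            raise ValueError(f"{self.rsid}: standard errors must be > 0")


@dataclass(frozen=True)
class OrCi:
    """An odds ratio with its confidence interval, as printed in a results
    table."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    df: float = math.inf  # inf => normal quantiles, else Student t

    def __post_init__(self):
        if self.odds_ratio <= 0 or self.ci_low <= 0 or self.ci_high <= 0:
            raise ValueError("odds ratio and CI bounds must be positive")
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("CI must bracket the odds ratio")
        if not (0 < self.level < 1):
            raise ValueError(f"invalid coverage level {self.level}")


def _quantile(level: float, df: float) -> float:
    if not (0 < level < 1):
        raise ValueError(f"invalid coverage level {level}")
    p = 1 - (1 - level) / 2
    if math.isinf(df):
        return float(stats.norm.ppf(p))
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    return float(stats.t.ppf(p, df))


def beta_se_from_or_ci(cell: OrCi) -> tuple[float, float]:
    """Invert a printed OR (CI) cell to (log-OR, SE).

    ``se = (ln ci_high - ln ci_low) / (2 q)`` with ``q`` the two-sided
    quantile for the cell's coverage level and quantile kind.  A degenerate
    (zero-width) CI yields ``se = 0``.
    """
    q = _quantile(cell.level, cell.df)
    beta = math.log(cell.odds_ratio)
    se = (math.log(cell.ci_high) - math.log(cell.ci_low)) / (2 * q)
    return beta, se


def or_ci_from_beta_se(beta: float, se: float, level: float = 0.95,
                       df: float = math.inf) -> OrCi:
    """Render (log-OR, SE) as an OR with its CI; inverse of
    :func:`beta_se_from_or_ci`."""
    if se < 0:
        raise ValueError(f"se must be >= 0, got {se}")
    q = _quantile(level, df)
    return OrCi(odds_ratio=math.exp(beta),
                ci_low=math.exp(beta - q * se),
                ci_high=math.exp(beta + q * se),
                level=level, df=df)


# ---------------------------------------------------------------------------
# harmonization


def _alleles_match(ea1, oa1, ea2, oa2):
    """Return 'same', 'flipped' or None for two allele pairs."""
    if (ea1, oa1) == (ea2, oa2):
        return "same"
    if (ea1, oa1) == (oa2, ea2):
        return "flipped"
    return None


def _complement_assoc(a: SnpAssociation) -> SnpAssociation:
    return replace(a, effect_allele=_COMPLEMENT[a.effect_allele],
                   other_allele=_COMPLEMENT[a.other_allele])


def _flip_outcome(a: SnpAssociation) -> SnpAssociation:
    return replace(a, effect_allele=a.other_allele,
                   other_allele=a.effect_allele, beta=-a.beta,
                   eaf=math.nan if _is_missing(a.eaf) else 1 - a.eaf)


def harmonize(exposure, outcome, proxy_map=None,
              palindromic_eaf_limit: float = 0.08):
    """Match exposure SNPs to outcome rows and align effect alleles.

    Parameters
    ----------
    exposure, outcome : sequence of SnpAssociation
        rsids must be unique within each table.
    proxy_map : mapping rsid -> rsid, optional
        Substitute outcome rsid to use when an exposure SNP is absent from
        the outcome table (the harmonized row carries the proxy rsid and
        records the original in ``proxy_of``).
    palindromic_eaf_limit : float
        A/T and C/G SNPs are strand-ambiguous; they are dropped when the
        effect-allele frequency is missing or within this distance of 0.5.

    Returns
    -------
    (harmonized, dropped)
        ``harmonized`` is a list of :class:`HarmonizedSnp` oriented so that
        ``beta_exposure >= 0``; ``dropped`` is a list of ``(rsid, reason)``
        pairs.  Every exposure SNP appears in exactly one of the two.
    """
    proxy_map = dict(proxy_map or {})
    for name, table in (("exposure", exposure), ("outcome", outcome)):
        ids = [s.rsid for s in table]
        if len(ids) != len(set(ids)):
            dup = sorted({r for r in ids if ids.count(r) > 1})
            raise ValueError(f"duplicate rsid(s) in {name} table: {dup}")
    out_by_rsid = {s.rsid: s for s in outcome}

    harmonized, dropped = [], []
    for exp in exposure:
        proxy_of = ""
        out = out_by_rsid.get(exp.rsid)
        if out is None and exp.rsid in proxy_map:
            out = out_by_rsid.get(proxy_map[exp.rsid])
            if out is not None:
                proxy_of = exp.rsid
        if out is None:
            dropped.append((exp.rsid, "no outcome match"))
            continue

        flags = set()
        if exp.is_palindromic:
            eaf = exp.eaf if not _is_missing(exp.eaf) else out.eaf
            if _is_missing(eaf) or abs(eaf - 0.5) < palindromic_eaf_limit:
                dropped.append((exp.rsid, "palindromic, frequency-ambiguous"))
                continue
            flags.add("palindromic")
            # direct and complemented matches are indistinguishable; align by
            # allele labels first, then check frequency concordance
            rel = _alleles_match(exp.effect_allele, exp.other_allele,
                                 out.effect_allele, out.other_allele)
            if rel is None:
                dropped.append((exp.rsid, "allele mismatch"))
                continue
            if rel == "flipped":
                out = _flip_outcome(out)
            if (not _is_missing(exp.eaf) and not _is_missing(out.eaf)
                    and (exp.eaf - 0.5) * (out.eaf - 0.5) < 0):
                out = _flip_outcome(out)  # frequencies disagree: other strand
                out = _complement_assoc(out)
                flags.add("strand_flipped")
        else:
            rel = _alleles_match(exp.effect_allele, exp.other_allele,
                                 out.effect_allele, out.other_allele)
            if rel is None:
                comp = _complement_assoc(out)
                rel = _alleles_match(exp.effect_allele, exp.other_allele,
                                     comp.effect_allele, comp.other_allele)
                if rel is None:
                    raise HarmonizationError(
                        f"{exp.rsid}: alleles {exp.effect_allele}/"
                        f"{exp.other_allele} (exposure) cannot be reconciled "
                        f"with {out.effect_allele}/{out.other_allele} "
                        "(outcome) by flip or strand complement")
                out = comp
                flags.add("strand_flipped")
            if rel == "flipped":
                out = _flip_outcome(out)

        # orient to the exposure-increasing allele
        bx, by = exp.beta, out.beta
        ea, oa = exp.effect_allele, exp.other_allele
        eaf = exp.eaf
        if bx < 0:
            bx, by = -bx, -by
            ea, oa = oa, ea
            eaf = math.nan if _is_missing(eaf) else 1 - eaf
        harmonized.append(HarmonizedSnp(
            rsid=out.rsid if proxy_of else exp.rsid,
            effect_allele=ea, other_allele=oa,
            beta_exposure=bx, se_exposure=exp.se,
            beta_outcome=by, se_outcome=out.se,
            eaf=eaf, proxy_of=proxy_of, flags=frozenset(flags)))
    return harmonized, dropped


# ---------------------------------------------------------------------------
# TSV I/O


def read_summary_table(path, column_map=None):
    """Read a tab-separated summary-association table.

    ``column_map`` maps file headers to canonical names (e.g. ``{"EA":
    "effect_allele"}``).  Missing values may be empty or ``"."``.  Parse
    failures are reported with 1-based line numbers.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["", "."],
                     keep_default_na=False)
    if column_map:
        df = df.rename(columns=dict(column_map))
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")

    records, errors = [], []
    for idx, row in df.iterrows():
        line = idx + 2  # header is line 1
        kwargs = {}
        try:
            for col, attr in (("eaf", "eaf"), ("beta", "beta"), ("se", "se"),
                              ("pval", "pvalue"), ("n", "n")):
                if col in df.columns and not pd.isna(row[col]):
                    kwargs[attr] = float(row[col])
            records.append(SnpAssociation(
                rsid=row["rsid"],
                chromosome="" if "chr" not in df.columns or pd.isna(row["chr"])
                else str(row["chr"]),
                effect_allele=row["effect_allele"],
                other_allele=row["other_allele"],
                **kwargs))
        except (ValueError, TypeError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise ValueError(f"{path}: " + "; ".join(errors))
    ids = [r.rsid for r in records]
    dups = sorted({r for r in ids if ids.count(r) > 1})
    if dups:
        raise ValueError(f"{path}: duplicate rsid(s) {dups}")
    return records


def write_summary_table(records, path):
    """Write SnpAssociation records as canonical-header TSV (row order kept)."""
    df = pd.DataFrame([{
        "rsid": r.rsid, "chr": r.chromosome,
        "effect_allele": r.effect_allele, "other_allele": r.other_allele,
        "eaf": r.eaf, "beta": r.beta, "se": r.se,
        "pval": r.pvalue, "n": r.n} for r in records],
        columns=list(CANONICAL_COLUMNS))
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def harmonized_to_frame(snps) -> pd.DataFrame:
    """Tabular view of harmonized SNPs (one row per SNP)."""
    return pd.DataFrame([{
        "rsid": s.rsid, "effect_allele": s.effect_allele,
        "other_allele": s.other_allele, "eaf": s.eaf,
        "beta_exposure": s.beta_exposure, "se_exposure": s.se_exposure,
        "beta_outcome": s.beta_outcome, "se_outcome": s.se_outcome,
        "proxy_of": s.proxy_of} for s in snps])


def frame_to_harmonized(df: pd.DataFrame):
    """Inverse of :func:`harmonized_to_frame`."""
    out = []
    for _, row in df.iterrows():
        out.append(HarmonizedSnp(
            rsid=row["rsid"],
            effect_allele=row.get("effect_allele", "G"),
            other_allele=row.get("other_allele", "A"),
            beta_exposure=float(row["beta_exposure"]),
            se_exposure=float(row["se_exposure"]),
            beta_outcome=float(row["beta_outcome"]),
            se_outcome=float(row["se_outcome"]),
            eaf=float(row["eaf"]) if "eaf" in row and not pd.isna(row["eaf"])
            else math.nan,
            proxy_of="" if "proxy_of" not in row or pd.isna(row["proxy_of"])
            else str(row["proxy_of"])))
    return out


def read_proxy_map(path):
    """Read a two-column (source_rsid, proxy_rsid) TSV into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = list(df.columns[:2])
    return dict(zip(df[cols[0]], df[cols[1]]))
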