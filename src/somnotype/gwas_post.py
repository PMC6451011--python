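"""GWAS summary-statistic post-processing.

Threshold accounting, allele alignment, per-locus variance explained,
directional-consistency (exact binomial sign) tests, fixed-effect
inverse-variance meta-analysis, combined lead-SNP effects and the genomic
inflation factor.  A packaged 47-row association table ships as an in-repo
fixture (`load_table3`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GwasHit",
    "MetaResult",
    "SumstatsError",
    "read_sumstats",
    "load_table3",
    "hits_to_frame",
    "count_below",
    "variance_explained",
    "trait_variance_explained",
    "align_to_increasing",
    "sign_consistency_test",
    "ivw_meta",
    "combined_effect_test",
    "lambda_gc",
    "effect_in_minutes",
    "STRINGENT_P",
]

# stricter genome-wide threshold accounting for the number of approximately
# independent variants and the eight traits analysed
STRINGENT_P = 8e-10

_REQUIRED = ["SNP", "CHR", "BP", "EA", "OA", "FREQ", "BETA", "SE", "P"]


class SumstatsError(ValueError):
    """Schema or row-level error in a summary-statistics file."""


@dataclass(frozen=True)
class GwasHit:
    """One summary-statistic row (effects on the inverse-normal trait scale)."""

    snp_id: str
    chrom: str
    bp: int
    ea: str
    oa: str
    eaf: float
    beta: float
    se: float
    p: float
    log10_p: float
    trait: str = ""
    gene: str = ""

    def validate(self) -> None:
        if not 0.0 < self.eaf < 1.0:
            raise SumstatsError(f"{self.snp_id}: FREQ must be in (0, 1)")
        if self.se <= 0:
            raise SumstatsError(f"{self.snp_id}: SE must be positive")
        if not 0.0 < self.p <= 1.0:
            raise SumstatsError(f"{self.snp_id}: P must be in (0, 1]")
        if self.ea == self.oa:
            raise SumstatsError(f"{self.snp_id}: EA and OA must differ")


def _parse_p(text: str) -> tuple[float, float]:
    """Parse a P value, accepting scientific shorthand like ``2E-35``.

    Returns (p, log10 p); log10 is computed from mantissa/exponent so tiny
    values survive even when closer to the float64 underflow limit.
    """
    s = str(text).strip()
    try:
        p = float(s)
    except ValueError as exc:
        raise SumstatsError(f"unparseable P value: {text!r}") from exc
    if p <= 0 or p > 1:
        raise SumstatsError(f"P value out of (0, 1]: {text!r}")
    up = s.upper()
    if "E" in up:
        mant, expo = up.split("E", 1)
        log10p = math.log10(float(mant)) + float(expo)
    else:
        log10p = math.log10(p)
    return p, log10p


def read_sumstats(path: str | Path) -> list[GwasHit]:
    """Read a tab-delimited summary-statistics file into validated hits.

    Required columns: SNP CHR BP EA OA FREQ BETA SE P (TRAIT and GENE are
    carried through when present).  Malformed rows are reported with their
    1-based file line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise SumstatsError(f"{path.name}: missing required column(s) {missing}")
    hits: list[GwasHit] = []
    errors: list[str] = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            p, log10p = _parse_p(row["P"])
            hit = GwasHit(
                snp_id=str(row["SNP"]),
                chrom=str(row["CHR"]),
                bp=int(row["BP"]),
                ea=str(row["EA"]).upper(),
                oa=str(row["OA"]).upper(),
                eaf=float(row["FREQ"]),
                beta=float(row["BETA"]),
                se=float(row["SE"]),
                p=p,
                log10_p=log10p,
                trait=str(row["TRAIT"]) if "TRAIT" in df.columns else "",
                gene=str(row["GENE"]) if "GENE" in df.columns else "",
            )
            hit.validate()
            hits.append(hit)
        except (SumstatsError, ValueError) as exc:
            errors.append(f"line {line}: {exc}")
    if errors:
        raise SumstatsError(f"{path.name}: " + "; ".join(errors))
    return hits


def load_table3() -> list[GwasHit]:
    """The packaged 47-row association-table fixture."""
    with resources.as_file(resources.files("somnotype.data") / "table3.tsv") as p:
        return read_sumstats(p)


def hits_to_frame(hits: list[GwasHit]) -> pd.DataFrame:
    return pd.DataFrame([vars(h) for h in hits])


def count_below(hits: list[GwasHit], p_threshold: float, trait: str | None = None) -> int:
    """Number of hits with P strictly below the threshold (optionally for
    one trait)."""
    if not 0.0 < p_threshold < 1.0:
        raise ValueError("p_threshold must be in (0, 1)")
    log_thr = math.log10(p_threshold)
    return sum(
        1
        for h in hits
        if (trait is None or h.trait == trait) and h.log10_p < log_thr
    )


def variance_explained(eaf, beta):
    """Variance of a unit-variance trait explained by one variant:
    ``2 f (1 - f) beta^2``."""
    eaf = np.asarray(eaf, dtype=float)
    beta = np.asarray(beta, dtype=float)
    out = 2.0 * eaf * (1.0 - eaf) * beta**2
    return float(out) if out.ndim == 0 else out


def trait_variance_explained(hits: list[GwasHit], trait: str) -> float:
    """Sum of per-variant variance explained over one trait's lead SNPs."""
    sub = [h for h in hits if h.trait == trait]
    if not sub:
        raise ValueError(f"no hits for trait {trait!r}")
    return float(sum(variance_explained(h.eaf, h.beta) for h in sub))


def align_to_increasing(hit: GwasHit) -> GwasHit:
    """Orient a hit to its trait-increasing allele (idempotent): a negative
    beta swaps alleles, flips the frequency and negates the effect."""
    if hit.beta >= 0:
        return hit
    return replace(hit, ea=hit.oa, oa=hit.ea, eaf=1.0 - hit.eaf, beta=-hit.beta)


def sign_consistency_test(k: int, n: int, sided: str = "one") -> float:
    """Exact binomial tail probability of >= k directionally consistent
    results out of n at chance 1/2; two-sided doubles the tail (capped at 1)."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    one = float(stats.binom.sf(k - 1, n, 0.5))
    if sided == "one":
        return one
    if sided == "two":
        return min(1.0, 2.0 * one)
    raise ValueError(f"sided must be 'one' or 'two', got {sided!r}")


@dataclass(frozen=True)
class MetaResult:
    beta: float
    se: float
    p: float
    n_studies: int
    q: float


def ivw_meta(betas, ses) -> MetaResult:
    """Fixed-effect inverse-variance meta-analysis with Wald p-value."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size < 1:
        raise ValueError("need at least one study")
    if np.any(ses <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    q = float(np.sum(w * (betas - beta) ** 2))
    p = float(2.0 * stats.norm.sf(abs(beta) / se)) if beta != 0 else 1.0
    return MetaResult(beta=beta, se=se, p=p, n_studies=int(betas.size), q=q)


def combined_effect_test(betas, ses) -> MetaResult:
    """Pool aligned per-SNP effects on one trait into a single overall
    effect (fixed-effect inverse-variance).  Inputs must already be oriented
    to the trait-increasing allele."""
    betas = np.asarray(betas, dtype=float)
    if betas.size < 2:
        raise ValueError("combined effect needs >= 2 lead SNPs")
    if np.any(betas < 0):
        raise ValueError("effects must be aligned to the trait-increasing allele (no negative betas)")
    return ivw_meta(betas, ses)


_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # 0.454936... (prints as 0.4549)


def lambda_gc(p_values) -> float:
    """Genomic inflation factor: median association chi-square (1 d.f.)
    divided by the null median."""
    p = np.asarray(p_values, dtype=float)
    if p.size < 1:
        raise ValueError("need at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must be in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / _CHI2_1_MEDIAN)


def effect_in_minutes(beta_sd: float, trait_sd_hours: float) -> float:
    """Convert an SD-scale effect to minutes using the trait SD in hours."""
    if trait_sd_hours <= 0:
        raise ValueError("trait_sd_hours must be positive")
    return beta_sd * trait_sd_hours * 60.0
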