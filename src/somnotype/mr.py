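"""Two-sample Mendelian-randomisation estimators and instrument pruning.

Estimators: inverse-variance weighted (IVW) mean of per-variant Wald ratios
(with multiplicative random-effects scaling when over-dispersed), MR-Egger
(free-intercept weighted regression), and the (penalised) weighted median.
Instrument QC: per-variant Cochran's Q contributions with iterative removal
of variants exceeding the Bonferroni-corrected chi-square(1) threshold.

Ratio-variance conventions: "first_order" uses ``se_out / |b_exp|``;
"second_order" adds the exposure-error term
``b_out^2 se_exp^2 / b_exp^4``.  Estimation defaults to first-order weights;
pruning defaults to second-order (both configurable).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MrInstrument",
    "MrEstimate",
    "wald_ratio",
    "ivw",
    "egger",
    "weighted_median",
    "cochran_q",
    "prune_instruments",
    "harmonise",
    "read_instruments",
    "run_all",
]


@dataclass(frozen=True)
class MrInstrument:
    """Harmonised per-variant exposure and outcome effects (same effect
    allele on both sides)."""

    snp_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float

    def validate(self) -> None:
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ValueError(f"{self.snp_id}: standard errors must be positive")


@dataclass
class MrEstimate:
    method: str
    estimate: float
    se: float
    p: float
    n_instruments_used: int
    excluded_snps: list[str] = field(default_factory=list)
    intercept: float | None = None
    intercept_se: float | None = None
    q: float | None = None


def _arrays(instruments: list[MrInstrument]) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    bx = np.array([i.beta_exposure for i in instruments])
    sx = np.array([i.se_exposure for i in instruments])
    by = np.array([i.beta_outcome for i in instruments])
    sy = np.array([i.se_outcome for i in instruments])
    return bx, sx, by, sy


def wald_ratio(instrument: MrInstrument) -> tuple[float, float]:
    """Per-variant causal ratio ``b_out / b_exp`` with first-order SE
    ``se_out / |b_exp|``."""
    instrument.validate()
    if instrument.beta_exposure == 0:
        raise ValueError(f"{instrument.snp_id}: Wald ratio undefined for beta_exposure = 0")
    est = instrument.beta_outcome / instrument.beta_exposure
    se = instrument.se_outcome / abs(instrument.beta_exposure)
    return est, se


def _ratio_se(bx, sx, by, sy, weights: str) -> np.ndarray:
    if weights == "first_order":
        return sy / np.abs(bx)
    if weights == "second_order":
        return np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
    raise ValueError(f"unknown weight scheme {weights!r}")


def ivw(
    instruments: list[MrInstrument],
    random_effects: bool = True,
    weights: str = "first_order",
) -> MrEstimate:
    """Inverse-variance-weighted mean of Wald ratios.

    With a single instrument this degenerates to the Wald ratio itself
    (documented deviation from the >=2 contract so the estimator family is
    total on any pruned set).  Under over-dispersion (Q/(n-1) > 1) the SE is
    scaled multiplicatively.
    """
    if len(instruments) < 1:
        raise ValueError("ivw needs at least one instrument (see wald_ratio)")
    for inst in instruments:
        inst.validate()
        if inst.beta_exposure == 0:
            raise ValueError(f"{inst.snp_id}: beta_exposure = 0; drop via wald_ratio precondition")
    bx, sx, by, sy = _arrays(instruments)
    r = by / bx
    se_r = _ratio_se(bx, sx, by, sy, weights)
    w = 1.0 / se_r**2
    est = float(np.sum(w * r) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    q = float(np.sum(w * (r - est) ** 2))
    n = len(instruments)
    if random_effects and n > 1:
        scale = max(1.0, math.sqrt(q / (n - 1)))
        se *= scale
    p = float(2.0 * stats.norm.sf(abs(est) / se))
    return MrEstimate(method="ivw", estimate=est, se=se, p=p, n_instruments_used=n, q=q)


def egger(instruments: list[MrInstrument]) -> MrEstimate:
    """MR-Egger: weighted regression of outcome on exposure effects with a
    free intercept (mean directional pleiotropy).

    Instruments are oriented so every exposure effect is non-negative; the
    residual scale is floored at 1 (multiplicative random effects).
    """
    if len(instruments) < 3:
        raise ValueError("egger needs at least three instruments")
    bx, sx, by, sy = _arrays(instruments)
    flip = np.sign(bx)
    flip[flip == 0] = 1.0
    bx, by = bx * flip, by * flip
    w = 1.0 / sy**2
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ by)
    resid = by - X @ coef
    dof = len(instruments) - 2
    sigma2 = max(1.0, float(np.sum(w * resid**2) / dof))
    cov = sigma2 * np.linalg.inv(xtwx)
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    p = float(2.0 * stats.norm.sf(abs(slope) / se_slope))
    return MrEstimate(
        method="egger",
        estimate=slope,
        se=se_slope,
        p=p,
        n_instruments_used=len(instruments),
        intercept=intercept,
        intercept_se=se_int,
        q=float(np.sum(w * resid**2)),
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted 50th percentile with the interpolation convention of the
    weighted-median MR estimator."""
    order = np.argsort(values)
    v = values[order]
    w = weights[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= np.sum(w)
    if cum[0] >= 0.5:
        return float(v[0])
    if cum[-1] <= 0.5:
        return float(v[-1])
    k = int(np.searchsorted(cum, 0.5, side="right")) - 1
    frac = (0.5 - cum[k]) / (cum[k + 1] - cum[k])
    return float(v[k] + frac * (v[k + 1] - v[k]))


def weighted_median(
    instruments: list[MrInstrument],
    penalised: bool = False,
    n_boot: int = 2000,
    seed: int = 0,
    penalty: float = 20.0,
    weights: str = "first_order",
) -> MrEstimate:
    """(Penalised) weighted-median estimator.

    Weights are inverse ratio variances; the penalised variant down-weights
    each instrument by ``min(1, penalty x p_i)`` where ``p_i`` is the
    chi-square(1) tail of its one-degree-of-freedom Q contribution about the
    unpenalised weighted-median estimate.  SE by parametric bootstrap.
    """
    if len(instruments) < 3:
        raise ValueError("weighted_median needs at least three instruments")
    bx, sx, by, sy = _arrays(instruments)

    def estimate_once(bxs, bys) -> float:
        r = bys / bxs
        se_r = _ratio_se(bxs, sx, bys, sy, weights)
        w = 1.0 / se_r**2
        est0 = _weighted_median(r, w)
        if not penalised:
            return est0
        qi = w * (r - est0) ** 2
        pi = stats.chi2.sf(qi, df=1)
        wp = w * np.minimum(1.0, penalty * pi)
        if np.sum(wp) == 0:
            return est0
        return _weighted_median(r, wp)

    est = estimate_once(bx, by)
    if n_boot >= 2:
        rng = np.random.default_rng(seed)
        boots = np.empty(n_boot)
        for b in range(n_boot):
            bxb = rng.normal(bx, sx)
            byb = rng.normal(by, sy)
            bxb[bxb == 0] = 1e-12
            boots[b] = estimate_once(bxb, byb)
        se = float(np.std(boots, ddof=1))
        p = float(2.0 * stats.norm.sf(abs(est) / se)) if se > 0 else float(est == 0)
    else:  # n_boot=0 skips the bootstrap (point estimate only, e.g. simulations)
        se = float("nan")
        p = float("nan")
    return MrEstimate(
        method="penalised_weighted_median" if penalised else "weighted_median",
        estimate=float(est),
        se=se,
        p=p,
        n_instruments_used=len(instruments),
    )


def cochran_q(
    instruments: list[MrInstrument],
    estimate: float,
    weights: str = "first_order",
) -> tuple[np.ndarray, float]:
    """Per-instrument heterogeneity contributions ``q_i = w_i (r_i - est)^2``
    and their total Q (chi-square with n-1 d.f. under homogeneity)."""
    if len(instruments) < 2:
        raise ValueError("cochran_q needs at least two instruments")
    bx, sx, by, sy = _arrays(instruments)
    r = by / bx
    se_r = _ratio_se(bx, sx, by, sy, weights)
    w = 1.0 / se_r**2
    qi = w * (r - estimate) ** 2
    return qi, float(np.sum(qi))


def prune_instruments(
    instruments: list[MrInstrument],
    alpha: float = 0.05,
    weights: str = "second_order",
) -> tuple[list[MrInstrument], list[str]]:
    """Iteratively drop the most heterogeneous instrument while its Q
    contribution exceeds the Bonferroni-corrected chi-square(1) quantile
    ``chi2.ppf(1 - alpha/n, 1)`` (n = current set size)."""
    if len(instruments) < 3:
        raise ValueError("prune_instruments needs at least three instruments")
    current = list(instruments)
    excluded: list[str] = []
    while True:
        n = len(current)
        if n < 2:
            raise ValueError(f"pruning left fewer than two instruments; removed: {excluded}")
        est = ivw(current, random_effects=False, weights=weights).estimate
        qi, _ = cochran_q(current, est, weights=weights)
        threshold = float(stats.chi2.ppf(1.0 - alpha / n, df=1))
        worst = int(np.argmax(qi))
        if qi[worst] <= threshold:
            return current, excluded
        excluded.append(current[worst].snp_id)
        current.pop(worst)


def harmonise(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    maf_ambiguous: float = 0.42,
) -> list[MrInstrument]:
    """Match exposure and outcome rows on SNP, flip outcome effects when the
    effect alleles are swapped, and drop strand-ambiguous (palindromic)
    variants with minor-allele frequency above ``maf_ambiguous``.

    Both frames need columns SNP, EA, OA, FREQ, BETA, SE.
    """
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    out = outcome.set_index("SNP")
    instruments: list[MrInstrument] = []
    for _, row in exposure.iterrows():
        snp = row["SNP"]
        if snp not in out.index:
            continue
        ea, oa = str(row["EA"]).upper(), str(row["OA"]).upper()
        if comp.get(ea) == oa:  # palindromic
            maf = min(float(row["FREQ"]), 1.0 - float(row["FREQ"]))
            if maf > maf_ambiguous:
                continue
        o = out.loc[snp]
        oea, ooa = str(o["EA"]).upper(), str(o["OA"]).upper()
        if (oea, ooa) == (ea, oa):
            b_out = float(o["BETA"])
        elif (oea, ooa) == (oa, ea):
            b_out = -float(o["BETA"])
        elif (comp.get(oea), comp.get(ooa)) == (ea, oa):
            b_out = float(o["BETA"])
        elif (comp.get(oea), comp.get(ooa)) == (oa, ea):
            b_out = -float(o["BETA"])
        else:
            continue  # allele mismatch
        instruments.append(
            MrInstrument(
                snp_id=str(snp),
                beta_exposure=float(row["BETA"]),
                se_exposure=float(row["SE"]),
                beta_outcome=b_out,
                se_outcome=float(o["SE"]),
            )
        )
    return instruments


def read_instruments(path: str | Path) -> list[MrInstrument]:
    """Tab-delimited instrument file: SNP, beta_exp, se_exp, beta_out, se_out."""
    df = pd.read_csv(path, sep="\t")
    required = ["SNP", "beta_exp", "se_exp", "beta_out", "se_out"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"instrument file missing columns {missing}")
    instruments = [
        MrInstrument(
            snp_id=str(r.SNP),
            beta_exposure=float(r.beta_exp),
            se_exposure=float(r.se_exp),
            beta_outcome=float(r.beta_out),
            se_outcome=float(r.se_out),
        )
        for r in df.itertuples()
    ]
    for inst in instruments:
        inst.validate()
    return instruments


def run_all(
    instruments: list[MrInstrument],
    methods: tuple[str, ...] = ("ivw", "egger", "wm", "pwm"),
    prune: bool = False,
    seed: int = 0,
) -> dict:
    """Run the requested estimators (optionally after pruning) and return a
    JSON-serialisable report."""
    excluded: list[str] = []
    used = list(instruments)
    if prune:
        used, excluded = prune_instruments(instruments)
    report: dict = {"n_input": len(instruments), "excluded_snps": excluded, "estimates": {}}
    runners = {
        "ivw": lambda: ivw(used),
        "egger": lambda: egger(used),
        "wm": lambda: weighted_median(used, penalised=False, seed=seed),
        "pwm": lambda: weighted_median(used, penalised=True, seed=seed),
    }
    for m in methods:
        if m not in runners:
            raise ValueError(f"unknown method {m!r}")
        e = runners[m]()
        e.excluded_snps = excluded
        report["estimates"][m] = {
            "estimate": e.estimate,
            "se": e.se,
            "p": e.p,
            "n_instruments_used": e.n_instruments_used,
            "intercept": e.intercept,
            "intercept_se": e.intercept_se,
            "q": e.q,
        }
    if len(used) >= 2:
        est = ivw(used, random_effects=False)
        qi, q_total = cochran_q(used, est.estimate)
        report["q_total"] = q_total
        report["q_per_snp"] = {inst.snp_id: float(v) for inst, v in zip(used, qi)}
    return report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2))
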