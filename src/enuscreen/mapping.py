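"""Automated meiotic mapping: per-allele logistic regression with Wald tests.

For each ENU allele in a pedigree the binary phenotype of the scored G3
cohort is regressed on a numeric genotype encoding — recessive (0,0,1),
dominant (0,1,1), or additive (0,1,2) for (REF, HET, HOM) — and a two-sided
Wald p-value is computed from the genotype coefficient.  An allele is called
significant when its p-value under any fitted model clears the per-pedigree
Bonferroni threshold ``alpha / (number of alleles tested)``.

Maximum likelihood is computed by iteratively reweighted least squares on
the counts aggregated by genotype level (the sufficient statistics for this
one-predictor model, so the fit is exact and fast).  Fully penetrant causal
alleles produce quasi-complete separation, under which the MLE diverges; such
fits are detected (non-convergence, runaway coefficients, or a singular
information matrix) and refit with Firth's penalized likelihood, which keeps
estimates and standard errors finite.  The fit method is flagged on every
test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2

from .genome import GeneticMap, chrom_sort_key
from .simulate import AFFECTED, GENOTYPES, HET, HOM, MISSING, REF, Pedigree, UNAFFECTED

__all__ = [
    "InheritanceModel",
    "RECESSIVE",
    "DOMINANT",
    "ADDITIVE",
    "get_model",
    "AlleleTest",
    "MappingResult",
    "FitResult",
    "DegenerateFitError",
    "FitConvergenceError",
    "EmptyCohortError",
    "encode_genotypes",
    "fit_logistic",
    "wald_p",
    "map_pedigree",
    "manhattan_table",
]

P_FLOOR = 1e-300  # display floor so -log10(p) stays finite

# |beta| beyond this is taken as a diverging MLE (quasi-complete separation)
_BETA_DIVERGED = 15.0


@dataclass(frozen=True)
class InheritanceModel:
    """A named numeric encoding of (REF, HET, HOM) genotypes."""

    name: str
    encoding: tuple[float, float, float]

    def encoding_map(self) -> dict[str, float]:
        return {REF: self.encoding[0], HET: self.encoding[1], HOM: self.encoding[2]}


RECESSIVE = InheritanceModel("recessive", (0.0, 0.0, 1.0))
DOMINANT = InheritanceModel("dominant", (0.0, 1.0, 1.0))
ADDITIVE = InheritanceModel("additive", (0.0, 1.0, 2.0))
_MODELS = {m.name: m for m in (RECESSIVE, DOMINANT, ADDITIVE)}


def get_model(model: "InheritanceModel | str") -> InheritanceModel:
    if isinstance(model, InheritanceModel):
        return model
    try:
        return _MODELS[model]
    except KeyError:
        raise ValueError(f"unknown inheritance model {model!r}") from None


class DegenerateFitError(Exception):
    """Constant phenotype or constant predictor: the test is skipped (p = 1)."""


class FitConvergenceError(Exception):
    """Neither IRLS nor the Firth fallback produced a usable fit."""


class EmptyCohortError(Exception):
    """The pedigree has no scored G3 mice to map."""


def encode_genotypes(calls: Sequence[str], model: "InheritanceModel | str") -> np.ndarray:
    """Map genotype calls to the model's numeric encoding; MISSING becomes NaN.

    Mice with NaN predictors are dropped from that allele's test downstream.
    """
    model = get_model(model)
    table = model.encoding_map()
    table[MISSING] = math.nan
    out = np.empty(len(calls), dtype=float)
    for i, call in enumerate(calls):
        try:
            out[i] = table[call]
        except KeyError:
            raise ValueError(f"unknown genotype call {call!r}") from None
    return out


@dataclass(frozen=True)
class FitResult:
    intercept: float
    coefficient: float
    se_intercept: float
    se_coefficient: float
    method: str  # "IRLS" | "Firth"


def _aggregate(y: np.ndarray, x: np.ndarray):
    """Collapse to counts per unique predictor level (the sufficient statistics)."""
    levels, inverse = np.unique(x, return_inverse=True)
    trials = np.bincount(inverse, minlength=levels.size).astype(float)
    successes = np.bincount(inverse, weights=y, minlength=levels.size)
    X = np.column_stack([np.ones_like(levels), levels])
    return X, trials, successes


def _loglik(X, beta, trials, successes) -> float:
    eta = X @ beta
    return float(np.sum(successes * eta - trials * np.logaddexp(0.0, eta)))


def _information(X, beta, trials):
    p = expit(X @ beta)
    w = trials * p * (1.0 - p)
    return (X * w[:, None]).T @ X, p, w


def _irls(X, trials, successes, max_iter=50, tol=1e-10):
    """Newton-Raphson MLE on aggregated binomial counts.

    Returns (beta, se) on success or (beta, None) when the fit failed or the
    MLE is diverging, in which case the caller falls back to Firth.
    """
    total_rate = (successes.sum() + 0.5) / (trials.sum() + 1.0)
    beta = np.array([math.log(total_rate / (1.0 - total_rate)), 0.0])
    ll = _loglik(X, beta, trials, successes)
    converged = False
    for _ in range(max_iter):
        info, p, _ = _information(X, beta, trials)
        score = X.T @ (successes - trials * p)
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            return beta, None
        new_beta = beta + step
        new_ll = _loglik(X, new_beta, trials, successes)
        for _ in range(25):  # step halving if the full Newton step overshoots
            if new_ll >= ll - 1e-13:
                break
            step = step / 2.0
            new_beta = beta + step
            new_ll = _loglik(X, new_beta, trials, successes)
        beta, ll = new_beta, new_ll
        if np.max(np.abs(beta)) > _BETA_DIVERGED:
            return beta, None
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    if not converged:
        return beta, None
    info, _, _ = _information(X, beta, trials)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return beta, None
    se = np.sqrt(np.diag(cov))
    if not np.all(np.isfinite(se)) or np.any(se <= 0):
        return beta, None
    return beta, se


def _penalized_loglik(X, beta, trials, successes) -> float:
    info, _, _ = _information(X, beta, trials)
    sign, logdet = np.linalg.slogdet(info)
    if sign <= 0:
        return -math.inf
    return _loglik(X, beta, trials, successes) + 0.5 * logdet


def _firth(X, trials, successes, max_iter=200, tol=1e-9):
    """Firth's penalized-likelihood logistic fit on aggregated counts.

    The modified score is U*(b) = X' (y - m p + h (1/2 - p)) with h the hat
    diagonal aggregated per genotype level; the Jeffreys penalty keeps the
    maximizer finite under separation.
    """
    total_rate = (successes.sum() + 0.5) / (trials.sum() + 1.0)
    beta = np.array([math.log(total_rate / (1.0 - total_rate)), 0.0])
    pll = _penalized_loglik(X, beta, trials, successes)
    cov = None
    for _ in range(max_iter):
        info, p, w = _information(X, beta, trials)
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            raise FitConvergenceError("singular information matrix in Firth fit")
        hat = w * np.einsum("ij,jk,ik->i", X, cov, X)
        score = X.T @ (successes - trials * p + hat * (0.5 - p))
        step = cov @ score
        new_beta = beta + step
        new_pll = _penalized_loglik(X, new_beta, trials, successes)
        for _ in range(30):
            if new_pll >= pll - 1e-13:
                break
            step = step / 2.0
            new_beta = beta + step
            new_pll = _penalized_loglik(X, new_beta, trials, successes)
        delta = np.max(np.abs(new_beta - beta))
        beta, pll = new_beta, new_pll
        if delta < tol:
            break
    info, _, _ = _information(X, beta, trials)
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        raise FitConvergenceError("singular information matrix at Firth optimum")
    se = np.sqrt(np.diag(cov))
    if not np.all(np.isfinite(beta)) or not np.all(np.isfinite(se)) or np.any(se <= 0):
        raise FitConvergenceError("Firth fit produced non-finite estimates")
    return beta, se


def fit_logistic(phenotypes: Sequence[float], predictor: Sequence[float]) -> FitResult:
    """Fit ``logit P(affected) = b0 + b1 * x`` by maximum likelihood.

    NaN predictor entries (missing genotypes) are dropped together with their
    phenotypes.  On detected separation or non-convergence the model is refit
    with Firth's penalized likelihood and the result flagged ``method="Firth"``.

    Raises :class:`DegenerateFitError` when the phenotype or predictor is
    constant (the test is meaningless; callers record p = 1), and
    ``ValueError`` on malformed input.
    """
    y = np.asarray(phenotypes, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("phenotypes and predictor must be 1-d arrays of equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    y, x = y[keep], x[keep]
    if y.size < 2:
        raise ValueError("need at least 2 observations after removing missing values")
    if not np.all((y == 0.0) | (y == 1.0)):
        raise ValueError("phenotypes must be binary 0/1")
    if np.all(y == y[0]) or np.all(x == x[0]):
        raise DegenerateFitError("constant phenotype or constant predictor")

    X, trials, successes = _aggregate(y, x)
    beta, se = _irls(X, trials, successes)
    if se is not None:
        return FitResult(float(beta[0]), float(beta[1]), float(se[0]), float(se[1]), "IRLS")
    beta, se = _firth(X, trials, successes)
    return FitResult(float(beta[0]), float(beta[1]), float(se[0]), float(se[1]), "Firth")


def wald_p(coefficient: float, standard_error: float) -> float:
    """Two-sided Wald p: the squared z statistic against chi-square(1).

    Clipped into (0, 1]; a zero coefficient gives exactly 1.
    """
    if not (math.isfinite(standard_error) and standard_error > 0):
        raise ValueError(f"standard error must be positive and finite, got {standard_error}")
    if not math.isfinite(coefficient):
        raise ValueError(f"coefficient must be finite, got {coefficient}")
    z2 = (coefficient / standard_error) ** 2
    p = float(chi2.sf(z2, df=1))
    return min(max(p, P_FLOOR), 1.0)


@dataclass(frozen=True)
class AlleleTest:
    """One allele under one inheritance model."""

    allele_id: str
    chrom: str
    pos_cM: float
    model: str
    coefficient: float
    standard_error: float
    wald_p: float
    method: str  # "IRLS" | "Firth" | "degenerate"
    n_by_genotype: dict[str, int] = field(default_factory=dict)


@dataclass
class MappingResult:
    """All per-allele tests for one pedigree plus the Bonferroni call."""

    pedigree_id: str
    tests: list[AlleleTest]
    n_alleles_tested: int
    alpha: float
    threshold: float
    significant_alleles: list[str]

    def significant_tests(self) -> list[AlleleTest]:
        return [t for t in self.tests if t.wald_p <= self.threshold]

    def best_test(self) -> AlleleTest | None:
        """The minimal-p significant test (labels the mapped locus), or None."""
        sig = self.significant_tests()
        if not sig:
            return None
        return min(sig, key=lambda t: (t.wald_p, chrom_sort_key(t.chrom), t.pos_cM))


def map_pedigree(
    pedigree: Pedigree,
    alpha: float = 0.05,
    models: Iterable["InheritanceModel | str"] = (RECESSIVE, DOMINANT),
    per_model_bonferroni: bool = False,
) -> MappingResult:
    """Run the meiotic-mapping association test on one pedigree.

    Tests every allele under every requested model over scored G3 mice only
    (dead and unscored mice are excluded).  The Bonferroni threshold is
    ``alpha / n_alleles`` — the number of alleles in the panel, not alleles
    times models — unless ``per_model_bonferroni`` asks for the stricter
    denominator.  Tests are ordered by chromosome then position.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    model_list = [get_model(m) for m in models]
    if not model_list:
        raise ValueError("need at least one inheritance model")
    cohort = pedigree.scored_g3()
    if not cohort:
        raise EmptyCohortError(f"pedigree {pedigree.pedigree_id!r} has no scored G3 mice")

    y = np.array([1.0 if m.phenotype == AFFECTED else 0.0 for m in cohort])
    alleles = sorted(
        pedigree.alleles, key=lambda a: (chrom_sort_key(a.locus.chrom), a.locus.pos_cM)
    )
    n_alleles = len(pedigree.alleles)
    denominator = n_alleles * (len(model_list) if per_model_bonferroni else 1)
    threshold = alpha / denominator

    tests: list[AlleleTest] = []
    for allele in alleles:
        calls = [m.genotypes.get(allele.allele_id, MISSING) for m in cohort]
        counts = {g: 0 for g in GENOTYPES}
        for c in calls:
            if c not in counts:
                raise ValueError(f"unknown genotype call {c!r}")
            counts[c] += 1
        for model in model_list:
            x = encode_genotypes(calls, model)
            try:
                fit = fit_logistic(y, x)
                p = wald_p(fit.coefficient, fit.se_coefficient)
            except DegenerateFitError:
                tests.append(
                    AlleleTest(allele.allele_id, allele.locus.chrom, allele.locus.pos_cM,
                               model.name, 0.0, math.nan, 1.0, "degenerate", counts)
                )
                continue
            except FitConvergenceError:
                tests.append(
                    AlleleTest(allele.allele_id, allele.locus.chrom, allele.locus.pos_cM,
                               model.name, 0.0, math.nan, 1.0, "degenerate", counts)
                )
                continue
            tests.append(
                AlleleTest(allele.allele_id, allele.locus.chrom, allele.locus.pos_cM,
                           model.name, fit.coefficient, fit.se_coefficient, p,
                           fit.method, counts)
            )

    significant: list[str] = []
    for allele in alleles:
        if any(t.wald_p <= threshold for t in tests if t.allele_id == allele.allele_id):
            significant.append(allele.allele_id)

    return MappingResult(
        pedigree_id=pedigree.pedigree_id,
        tests=tests,
        n_alleles_tested=n_alleles,
        alpha=alpha,
        threshold=threshold,
        significant_alleles=significant,
    )


def manhattan_table(result: MappingResult, genetic_map: GeneticMap | None = None) -> pd.DataFrame:
    """Tabular Manhattan output: one record per allele per model.

    Columns: chrom, pos_cM, allele_id, model, neg_log10_p, significant —
    sorted by chromosome (map order when a map is given, natural label order
    otherwise) then ascending position.  p is floored at 1e-300 so the
    -log10 transform stays finite.
    """
    if not result.tests:
        raise ValueError("mapping result has no tests")
    records = [
        {
            "chrom": t.chrom,
            "pos_cM": t.pos_cM,
            "allele_id": t.allele_id,
            "model": t.model,
            "neg_log10_p": -math.log10(max(t.wald_p, P_FLOOR)),
            "significant": bool(t.wald_p <= result.threshold),
        }
        for t in result.tests
    ]
    df = pd.DataFrame.from_records(records)
    if genetic_map is not None:
        key = df["chrom"].map(genetic_map.order_index)
    else:
        key = df["chrom"].map(chrom_sort_key)
    df = (
        df.assign(_key=key)
        .sort_values(["_key", "pos_cM", "allele_id", "model"], kind="mergesort")
        .drop(columns="_key")
        .reset_index(drop=True)
    )
    return df
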