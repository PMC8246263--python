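"""Screen-level analytics: penetrance, classification, Wilcoxon, saturation, power.

A pedigree is "affected" when at least two of its scored G3 mice carry the
phenotype, and "mapped" when the mapping test called at least one allele
significant after the per-pedigree Bonferroni correction.  The minimal-p
significant allele labels the mapped locus (co-segregating passengers are
visible in the full test table); its model attributes the pedigree as
recessive or dominant.  Penetrance is the affected fraction among scored
mice of a genotype class.  Reported percentages are rounded half-up at the
conventional precision (one decimal for screen-level percentages, zero for
penetrance percentages); raw fractions are always retained.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .config import SimulationConfig
from .genome import GeneticMap, Locus
from .mapping import MappingResult, map_pedigree
from .simulate import (
    AFFECTED,
    DAMAGING_CLASSES,
    HET,
    HOM,
    PhenotypeModel,
    Pedigree,
    assign_phenotypes,
    breed_pedigree,
    generate_allele_panel,
)

__all__ = [
    "PenetranceEstimate",
    "UndefinedPenetranceError",
    "penetrance",
    "ScreenSummary",
    "classify_pedigrees",
    "penetrance_distribution",
    "WilcoxonResult",
    "wilcoxon_rank_sum",
    "SaturationResult",
    "saturation_count",
    "hom_examined_table",
    "power_curve",
    "round_half_up",
]


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (so 0.5 always rounds away from zero)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


class UndefinedPenetranceError(Exception):
    """No scored G3 mouse of the requested genotype class exists."""


@dataclass(frozen=True)
class PenetranceEstimate:
    fraction: float
    n_affected: int
    n_scored: int

    @property
    def percent(self) -> float:
        """Percentage rounded half-up to zero decimals (e.g. 15/21 -> 71)."""
        return round_half_up(100.0 * self.fraction, 0)


def penetrance(pedigree: Pedigree, allele_id: str, genotype_class: str) -> PenetranceEstimate:
    """Affected fraction among scored G3 mice of ``genotype_class`` at an allele."""
    if genotype_class not in (HET, HOM):
        raise ValueError(f"genotype class must be HET or HOM, got {genotype_class!r}")
    if allele_id not in pedigree.allele_ids:
        raise KeyError(f"allele {allele_id!r} not in pedigree {pedigree.pedigree_id!r}")
    in_class = [
        m for m in pedigree.scored_g3() if m.genotypes.get(allele_id) == genotype_class
    ]
    if not in_class:
        raise UndefinedPenetranceError(
            f"no scored G3 mouse is {genotype_class} at {allele_id!r}"
        )
    n_affected = sum(1 for m in in_class if m.phenotype == AFFECTED)
    return PenetranceEstimate(n_affected / len(in_class), n_affected, len(in_class))


@dataclass
class ScreenSummary:
    """Counts and percentages summarizing one screen."""

    n_pedigrees: int = 0
    n_affected_pedigrees: int = 0
    percent_affected_pedigrees: float = 0.0
    n_mapped: int = 0
    percent_mapped_among_affected: float = 0.0
    n_mapped_recessive: int = 0
    n_mapped_dominant: int = 0
    n_mapped_recessive_penetrance_ge_080: int = 0
    percent_mapped_recessive_penetrance_ge_080: float = 0.0
    affected_counts_mapped: list[int] = field(default_factory=list)
    affected_counts_unmapped: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "n_pedigrees": self.n_pedigrees,
            "n_affected_pedigrees": self.n_affected_pedigrees,
            "percent_affected_pedigrees": self.percent_affected_pedigrees,
            "n_mapped": self.n_mapped,
            "percent_mapped_among_affected": self.percent_mapped_among_affected,
            "n_mapped_recessive": self.n_mapped_recessive,
            "n_mapped_dominant": self.n_mapped_dominant,
            "n_mapped_recessive_penetrance_ge_080": self.n_mapped_recessive_penetrance_ge_080,
            "percent_mapped_recessive_penetrance_ge_080": self.percent_mapped_recessive_penetrance_ge_080,
            "affected_counts_mapped": list(self.affected_counts_mapped),
            "affected_counts_unmapped": list(self.affected_counts_unmapped),
        }


def _percent(numerator: int, denominator: int, ndigits: int, what: str) -> float:
    if denominator == 0:
        if numerator:
            raise ValueError(f"{what}: nonzero numerator over zero denominator")
        warnings.warn(f"{what}: zero denominator, reporting 0.0", stacklevel=3)
        return 0.0
    return round_half_up(100.0 * numerator / denominator, ndigits)


def classify_pedigrees(
    pedigrees: Sequence[Pedigree],
    mapping_results: Mapping[str, MappingResult],
    min_affected: int = 2,
    penetrance_threshold: float = 0.8,
) -> ScreenSummary:
    """Classify a screen into affected / mapped pedigrees and summarize.

    ``mapping_results`` maps pedigree id to its :class:`MappingResult`; only
    affected pedigrees need an entry (an affected pedigree without one counts
    as unmapped).  Recessive/dominant attribution follows the model of the
    minimal-p significant allele; the HOM penetrance at that allele feeds the
    high-penetrance tally, with undefined penetrances excluded under a
    warning.
    """
    affected_peds = [p for p in pedigrees if p.n_affected_g3() >= min_affected]
    n_mapped = n_rec = n_dom = 0
    rec_penetrances: list[float | None] = []
    counts_mapped: list[int] = []
    counts_unmapped: list[int] = []

    for ped in affected_peds:
        result = mapping_results.get(ped.pedigree_id)
        n_aff = ped.n_affected_g3()
        best = result.best_test() if result is not None else None
        if best is None:
            counts_unmapped.append(n_aff)
            continue
        n_mapped += 1
        counts_mapped.append(n_aff)
        if best.model == "recessive":
            n_rec += 1
            try:
                rec_penetrances.append(penetrance(ped, best.allele_id, HOM).fraction)
            except UndefinedPenetranceError:
                rec_penetrances.append(None)
        elif best.model == "dominant":
            n_dom += 1

    n_ge, n_defined, _ = penetrance_distribution(rec_penetrances, penetrance_threshold)

    return ScreenSummary(
        n_pedigrees=len(pedigrees),
        n_affected_pedigrees=len(affected_peds),
        percent_affected_pedigrees=_percent(
            len(affected_peds), len(pedigrees), 1, "percent affected pedigrees"
        ),
        n_mapped=n_mapped,
        percent_mapped_among_affected=_percent(
            n_mapped, len(affected_peds), 1, "percent mapped among affected"
        ),
        n_mapped_recessive=n_rec,
        n_mapped_dominant=n_dom,
        n_mapped_recessive_penetrance_ge_080=n_ge,
        percent_mapped_recessive_penetrance_ge_080=_percent(
            n_ge, n_defined, 0, "percent mapped recessive with high penetrance"
        ) if n_defined else 0.0,
        affected_counts_mapped=counts_mapped,
        affected_counts_unmapped=counts_unmapped,
    )


def penetrance_distribution(
    penetrances: Iterable[float | None], threshold: float = 0.8
) -> tuple[int, int, float]:
    """(count at/above threshold, count defined, fraction) over pedigree penetrances.

    ``None`` entries (undefined penetrance) are excluded with a warning.
    """
    values = list(penetrances)
    defined = [v for v in values if v is not None]
    if len(defined) < len(values):
        warnings.warn(
            f"excluding {len(values) - len(defined)} pedigree(s) with undefined penetrance",
            stacklevel=2,
        )
    if not defined:
        return 0, 0, 0.0
    n_ge = sum(1 for v in defined if v >= threshold)
    return n_ge, len(defined), n_ge / len(defined)


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float  # rank sum of the first group, mid-ranks for ties
    p_value: float
    method: str  # "exact" | "normal-approximation"


def _exact_two_sided_p(ranks: np.ndarray, n_a: int, statistic: float) -> float:
    """Exact two-sided p for the rank-sum via DP over doubled mid-ranks.

    Mid-ranks are multiples of 1/2, so doubling makes them integers and the
    permutation distribution of the rank sum is countable exactly even with
    ties: dp[k, s] = number of size-k subsets of the doubled ranks summing
    to s.
    """
    r2 = np.rint(ranks * 2).astype(np.int64)
    n = r2.size
    total = int(r2.sum())
    dp = np.zeros((n_a + 1, total + 1))
    dp[0, 0] = 1.0
    for r in r2:
        r = int(r)
        for k in range(n_a, 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    mean2 = n_a * (n + 1)  # doubled expectation of the rank sum
    dev = abs(2.0 * statistic - mean2)
    sums = np.arange(total + 1)
    extreme = np.abs(sums - mean2) >= dev - 1e-9
    count = float(dp[n_a, extreme].sum())
    n_subsets = float(math.comb(n, n_a))
    return min(1.0, count / n_subsets)


def wilcoxon_rank_sum(
    group_a: Sequence[float], group_b: Sequence[float], exact_max_n: int = 25
) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum test with mid-ranks for ties.

    Exact by enumeration of the permutation distribution when the combined
    sample size is at most ``exact_max_n``; otherwise a normal approximation
    with tie-corrected variance and continuity correction.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    ranks = rankdata(combined)
    statistic = float(ranks[: a.size].sum())
    n = combined.size

    if n <= exact_max_n:
        p = _exact_two_sided_p(ranks, a.size, statistic)
        return WilcoxonResult(statistic, p, "exact")

    mu = a.size * (n + 1) / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var = a.size * b.size / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return WilcoxonResult(statistic, 1.0, "normal-approximation")
    z = (statistic - mu - 0.5 * np.sign(statistic - mu)) / math.sqrt(var)
    p = min(max(2.0 * float(norm.sf(abs(z))), 1e-300), 1.0)
    return WilcoxonResult(statistic, p, "normal-approximation")


@dataclass(frozen=True)
class SaturationResult:
    n_genes_hit: int
    n_genes_observed: int
    gene_universe_size: int
    fraction: float


def saturation_count(
    allele_table: "pd.DataFrame | Iterable[tuple[str, str, int]]",
    gene_universe_size: int,
    damaging_classes: Iterable[str] = DAMAGING_CLASSES,
    min_hom_examined: int = 2,
) -> SaturationResult:
    """Fraction of the gene universe hit by a damaging allele examined >= 2x HOM.

    ``allele_table`` has one row per allele: (gene_id, effect_class,
    n_hom_examined).  A gene counts when any of its alleles is of a damaging
    class and was examined in the homozygous state at least
    ``min_hom_examined`` times.
    """
    if isinstance(allele_table, pd.DataFrame):
        rows = list(
            allele_table[["gene_id", "effect_class", "n_hom_examined"]].itertuples(index=False)
        )
    else:
        rows = [tuple(r) for r in allele_table]
    damaging = frozenset(damaging_classes)
    genes = {r[0] for r in rows}
    if gene_universe_size < len(genes):
        raise ValueError(
            f"gene universe ({gene_universe_size}) smaller than observed gene set ({len(genes)})"
        )
    hit = {r[0] for r in rows if r[1] in damaging and int(r[2]) >= min_hom_examined}
    fraction = len(hit) / gene_universe_size if gene_universe_size else 0.0
    return SaturationResult(len(hit), len(genes), gene_universe_size, fraction)


def hom_examined_table(pedigrees: Sequence[Pedigree]) -> pd.DataFrame:
    """Screen-wide allele table: HOM scored-G3 counts per allele, for saturation."""
    records = []
    for ped in pedigrees:
        scored = ped.scored_g3()
        for allele in ped.alleles:
            n_hom = sum(1 for m in scored if m.genotypes.get(allele.allele_id) == HOM)
            records.append(
                {
                    "pedigree_id": ped.pedigree_id,
                    "allele_id": allele.allele_id,
                    "gene_id": allele.gene_id,
                    "effect_class": allele.effect_class,
                    "n_hom_examined": n_hom,
                }
            )
    return pd.DataFrame.from_records(
        records,
        columns=["pedigree_id", "allele_id", "gene_id", "effect_class", "n_hom_examined"],
    )


def _split_litters(total: int, max_litter: int = 8) -> list[int]:
    n_dams = max(1, math.ceil(total / max_litter))
    base, extra = divmod(total, n_dams)
    return [base + (1 if i < extra else 0) for i in range(n_dams)]


def _planted_pedigree(
    config: SimulationConfig,
    genetic_map: GeneticMap,
    f_hom: float,
    cohort_size: int,
    rng_genotypes: np.random.Generator,
    rng_phenotypes: np.random.Generator,
    pedigree_id: str,
) -> Pedigree:
    panel = generate_allele_panel(
        config.n_alleles, config.effect_weights, genetic_map, rng_genotypes,
        id_prefix=f"{pedigree_id}-",
    )
    damaging = [i for i, a in enumerate(panel) if a.effect_class in DAMAGING_CLASSES]
    idx = int(rng_genotypes.choice(damaging)) if damaging else 0
    if not damaging:
        panel[idx].effect_class = "probably_damaging"
    panel[idx].causal = True
    pm = PhenotypeModel.recessive(
        panel[idx].allele_id, f_hom, config.background_rate, config.hom_lethality
    )
    litters = _split_litters(cohort_size, config.litter_size_max)
    ped = breed_pedigree(
        panel, len(litters), litters, genetic_map, rng_genotypes,
        pedigree_id=pedigree_id, phenotype_model=pm,
    )
    return assign_phenotypes(ped, rng_phenotypes)


def _mapped_near_causal(result: MappingResult, causal: Locus, window_cM: float) -> bool:
    for t in result.significant_tests():
        if t.chrom == causal.chrom and abs(t.pos_cM - causal.pos_cM) <= window_cM:
            return True
    return False


def power_curve(
    penetrances: Sequence[float],
    cohort_sizes: Sequence[int],
    replicates: int,
    config: SimulationConfig,
    seed: int,
    window_cM: float | None = None,
) -> pd.DataFrame:
    """Mapping probability for a planted recessive allele over a parameter grid.

    For each (HOM penetrance, G3 cohort size) point, ``replicates`` pedigrees
    are simulated with a planted recessive causal allele and mapped; success
    means a Bonferroni-significant allele lies within ``window_cM`` of the
    causal locus (the causal allele itself or a linked passenger).  Genotype
    and phenotype randomness use separate substreams keyed by (cohort-size
    index, replicate), so power is monotone-coupled in penetrance at a fixed
    cohort size.  Returns one row per grid point with a Monte-Carlo standard
    error.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    window = config.mapping_window_cM if window_cM is None else float(window_cM)
    gmap = config.genetic_map()
    rows = []
    for si, size in enumerate(cohort_sizes):
        for pi, pen in enumerate(penetrances):
            hits = 0
            for r in range(replicates):
                rng_geno = np.random.default_rng(
                    np.random.SeedSequence(seed, spawn_key=(si, r, 0))
                )
                rng_phen = np.random.default_rng(
                    np.random.SeedSequence(seed, spawn_key=(si, r, 1))
                )
                ped = _planted_pedigree(
                    config, gmap, float(pen), int(size), rng_geno, rng_phen,
                    pedigree_id=f"pw{si}-{pi}-{r}",
                )
                result = map_pedigree(
                    ped, alpha=config.alpha, models=config.models,
                    per_model_bonferroni=config.per_model_bonferroni,
                )
                if _mapped_near_causal(result, ped.causal_allele.locus, window):
                    hits += 1
            power = hits / replicates
            rows.append(
                {
                    "penetrance": float(pen),
                    "cohort_size": int(size),
                    "replicates": replicates,
                    "power": power,
                    "mc_se": math.sqrt(power * (1.0 - power) / replicates),
                }
            )
    return pd.DataFrame(rows)
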