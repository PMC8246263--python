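import math

import numpy as np
import pytest
from _oracles import wilcoxon_permutation_oracle
from conftest import make_scored_pedigree
from hypothesis import given, settings, strategies as st

from enuscreen import (
    MappingResult,
    SimulationConfig,
    UndefinedPenetranceError,
    classify_pedigrees,
    hom_examined_table,
    map_pedigree,
    penetrance,
    penetrance_distribution,
    power_curve,
    saturation_count,
    simulate_screen,
    wilcoxon_rank_sum,
)
from enuscreen.analytics import round_half_up
from enuscreen.mapping import AlleleTest
from enuscreen.simulate import HET, HOM


class TestPenetrance:
    def test_het_penetrance_15_of_21(self):
        # the dominant worked example: 15 affected of 21 heterozygotes
        ped = make_scored_pedigree("dom1", 15, 6, genotype=HET)
        est = penetrance(ped, "dom1-a0", HET)
        assert est.fraction == pytest.approx(15 / 21)
        assert (est.n_affected, est.n_scored) == (15, 21)
        assert est.percent == 71.0

    def test_full_hom_penetrance_6_of_6(self):
        ped = make_scored_pedigree("rec1", 6, 0, genotype=HOM)
        est = penetrance(ped, "rec1-a0", HOM)
        assert est.fraction == 1.0
        assert est.percent == 100.0

    def test_zero_affected_gives_zero(self):
        ped = make_scored_pedigree("p", 0, 9, genotype=HOM)
        assert penetrance(ped, "p-a0", HOM).fraction == 0.0

    def test_empty_genotype_class_is_undefined(self):
        ped = make_scored_pedigree("p", 3, 3, genotype=HET)
        with pytest.raises(UndefinedPenetranceError):
            penetrance(ped, "p-a0", HOM)


def _fake_mapping_result(ped, model="recessive", p=1e-9):
    aid = ped.alleles[0].allele_id
    test = AlleleTest(
        aid, ped.alleles[0].locus.chrom, ped.alleles[0].locus.pos_cM,
        model, 5.0, 1.0, p, "Firth", {},
    )
    return MappingResult(ped.pedigree_id, [test], 1, 0.05, 0.05, [aid])


def _printed_counts_screen():
    """A screen shaped like the published counts: 1275 pedigrees, 94 with >=2

    affected mice, 20 mapped (19 recessive, 1 dominant), 12 of 19 recessive
    pedigrees at >=80% HOM penetrance.
    """
    pedigrees, results = [], {}
    k = 0

    def add(n_affected, n_unaffected, mapped_model=None, genotype=HOM):
        nonlocal k
        ped = make_scored_pedigree(f"s{k:04d}", n_affected, n_unaffected, genotype)
        if mapped_model:
            results[ped.pedigree_id] = _fake_mapping_result(ped, mapped_model)
        pedigrees.append(ped)
        k += 1

    for _ in range(12):  # mapped recessive, HOM penetrance 4/5 = 0.8
        add(4, 1, "recessive")
    for _ in range(7):  # mapped recessive, HOM penetrance 0.5
        add(2, 2, "recessive")
    add(5, 2, "dominant", genotype=HET)  # the single dominant pedigree
    for _ in range(74):  # affected but unmapped
        add(2, 10)
    for _ in range(1275 - 94):  # below the two-affected rule
        add(1, 12)
    return pedigrees, results


class TestClassification:
    def test_printed_screen_ratios(self):
        pedigrees, results = _printed_counts_screen()
        summary = classify_pedigrees(pedigrees, results)
        assert summary.n_pedigrees == 1275
        assert summary.n_affected_pedigrees == 94
        assert summary.percent_affected_pedigrees == 7.4  # 94/1275, half-up 1 dp
        assert summary.n_mapped == 20
        assert summary.percent_mapped_among_affected == 21.3  # 20/94
        assert (summary.n_mapped_recessive, summary.n_mapped_dominant) == (19, 1)
        assert summary.n_mapped_recessive_penetrance_ge_080 == 12
        assert summary.percent_mapped_recessive_penetrance_ge_080 == 63.0
        assert len(summary.affected_counts_mapped) == 20
        assert len(summary.affected_counts_unmapped) == 74

    def test_empty_screen_reports_zeros_with_warning(self):
        with pytest.warns(UserWarning):
            summary = classify_pedigrees([], {})
        assert summary.n_pedigrees == 0
        assert summary.percent_affected_pedigrees == 0.0

    def test_count_consistency_on_simulated_screen(self):
        config = SimulationConfig(n_alleles=10, causal_fraction=0.3, background_rate=0.02)
        peds = simulate_screen(40, config, seed=5)
        results = {
            p.pedigree_id: map_pedigree(p, alpha=config.alpha)
            for p in peds
            if p.n_affected_g3() >= 2 and p.scored_g3()
        }
        summary = classify_pedigrees(peds, results)
        assert summary.n_mapped <= summary.n_affected_pedigrees <= summary.n_pedigrees
        assert (
            summary.n_mapped_recessive + summary.n_mapped_dominant <= summary.n_mapped
        )

    def test_round_half_up(self):
        assert round_half_up(7.35, 1) == 7.4
        assert round_half_up(20.6499, 1) == 20.6
        assert round_half_up(62.5, 0) == 63.0


class TestPenetranceDistribution:
    def test_twelve_of_nineteen(self):
        values = [0.85] * 12 + [0.5] * 7
        n_ge, n_def, frac = penetrance_distribution(values)
        assert (n_ge, n_def) == (12, 19)
        assert frac == pytest.approx(12 / 19)
        assert round_half_up(100 * frac, 0) == 63.0

    def test_boundary_is_inclusive_at_080(self):
        assert penetrance_distribution([0.8, 1.0])[0] == 2
        assert penetrance_distribution([0.79, 0.799])[0] == 0

    def test_none_excluded_with_warning(self):
        with pytest.warns(UserWarning):
            n_ge, n_def, _ = penetrance_distribution([1.0, None])
        assert (n_ge, n_def) == (1, 1)


class TestWilcoxon:
    def test_identical_groups_give_p_one(self):
        res = wilcoxon_rank_sum([1, 2, 3], [1, 2, 3])
        assert res.method == "exact"
        assert res.p_value == 1.0

    def test_two_versus_two_enumeration(self):
        res = wilcoxon_rank_sum([1, 2], [3, 4])
        assert res.p_value == pytest.approx(2 / 6)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1, 2])

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        a=st.lists(st.integers(0, 5), min_size=1, max_size=5),
        b=st.lists(st.integers(0, 5), min_size=1, max_size=5),
    )
    def test_exact_matches_permutation_oracle(self, a, b):
        res = wilcoxon_rank_sum(a, b)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(wilcoxon_permutation_oracle(a, b), abs=1e-12)

    def test_large_samples_use_tie_corrected_normal(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 8, size=30).tolist()
        b = (rng.integers(0, 8, size=40) + 2).tolist()
        res = wilcoxon_rank_sum(a, b)
        assert res.method == "normal-approximation"
        from scipy.stats import mannwhitneyu

        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p_value == pytest.approx(ref.pvalue, rel=0.05)


class TestSaturation:
    def test_counting_rule(self):
        table = [
            ("A", "probably_damaging", 2),
            ("B", "putative_null", 1),
            ("C", "benign", 5),
        ]
        res = saturation_count(table, gene_universe_size=3)
        assert res.n_genes_hit == 1
        assert res.fraction == pytest.approx(1 / 3)

    def test_empty_table(self):
        res = saturation_count([], gene_universe_size=100)
        assert res.n_genes_hit == 0 and res.fraction == 0.0

    def test_universe_smaller_than_observed_rejected(self):
        with pytest.raises(ValueError):
            saturation_count([("A", "benign", 1), ("B", "benign", 1)], 1)

    def test_simulated_screen_matches_file_recount(self, tmp_path):
        from enuscreen import read_pedigree_tables, write_pedigree_tables
        import pandas as pd

        config = SimulationConfig(n_alleles=8, causal_fraction=0.2)
        peds = simulate_screen(25, config, seed=17)
        table = hom_examined_table(peds)
        res = saturation_count(table, gene_universe_size=500)

        # independent recount straight off the emitted TSVs
        damaging = {"probably_damaging", "possibly_damaging", "putative_null"}
        hit = set()
        for ped in peds:
            d = write_pedigree_tables(ped, tmp_path / ped.pedigree_id)
            mice = pd.read_csv(d / "mice.tsv", sep="\t")
            geno = pd.read_csv(d / "genotypes.tsv", sep="\t")
            alleles = pd.read_csv(d / "alleles.tsv", sep="\t")
            scored = mice.loc[
                (mice.generation == "G3") & (mice.phenotype != "unscored"), "mouse_id"
            ]
            hom = geno[(geno.genotype == "HOM") & geno.mouse_id.isin(scored)]
            counts = hom.groupby("allele_id").size()
            for _, row in alleles.iterrows():
                if row.effect_class in damaging and counts.get(row.allele_id, 0) >= 2:
                    hit.add(row.gene_id)
        assert res.n_genes_hit == len(hit)


class TestPowerCurve:
    def test_null_penetrance_bounded_by_fwer(self):
        config = SimulationConfig(n_alleles=10, background_rate=0.05)
        table = power_curve([0.0], [24], replicates=40, config=config, seed=3)
        bound = config.alpha + 3 * math.sqrt(config.alpha * (1 - config.alpha) / 40)
        assert table.power.iloc[0] <= bound

    def test_monotone_in_penetrance_with_paired_seeds(self):
        config = SimulationConfig(n_alleles=10)
        table = power_curve([0.3, 0.6, 1.0], [48], replicates=25, config=config, seed=4)
        powers = table.sort_values("penetrance").power.to_numpy()
        assert (np.diff(powers) >= 0).all()  # exact under the coupled streams

    def test_same_seed_reproduces(self):
        config = SimulationConfig(n_alleles=6)
        t1 = power_curve([0.9], [32], replicates=10, config=config, seed=9)
        t2 = power_curve([0.9], [32], replicates=10, config=config, seed=9)
        assert t1.equals(t2)
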