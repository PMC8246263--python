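import numpy as np
import pytest

from enuscreen import (
    EnuAllele,
    GeneticMap,
    Locus,
    Mouse,
    Pedigree,
    default_mouse_map,
)
from enuscreen.simulate import AFFECTED, HET, HOM, UNAFFECTED


@pytest.fixture(scope="session")
def mouse_map():
    return default_mouse_map()


@pytest.fixture(scope="session")
def two_chrom_map():
    return GeneticMap([("1", 100.0), ("2", 80.0)])


@pytest.fixture
def rng():
    return np.random.default_rng(20210618)


def make_scored_pedigree(
    pedigree_id: str,
    n_affected: int,
    n_unaffected: int,
    genotype: str = HOM,
    chrom: str = "1",
    pos_cM: float = 50.0,
) -> Pedigree:
    """A minimal hand-built pedigree: one allele, one dam, scored G3 mice.

    Every G3 mouse carries ``genotype`` at the single allele; the first
    ``n_affected`` are affected, the rest unaffected.  Useful for feeding
    known counts through penetrance and classification arithmetic.
    """
    allele = EnuAllele(
        f"{pedigree_id}-a0", f"{pedigree_id}-g0", Locus(chrom, pos_cM), "probably_damaging"
    )
    sire = Mouse(f"{pedigree_id}-G1", "G1", "M", None, None, {allele.allele_id: HET})
    dam = Mouse(
        f"{pedigree_id}-G2-00", "G2", "F", sire.mouse_id, None, {allele.allele_id: HET}
    )
    g3 = []
    for i in range(n_affected + n_unaffected):
        g3.append(
            Mouse(
                f"{pedigree_id}-G3-{i:03d}",
                "G3",
                "M" if i % 2 else "F",
                sire.mouse_id,
                dam.mouse_id,
                {allele.allele_id: genotype},
                phenotype=AFFECTED if i < n_affected else UNAFFECTED,
            )
        )
    return Pedigree(pedigree_id, [allele], sire, [dam], g3)
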