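"""Synthetic ENU-screen data: allele panels, backcross pedigrees, phenotypes.

The breeding design being emulated: a mutagenized G0 male is outcrossed to
wild-type females; a G1 son is heterozygous for a panel of induced point
mutations.  The G1 male is outcrossed again, and his G2 daughters — each
heterozygous or wild type at every panel allele, depending on which strand
they inherited — are backcrossed to their G1 sire.  The resulting G3 cohort
is the screened generation: it is the first in which homozygotes for an
induced allele can appear (with probability 1/8 per G3 mouse per allele:
1/2 that the dam is a carrier times 1/4 for the HOM outcome of a HET x HET
cross).

Phenotypes are binary.  A G3 mouse carrying the pedigree's causal genotype is
scored affected with the configured penetrance; everything else is affected
at a small background rate modeling radiographic false calls.  Homozygotes
for a lethal causal allele can be removed before scoring.  G1/G2 mice are
never scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .genome import GeneticMap, Haplotype, Locus, simulate_gamete

__all__ = [
    "REF",
    "HET",
    "HOM",
    "MISSING",
    "GENOTYPES",
    "EFFECT_CLASSES",
    "DAMAGING_CLASSES",
    "AFFECTED",
    "UNAFFECTED",
    "UNSCORED",
    "EnuAllele",
    "PhenotypeModel",
    "Mouse",
    "Pedigree",
    "generate_allele_panel",
    "breed_pedigree",
    "assign_phenotypes",
    "simulate_pedigree",
    "simulate_screen",
]

REF = "REF"
HET = "HET"
HOM = "HOM"
MISSING = "MISSING"
GENOTYPES = (REF, HET, HOM, MISSING)

AFFECTED = "affected"
UNAFFECTED = "unaffected"
UNSCORED = "unscored"
PHENOTYPES = (AFFECTED, UNAFFECTED, UNSCORED)

# Predicted-effect annotation of a nonsynonymous ENU variant, in the style of
# PolyPhen damage classes plus putative nulls (nonsense/splice) and synonymous
# passengers picked up by exome sequencing.
EFFECT_CLASSES = (
    "probably_damaging",
    "possibly_damaging",
    "benign",
    "putative_null",
    "synonymous",
)
DAMAGING_CLASSES = frozenset({"probably_damaging", "possibly_damaging", "putative_null"})


@dataclass
class EnuAllele:
    """One induced point mutation segregating in a pedigree.

    ``causal`` is simulation ground truth, hidden from the mapping test.
    """

    allele_id: str
    gene_id: str
    locus: Locus
    effect_class: str
    causal: bool = False

    def __post_init__(self) -> None:
        if self.effect_class not in EFFECT_CLASSES:
            raise ValueError(f"unknown effect class {self.effect_class!r}")


@dataclass
class PhenotypeModel:
    """Genotype-dependent penetrance plus scoring noise for one pedigree.

    ``penetrance`` is (f_REF, f_HET, f_HOM).  A recessive configuration has
    f_HET == f_REF; a dominant one f_HET == f_HOM.  A live G3 mouse is
    affected with probability ``max(background_rate, penetrance at its causal
    genotype)``; with no causal allele the background rate alone applies.
    """

    causal_allele_id: str | None = None
    penetrance: tuple[float, float, float] = (0.0, 0.0, 0.0)
    background_rate: float = 0.0
    hom_lethality: float = 0.0

    def __post_init__(self) -> None:
        probs = (*self.penetrance, self.background_rate, self.hom_lethality)
        for p in probs:
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probabilities must lie in [0, 1], got {p}")

    @classmethod
    def null(cls, background_rate: float = 0.0) -> "PhenotypeModel":
        return cls(None, (0.0, 0.0, 0.0), background_rate)

    @classmethod
    def recessive(
        cls,
        causal_allele_id: str,
        f_hom: float,
        background_rate: float = 0.0,
        hom_lethality: float = 0.0,
    ) -> "PhenotypeModel":
        return cls(causal_allele_id, (0.0, 0.0, f_hom), background_rate, hom_lethality)

    @classmethod
    def dominant(
        cls,
        causal_allele_id: str,
        f: float,
        background_rate: float = 0.0,
        hom_lethality: float = 0.0,
    ) -> "PhenotypeModel":
        return cls(causal_allele_id, (0.0, f, f), background_rate, hom_lethality)

    @property
    def mode(self) -> str:
        """'none', 'recessive', 'dominant', or 'other' from the penetrance triple."""
        if self.causal_allele_id is None:
            return "none"
        f_ref, f_het, f_hom = self.penetrance
        if f_het == f_ref:
            return "recessive"
        if f_het == f_hom:
            return "dominant"
        return "other"


@dataclass
class Mouse:
    mouse_id: str
    generation: str  # G1 | G2 | G3
    sex: str  # M | F
    sire_id: str | None
    dam_id: str | None
    genotypes: dict[str, str] = field(default_factory=dict)
    phenotype: str = UNSCORED
    alive: bool = True

    @property
    def scored(self) -> bool:
        return self.phenotype in (AFFECTED, UNAFFECTED)


@dataclass
class Pedigree:
    """One G1 sire's family: his G2 daughters and the backcrossed G3 cohort."""

    pedigree_id: str
    alleles: list[EnuAllele]
    g1_sire: Mouse
    g2_dams: list[Mouse]
    g3: list[Mouse]
    phenotype_model: PhenotypeModel = field(default_factory=PhenotypeModel.null)

    @property
    def allele_ids(self) -> list[str]:
        return [a.allele_id for a in self.alleles]

    def allele(self, allele_id: str) -> EnuAllele:
        for a in self.alleles:
            if a.allele_id == allele_id:
                return a
        raise KeyError(f"allele {allele_id!r} not in pedigree {self.pedigree_id!r}")

    def scored_g3(self) -> list[Mouse]:
        return [m for m in self.g3 if m.alive and m.scored]

    def n_affected_g3(self) -> int:
        return sum(1 for m in self.g3 if m.alive and m.phenotype == AFFECTED)

    @property
    def causal_allele(self) -> EnuAllele | None:
        cid = self.phenotype_model.causal_allele_id
        return self.allele(cid) if cid is not None else None


def _normalize_weights(weights) -> np.ndarray:
    if isinstance(weights, Mapping):
        unknown = set(weights) - set(EFFECT_CLASSES)
        if unknown:
            raise ValueError(f"unknown effect classes in weights: {sorted(unknown)}")
        w = np.array([float(weights.get(c, 0.0)) for c in EFFECT_CLASSES])
    else:
        w = np.asarray(list(weights), dtype=float)
        if w.shape != (len(EFFECT_CLASSES),):
            raise ValueError(
                f"expected {len(EFFECT_CLASSES)} weights aligned with {EFFECT_CLASSES}"
            )
    if np.any(w < 0) or not math.isclose(float(w.sum()), 1.0, abs_tol=1e-6):
        raise ValueError("effect-class weights must be non-negative and sum to 1")
    return w / w.sum()


def generate_allele_panel(
    n_alleles: int,
    effect_weights,
    genetic_map: GeneticMap,
    rng: np.random.Generator,
    id_prefix: str = "",
) -> list[EnuAllele]:
    """Draw the panel of ENU alleles segregating in one G1 sire.

    Loci are uniform over the map (chromosome chosen proportional to its cM
    length); effect classes are multinomial with ``effect_weights`` aligned to
    :data:`EFFECT_CLASSES` (a mapping is also accepted).  Gene ids are unique
    within the panel.
    """
    if n_alleles < 1:
        raise ValueError("n_alleles must be >= 1")
    w = _normalize_weights(effect_weights)
    classes = rng.choice(len(EFFECT_CLASSES), size=n_alleles, p=w)

    chroms = genetic_map.chromosomes
    bounds = np.cumsum([length for _, length in chroms])
    u = rng.uniform(0.0, genetic_map.total_length_cM, size=n_alleles)
    panel: list[EnuAllele] = []
    for i in range(n_alleles):
        ci = int(np.searchsorted(bounds, u[i], side="right"))
        ci = min(ci, len(chroms) - 1)
        chrom, length = chroms[ci]
        offset = u[i] - (bounds[ci] - length)
        locus = Locus(chrom, float(min(max(offset, 0.0), length)))
        panel.append(
            EnuAllele(
                allele_id=f"{id_prefix}a{i:04d}",
                gene_id=f"{id_prefix}g{i:04d}",
                locus=locus,
                effect_class=EFFECT_CLASSES[int(classes[i])],
            )
        )
    return panel


def _genotype_from_copies(copies: int) -> str:
    return (REF, HET, HOM)[copies]


def breed_pedigree(
    panel: Sequence[EnuAllele],
    n_g2_dams: int,
    litter_sizes: Sequence[int],
    genetic_map: GeneticMap,
    rng: np.random.Generator,
    pedigree_id: str = "ped",
    phenotype_model: PhenotypeModel | None = None,
) -> Pedigree:
    """Breed one pedigree: G1 sire (HET at every allele), G2 dams, G3 backcross.

    Each G2 dam receives one simulated sire gamete paired with a reference
    gamete from her wild-type mother, so she is REF or HET at every allele.
    Each G3 mouse combines one gamete from its G2 dam with one from the G1
    sire.  ``litter_sizes`` gives the G3 litter per dam and must have
    ``n_g2_dams`` entries.
    """
    if n_g2_dams < 1:
        raise ValueError("n_g2_dams must be >= 1")
    litter_sizes = [int(x) for x in litter_sizes]
    if len(litter_sizes) != n_g2_dams:
        raise ValueError("litter_sizes must have one entry per G2 dam")
    if any(x < 1 for x in litter_sizes):
        raise ValueError("litter sizes must be positive")

    panel = list(panel)
    ids = [a.allele_id for a in panel]
    if len(set(ids)) != len(ids):
        raise ValueError("allele ids must be unique within a pedigree")
    loci = [a.locus for a in panel]

    sire = Mouse(
        mouse_id=f"{pedigree_id}-G1",
        generation="G1",
        sex="M",
        sire_id=None,
        dam_id=None,
        genotypes={aid: HET for aid in ids},
    )

    dams: list[Mouse] = []
    for j in range(n_g2_dams):
        gamete = simulate_gamete(loci, genetic_map, rng)
        genotypes = {ids[i]: (HET if gamete[i] else REF) for i in range(len(ids))}
        dams.append(
            Mouse(
                mouse_id=f"{pedigree_id}-G2-{j:02d}",
                generation="G2",
                sex="F",
                sire_id=sire.mouse_id,
                dam_id=None,  # wild-type dam, not modeled
                genotypes=genotypes,
            )
        )

    g3: list[Mouse] = []
    counter = 0
    for j, dam in enumerate(dams):
        het_idx = [i for i in range(len(ids)) if dam.genotypes[ids[i]] == HET]
        het_loci = [loci[i] for i in het_idx]
        for _ in range(litter_sizes[j]):
            sire_gamete = simulate_gamete(loci, genetic_map, rng)
            dam_gamete = simulate_gamete(het_loci, genetic_map, rng)
            dam_flags = dict(zip(het_idx, dam_gamete.flags))
            genotypes = {}
            for i, aid in enumerate(ids):
                copies = int(sire_gamete[i]) + int(dam_flags.get(i, 0))
                genotypes[aid] = _genotype_from_copies(copies)
            sex = "M" if rng.integers(0, 2) else "F"
            g3.append(
                Mouse(
                    mouse_id=f"{pedigree_id}-G3-{counter:03d}",
                    generation="G3",
                    sex=sex,
                    sire_id=sire.mouse_id,
                    dam_id=dam.mouse_id,
                    genotypes=genotypes,
                )
            )
            counter += 1

    return Pedigree(
        pedigree_id=pedigree_id,
        alleles=panel,
        g1_sire=sire,
        g2_dams=dams,
        g3=g3,
        phenotype_model=phenotype_model or PhenotypeModel.null(),
    )


def assign_phenotypes(pedigree: Pedigree, rng: np.random.Generator) -> Pedigree:
    """Score the G3 cohort in place (and return the pedigree).

    Homozygotes for a lethal causal allele are removed (alive=False,
    phenotype unscored) before scoring.  Each remaining G3 mouse is affected
    with probability ``max(background, penetrance at its causal genotype)``.
    G1/G2 mice stay unscored.  One uniform draw is consumed per live G3 mouse
    in cohort order, so phenotype assignment is monotone-coupled in
    penetrance for a fixed stream.
    """
    pm = pedigree.phenotype_model
    pen_by_genotype = {
        REF: pm.penetrance[0],
        HET: pm.penetrance[1],
        HOM: pm.penetrance[2],
        MISSING: 0.0,
    }
    for mouse in pedigree.g3:
        if not mouse.alive:
            mouse.phenotype = UNSCORED
            continue
        if pm.causal_allele_id is not None:
            g = mouse.genotypes.get(pm.causal_allele_id, MISSING)
            if g == HOM and pm.hom_lethality > 0.0 and rng.random() < pm.hom_lethality:
                mouse.alive = False
                mouse.phenotype = UNSCORED
                continue
            p_affected = max(pm.background_rate, pen_by_genotype[g])
        else:
            p_affected = pm.background_rate
        mouse.phenotype = AFFECTED if rng.random() < p_affected else UNAFFECTED
    return pedigree


def simulate_pedigree(config, rng: np.random.Generator, pedigree_id: str = "ped") -> Pedigree:
    """Simulate one pedigree under a :class:`~enuscreen.config.SimulationConfig`.

    With probability ``causal_fraction`` the pedigree carries a causal allele
    (chosen among damaging-class panel members; if none exist one allele is
    relabeled probably_damaging), recessive or dominant per
    ``dominant_fraction``, with penetrance drawn uniformly from
    ``[penetrance_min, penetrance_max]``.
    """
    gmap = config.genetic_map()
    panel = generate_allele_panel(
        config.n_alleles, config.effect_weights, gmap, rng, id_prefix=f"{pedigree_id}-"
    )

    phenotype_model = PhenotypeModel.null(config.background_rate)
    if rng.random() < config.causal_fraction:
        damaging = [i for i, a in enumerate(panel) if a.effect_class in DAMAGING_CLASSES]
        idx = int(rng.choice(damaging)) if damaging else int(rng.integers(len(panel)))
        if not damaging:
            panel[idx].effect_class = "probably_damaging"
        panel[idx].causal = True
        f = float(rng.uniform(config.penetrance_min, config.penetrance_max))
        if rng.random() < config.dominant_fraction:
            phenotype_model = PhenotypeModel.dominant(
                panel[idx].allele_id, f, config.background_rate, config.hom_lethality
            )
        else:
            phenotype_model = PhenotypeModel.recessive(
                panel[idx].allele_id, f, config.background_rate, config.hom_lethality
            )

    litters = rng.integers(config.litter_size_min, config.litter_size_max + 1,
                           size=config.n_g2_dams)
    pedigree = breed_pedigree(
        panel,
        config.n_g2_dams,
        litters.tolist(),
        gmap,
        rng,
        pedigree_id=pedigree_id,
        phenotype_model=phenotype_model,
    )
    return assign_phenotypes(pedigree, rng)


def simulate_screen(n_pedigrees: int, config, seed: int) -> list[Pedigree]:
    """Simulate ``n_pedigrees`` independent pedigrees.

    Pedigree ``k`` draws from a substream keyed by ``(seed, k)``, so it is
    bit-reproducible regardless of how many pedigrees are requested.
    """
    if n_pedigrees < 0:
        raise ValueError("n_pedigrees must be >= 0")
    pedigrees = []
    for k in range(n_pedigrees):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(k,)))
        pedigrees.append(simulate_pedigree(config, rng, pedigree_id=f"ped{k:04d}"))
    return pedigrees
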