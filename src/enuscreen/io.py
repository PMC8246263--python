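"""Pedigree file formats, VCF export, and run logging.

One pedigree is interchanged as three TSVs in one directory:

* ``mice.tsv``       — mouse_id, generation, sex, sire_id, dam_id, phenotype
* ``alleles.tsv``    — allele_id, gene_id, chrom, pos_cM, effect_class
* ``genotypes.tsv``  — mouse_id, allele_id, genotype in {REF,HET,HOM,MISSING}

TSV is the primary interchange format (simple, diff-able); VCF is an
export-only convenience, because cM-coordinate genetics fits VCF awkwardly —
positions there are synthetic integers (cM x 10^4, 1-based) with the true cM
position carried in INFO/CM.

Readers tolerate CRLF line endings and a UTF-8 BOM, and report parse errors
with the offending file and line number.  Simulation ground truth (causal
allele, penetrance model) is deliberately not part of the pedigree tables:
it is hidden from mapping, and the simulate CLI writes it to a separate
truth table instead.
"""

from __future__ import annotations

import csv
import datetime
import json
import math
from pathlib import Path

import numpy as np

from .genome import GeneticMap, Locus, chrom_sort_key
from .simulate import (
    EFFECT_CLASSES,
    GENOTYPES,
    HET,
    HOM,
    MISSING,
    PHENOTYPES,
    REF,
    EnuAllele,
    Mouse,
    Pedigree,
    PhenotypeModel,
)

__all__ = [
    "PedigreeParseError",
    "MICE_COLUMNS",
    "ALLELE_COLUMNS",
    "GENOTYPE_COLUMNS",
    "write_pedigree_tables",
    "read_pedigree_tables",
    "write_vcf",
    "write_run_log",
]

MICE_COLUMNS = ["mouse_id", "generation", "sex", "sire_id", "dam_id", "phenotype"]
ALLELE_COLUMNS = ["allele_id", "gene_id", "chrom", "pos_cM", "effect_class"]
GENOTYPE_COLUMNS = ["mouse_id", "allele_id", "genotype"]

_NA = ""  # empty field encodes a missing parent id


class PedigreeParseError(Exception):
    """A pedigree table failed validation; message names the file and line."""

    def __init__(self, path, lineno: int | None, message: str):
        where = f"{path}:{lineno}" if lineno is not None else str(path)
        super().__init__(f"{where}: {message}")
        self.path = str(path)
        self.lineno = lineno


def _read_tsv(path: Path, columns: list[str]) -> list[tuple[int, dict[str, str]]]:
    if not path.is_file():
        raise PedigreeParseError(path, None, "file not found")
    with open(path, encoding="utf-8-sig", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise PedigreeParseError(path, 1, "empty file") from None
        if header != columns:
            unknown = [c for c in header if c not in columns]
            missing = [c for c in columns if c not in header]
            parts = []
            if unknown:
                parts.append(f"unknown column(s) {unknown}")
            if missing:
                parts.append(f"missing column(s) {missing}")
            detail = "; ".join(parts) or f"columns out of order (expected {columns})"
            raise PedigreeParseError(path, 1, detail)
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row or row == [""]:
                continue
            if len(row) != len(columns):
                raise PedigreeParseError(
                    path, lineno, f"expected {len(columns)} fields, got {len(row)}"
                )
            rows.append((lineno, dict(zip(columns, row))))
        return rows


def write_pedigree_tables(pedigree: Pedigree, directory: str | Path) -> Path:
    """Write mice.tsv / alleles.tsv / genotypes.tsv into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    mice = [pedigree.g1_sire, *pedigree.g2_dams, *pedigree.g3]

    with open(directory / "mice.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(MICE_COLUMNS) + "\n")
        for m in mice:
            fh.write(
                "\t".join(
                    [m.mouse_id, m.generation, m.sex, m.sire_id or _NA, m.dam_id or _NA,
                     m.phenotype]
                )
                + "\n"
            )

    with open(directory / "alleles.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(ALLELE_COLUMNS) + "\n")
        for a in pedigree.alleles:
            fh.write(
                f"{a.allele_id}\t{a.gene_id}\t{a.locus.chrom}\t{a.locus.pos_cM:.6f}\t"
                f"{a.effect_class}\n"
            )

    with open(directory / "genotypes.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(GENOTYPE_COLUMNS) + "\n")
        for m in mice:
            for a in pedigree.alleles:
                fh.write(f"{m.mouse_id}\t{a.allele_id}\t{m.genotypes[a.allele_id]}\n")

    return directory


def read_pedigree_tables(
    directory: str | Path, phenotype_model: PhenotypeModel | None = None
) -> Pedigree:
    """Read and cross-validate one pedigree from its three TSVs.

    Checks: known column sets, legal symbols, unique ids, closed parentage
    (every G3 mouse's sire is the single G1 male, its dam one of the G2
    females), no HOM genotype outside G3, and a complete mouse x allele
    genotype matrix.  The returned pedigree carries no simulation truth:
    causal flags are False and the phenotype model defaults to null.
    """
    directory = Path(directory)
    allele_rows = _read_tsv(directory / "alleles.tsv", ALLELE_COLUMNS)
    mice_rows = _read_tsv(directory / "mice.tsv", MICE_COLUMNS)
    genotype_rows = _read_tsv(directory / "genotypes.tsv", GENOTYPE_COLUMNS)

    alleles: list[EnuAllele] = []
    seen_alleles: set[str] = set()
    for lineno, row in allele_rows:
        path = directory / "alleles.tsv"
        if row["allele_id"] in seen_alleles:
            raise PedigreeParseError(path, lineno, f"duplicate allele id {row['allele_id']!r}")
        seen_alleles.add(row["allele_id"])
        if row["effect_class"] not in EFFECT_CLASSES:
            raise PedigreeParseError(path, lineno, f"illegal effect class {row['effect_class']!r}")
        try:
            pos = float(row["pos_cM"])
        except ValueError:
            raise PedigreeParseError(path, lineno, f"bad position {row['pos_cM']!r}") from None
        if not math.isfinite(pos) or pos < 0:
            raise PedigreeParseError(path, lineno, f"bad position {row['pos_cM']!r}")
        alleles.append(
            EnuAllele(row["allele_id"], row["gene_id"], Locus(row["chrom"], pos),
                      row["effect_class"])
        )
    if not alleles:
        raise PedigreeParseError(directory / "alleles.tsv", None, "no alleles")

    mice: dict[str, Mouse] = {}
    mouse_lines: dict[str, int] = {}
    for lineno, row in mice_rows:
        path = directory / "mice.tsv"
        mid = row["mouse_id"]
        if mid in mice:
            raise PedigreeParseError(path, lineno, f"duplicate mouse id {mid!r}")
        if row["generation"] not in ("G1", "G2", "G3"):
            raise PedigreeParseError(path, lineno, f"illegal generation {row['generation']!r}")
        if row["sex"] not in ("M", "F"):
            raise PedigreeParseError(path, lineno, f"illegal sex {row['sex']!r}")
        if row["phenotype"] not in PHENOTYPES:
            raise PedigreeParseError(path, lineno, f"illegal phenotype {row['phenotype']!r}")
        mice[mid] = Mouse(
            mouse_id=mid,
            generation=row["generation"],
            sex=row["sex"],
            sire_id=row["sire_id"] or None,
            dam_id=row["dam_id"] or None,
            phenotype=row["phenotype"],
        )
        mouse_lines[mid] = lineno

    g1 = [m for m in mice.values() if m.generation == "G1"]
    g2 = [m for m in mice.values() if m.generation == "G2"]
    g3 = [m for m in mice.values() if m.generation == "G3"]
    path = directory / "mice.tsv"
    if len(g1) != 1:
        raise PedigreeParseError(path, None, f"expected exactly one G1 sire, found {len(g1)}")
    sire = g1[0]
    g2_ids = {m.mouse_id for m in g2}
    for m in g3:
        if m.sire_id != sire.mouse_id:
            raise PedigreeParseError(
                path, mouse_lines[m.mouse_id],
                f"G3 mouse {m.mouse_id!r}: sire {m.sire_id!r} is not the G1 sire",
            )
        if m.dam_id not in g2_ids:
            raise PedigreeParseError(
                path, mouse_lines[m.mouse_id],
                f"G3 mouse {m.mouse_id!r}: dam {m.dam_id!r} is not a G2 dam",
            )

    allele_ids = {a.allele_id for a in alleles}
    for lineno, row in genotype_rows:
        path = directory / "genotypes.tsv"
        mid, aid, call = row["mouse_id"], row["allele_id"], row["genotype"]
        if mid not in mice:
            raise PedigreeParseError(path, lineno, f"unknown mouse id {mid!r}")
        if aid not in allele_ids:
            raise PedigreeParseError(path, lineno, f"unknown allele id {aid!r}")
        if call not in GENOTYPES:
            raise PedigreeParseError(path, lineno, f"illegal genotype symbol {call!r}")
        mouse = mice[mid]
        if call == HOM and mouse.generation != "G3":
            raise PedigreeParseError(
                path, lineno, f"HOM genotype on {mouse.generation} mouse {mid!r}"
            )
        if aid in mouse.genotypes:
            raise PedigreeParseError(path, lineno, f"duplicate genotype for ({mid!r}, {aid!r})")
        mouse.genotypes[aid] = call

    for m in mice.values():
        missing = allele_ids - set(m.genotypes)
        if missing:
            raise PedigreeParseError(
                directory / "genotypes.tsv", None,
                f"mouse {m.mouse_id!r} lacks genotypes for {len(missing)} allele(s)",
            )

    return Pedigree(
        pedigree_id=directory.name,
        alleles=alleles,
        g1_sire=sire,
        g2_dams=sorted(g2, key=lambda m: m.mouse_id),
        g3=sorted(g3, key=lambda m: m.mouse_id),
        phenotype_model=phenotype_model or PhenotypeModel.null(),
    )


_VCF_GT = {REF: "0/0", HET: "0/1", HOM: "1/1", MISSING: "./."}
_CM_SCALE = 10_000  # synthetic integer coordinate = cM * scale, 1-based


def write_vcf(
    pedigree: Pedigree, path: str | Path, genetic_map: GeneticMap | None = None
) -> Path:
    """Export genotypes as a minimal VCF 4.2 with synthetic cM-derived positions.

    One record per allele; samples are the G1 sire, G2 dams, then the G3
    cohort.  The true cM position is stored in INFO as ``CM=``; contig
    lengths come from the genetic map when given, otherwise from the maximal
    allele position per chromosome.
    """
    path = Path(path)
    mice = [pedigree.g1_sire, *pedigree.g2_dams, *pedigree.g3]

    if genetic_map is not None:
        contigs = [(c, length) for c, length in genetic_map.chromosomes]
        order = {c: i for i, (c, _) in enumerate(contigs)}
    else:
        maxima: dict[str, float] = {}
        for a in pedigree.alleles:
            maxima[a.locus.chrom] = max(maxima.get(a.locus.chrom, 0.0), a.locus.pos_cM)
        chroms = sorted(maxima, key=chrom_sort_key)
        contigs = [(c, maxima[c] + 1.0) for c in chroms]
        order = {c: i for i, c in enumerate(chroms)}

    alleles = sorted(
        pedigree.alleles, key=lambda a: (order[a.locus.chrom], a.locus.pos_cM, a.allele_id)
    )

    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=enuscreen (pedigree {pedigree.pedigree_id})\n")
        for chrom, length in contigs:
            fh.write(f"##contig=<ID={chrom},length={int(length * _CM_SCALE) + 2}>\n")
        fh.write(
            '##INFO=<ID=CM,Number=1,Type=Float,Description="Genetic map position in centimorgans">\n'
        )
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene label">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(m.mouse_id for m in mice)
            + "\n"
        )
        for a in alleles:
            pos = int(round(a.locus.pos_cM * _CM_SCALE)) + 1
            info = f"CM={a.locus.pos_cM:.6f};GENE={a.gene_id}"
            gts = "\t".join(_VCF_GT[m.genotypes[a.allele_id]] for m in mice)
            fh.write(
                f"{a.locus.chrom}\t{pos}\t{a.allele_id}\tA\tT\t.\tPASS\t{info}\tGT\t{gts}\n"
            )
    return path


def write_run_log(
    log_path: str | Path,
    command: str,
    params: dict,
    seed: int | None,
    counts: dict,
) -> Path:
    """Append one structured JSON record capturing enough to reproduce a run."""
    import enuscreen

    record = {
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "command": command,
        "seed": seed,
        "params": params,
        "counts": counts,
        "versions": {
            "enuscreen": enuscreen.__version__,
            "numpy": np.__version__,
        },
    }
    log_path = Path(log_path)
    log_path.parent.mkdir(parents=True, exist_ok=True)
    with open(log_path, "a", encoding="utf-8") as fh:
        fh.write(json.dumps(record, sort_keys=True) + "\n")
    return log_path
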