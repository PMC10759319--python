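"""Readers and writers for the pipeline's file formats.

VCF v4.2 is read through cyvcf2; everything else (PED, cohort labels,
gene panel BED/TSV, annotation TSV, SV TSV) is plain tab-separated text.
Writers exist for VCF and PED so that a parsed cohort round-trips.

Allelic-fraction source precedence: an explicit per-sample ``VAF`` FORMAT
field wins over a fraction derived from ``AD`` (alt depth / total depth);
with neither, the fraction is missing and the call is exempt from the
allelic-fraction filter.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
from cyvcf2 import VCF

from .cohort import (
    HET,
    HOM_ALT,
    HOM_REF,
    MISSING,
    AnnotatedVariant,
    GenePanel,
    Individual,
    Pedigree,
    PedigreeError,
    SVInterval,
    VariantCall,
    VariantKey,
)

__all__ = [
    "ParseError",
    "read_annotations",
    "parse_vcf",
    "write_vcf",
    "parse_ped",
    "write_ped",
    "write_cohort_labels",
    "read_panel",
    "write_panel_bed",
    "read_sv_table",
    "write_sv_table",
]


class ParseError(ValueError):
    """Malformed input file; the message names the file and offending record."""


# ---------------------------------------------------------------------------
# annotation TSV

_ANN_COLUMNS = ["chrom", "pos", "ref", "alt", "gene", "consequence",
                "regulatory_sources", "gnomad_af"]


def read_annotations(path: str | Path) -> dict[VariantKey, dict]:
    """Annotation TSV keyed by (chrom, pos, ref, alt).

    Columns: chrom, pos, ref, alt, gene, consequence, regulatory_sources
    (semicolon-separated subset of RefSeq/Ensembl/Encode/ORegAnno, empty
    allowed) and gnomad_af (empty = absent from gnomAD).
    """
    path = Path(path)
    table: dict[VariantKey, dict] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_ANN_COLUMNS) - set(reader.fieldnames or [])
        if missing:
            raise ParseError(f"{path}: missing annotation columns {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            try:
                key = VariantKey(row["chrom"], int(row["pos"]), row["ref"], row["alt"])
            except (ValueError, KeyError) as exc:
                raise ParseError(f"{path}: line {i}: {exc}") from exc
            if key in table:
                raise ParseError(f"{path}: line {i}: duplicate annotation for {key}")
            sources = frozenset(
                s for s in row["regulatory_sources"].split(";") if s
            )
            af_text = row["gnomad_af"].strip()
            table[key] = {
                "gene": row["gene"] or None,
                "consequence": row["consequence"] or "other",
                "regulatory_sources": sources,
                "population_af": float(af_text) if af_text else None,
            }
    return table


def write_annotations(path: str | Path, variants: list[AnnotatedVariant]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_ANN_COLUMNS)
        for v in variants:
            writer.writerow([
                v.key.chrom, v.key.pos, v.key.ref, v.key.alt,
                v.gene or "",
                v.consequence,
                ";".join(sorted(v.regulatory_sources)),
                "" if v.population_af is None else f"{v.population_af:.6g}",
            ])


# ---------------------------------------------------------------------------
# VCF

def parse_vcf(
    path: str | Path,
    annotation_path: str | Path | None = None,
) -> tuple[list[AnnotatedVariant], list[str]]:
    """Read a VCF into :class:`AnnotatedVariant` objects.

    Multi-allelic records are split into one variant per alternate allele,
    with genotypes mapped per allele.  Only informative calls (het,
    hom_alt, missing genotype) are stored; absent calls mean hom_ref.
    Variants lacking an annotation row keep gene=None, consequence=other
    and missing population frequency.

    Returns ``(variants, samples)`` where ``samples`` is the VCF sample
    roster in column order.
    """
    path = Path(path)
    annotations = read_annotations(annotation_path) if annotation_path else {}
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception on bad headers
        raise ParseError(f"{path}: cannot read VCF header: {exc}") from exc
    samples = list(vcf.samples)
    variants: list[AnnotatedVariant] = []
    for record in vcf:
        gts = record.genotypes  # [[a, b, phased], ...]
        try:
            ad = record.format("AD")
        except KeyError:
            ad = None
        try:
            vaf = record.format("VAF")
        except KeyError:
            vaf = None
        for alt_index, alt in enumerate(record.ALT):
            allele_number = alt_index + 1
            try:
                key = VariantKey(record.CHROM, record.POS, record.REF, alt)
            except ValueError as exc:
                raise ParseError(
                    f"{path}: record {record.CHROM}:{record.POS}: {exc}"
                ) from exc
            calls: dict[str, VariantCall] = {}
            for s_idx, sample in enumerate(samples):
                g = gts[s_idx]
                alleles = [a for a in g[:-1]]
                if any(a < 0 for a in alleles):
                    genotype = MISSING
                else:
                    n_alt = sum(1 for a in alleles if a == allele_number)
                    genotype = {0: HOM_REF, 1: HET}.get(n_alt, HOM_ALT)
                if genotype == HOM_REF:
                    continue
                af = _allelic_fraction(vaf, ad, s_idx, alt_index)
                calls[sample] = VariantCall(sample, genotype, af)
            ann = annotations.get(key, {})
            variants.append(AnnotatedVariant(
                key=key,
                gene=ann.get("gene"),
                consequence=ann.get("consequence", "other"),
                regulatory_sources=ann.get("regulatory_sources", frozenset()),
                population_af=ann.get("population_af"),
                calls=calls,
            ))
    return variants, samples


def _allelic_fraction(vaf, ad, sample_idx: int, alt_index: int) -> float | None:
    if vaf is not None:
        value = float(np.atleast_2d(vaf)[sample_idx, alt_index]
                      if np.ndim(vaf) > 1 and np.shape(vaf)[1] > alt_index
                      else np.ravel(vaf)[sample_idx])
        if np.isnan(value) or value < 0:
            return None
        # VAF arrives as float32; re-quantize so text round-trips exactly
        return round(value, 6)
    if ad is not None:
        row = np.atleast_2d(ad)[sample_idx]
        row = np.where(row < 0, 0, row)  # cyvcf2 encodes missing AD as negative
        total = int(row.sum())
        if total == 0:
            return None
        return float(row[alt_index + 1]) / total
    return None


def write_vcf(
    path: str | Path,
    variants: list[AnnotatedVariant],
    samples: list[str],
) -> None:
    """Write variants as VCF v4.2 with a GT:VAF FORMAT.

    Samples absent from a variant's calls are written 0/0.  The stored
    allelic fraction is emitted in a VAF field (4 decimals) so that a
    write/parse cycle reproduces the domain objects exactly.
    """
    by_pos = sorted(variants, key=lambda v: v.key)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=VAF,Number=A,Type=Float,'
                 'Description="Allelic fraction of the alternate allele">\n')
        for chrom in dict.fromkeys(v.key.chrom for v in by_pos):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for v in by_pos:
            fields = [v.key.chrom, str(v.key.pos), ".", v.key.ref, v.key.alt,
                      ".", "PASS", ".", "GT:VAF"]
            for sample in samples:
                call = v.calls.get(sample)
                if call is None:
                    fields.append("0/0:.")
                    continue
                gt = {HET: "0/1", HOM_ALT: "1/1", MISSING: "./.",
                      HOM_REF: "0/0"}[call.genotype]
                af = "." if call.allelic_fraction is None else f"{call.allelic_fraction:.4f}"
                fields.append(f"{gt}:{af}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# PED + cohort labels

def parse_ped(path: str | Path, cohort_path: str | Path) -> Pedigree:
    """Six-column PED plus a sidecar TSV (sample_id, cohort, is_index).

    PED columns: family, sample, father, mother, sex (1=male, 2=female,
    other=unknown), affected (2=affected).  "0" marks a missing parent.
    """
    path, cohort_path = Path(path), Path(cohort_path)
    labels: dict[str, tuple[str, bool]] = {}
    with open(cohort_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        need = {"sample_id", "cohort", "is_index"}
        if not need <= set(reader.fieldnames or []):
            raise ParseError(f"{cohort_path}: needs columns {sorted(need)}")
        for i, row in enumerate(reader, start=2):
            sid = row["sample_id"]
            if sid in labels:
                raise ParseError(f"{cohort_path}: line {i}: duplicate sample {sid}")
            if row["cohort"] not in ("case", "control"):
                raise ParseError(
                    f"{cohort_path}: line {i}: cohort must be case/control"
                )
            labels[sid] = (row["cohort"], row["is_index"].strip() in ("1", "true", "True"))

    individuals: dict[str, Individual] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 6:
                raise ParseError(f"{path}: line {i}: expected 6 columns")
            fam, sid, father, mother, sex, aff = parts
            if sid in individuals:
                raise ParseError(f"{path}: line {i}: duplicate sample {sid}")
            if sid not in labels:
                raise ParseError(f"{path}: line {i}: sample {sid} missing from cohort table")
            cohort, is_index = labels[sid]
            individuals[sid] = Individual(
                sample_id=sid,
                family_id=fam,
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                sex={"1": "male", "2": "female"}.get(sex, "unknown"),
                affected=aff == "2",
                cohort=cohort,
                is_index=is_index,
            )
    extra = set(labels) - set(individuals)
    if extra:
        raise ParseError(f"{cohort_path}: samples absent from PED: {sorted(extra)[:5]}")
    try:
        return Pedigree(individuals)
    except PedigreeError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_ped(path: str | Path, pedigree: Pedigree) -> None:
    with open(path, "w") as fh:
        for person in pedigree:
            fh.write("\t".join([
                person.family_id,
                person.sample_id,
                person.father_id or "0",
                person.mother_id or "0",
                {"male": "1", "female": "2"}.get(person.sex, "0"),
                "2" if person.affected else "1",
            ]) + "\n")


def write_cohort_labels(path: str | Path, pedigree: Pedigree) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tcohort\tis_index\n")
        for person in pedigree:
            fh.write(f"{person.sample_id}\t{person.cohort}\t"
                     f"{1 if person.is_index else 0}\n")


# ---------------------------------------------------------------------------
# gene panel

def read_panel(path: str | Path) -> GenePanel:
    """Gene panel from BED (chrom, start, end, gene) or TSV with a header
    (gene, chrom, start, end).  Intervals are 0-based half-open in both."""
    path = Path(path)
    genes: dict[str, list[tuple[str, int, int]]] = {}
    with open(path) as fh:
        first = fh.readline()
        if not first:
            raise ParseError(f"{path}: empty panel file")
        header_mode = first.lower().startswith("gene\t")
        lines = [] if header_mode else [first]
        lines += fh.readlines()
        for i, line in enumerate(lines, start=2 if header_mode else 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}: line {i}: expected 4 columns")
            if header_mode:
                gene, chrom, start, end = parts[:4]
            else:
                chrom, start, end, gene = parts[:4]
            try:
                iv = (chrom, int(start), int(end))
            except ValueError as exc:
                raise ParseError(f"{path}: line {i}: {exc}") from exc
            genes.setdefault(gene, []).append(iv)
    return GenePanel(genes)


def write_panel_bed(path: str | Path, panel: GenePanel) -> None:
    with open(path, "w") as fh:
        for gene, ivs in panel.genes.items():
            for chrom, start, end in ivs:
                fh.write(f"{chrom}\t{start}\t{end}\t{gene}\n")


# ---------------------------------------------------------------------------
# structural variants

def read_sv_table(path: str | Path) -> list[SVInterval]:
    """SV TSV: sample_id, chrom, start, end, sv_type (0-based half-open)."""
    path = Path(path)
    out: list[SVInterval] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        need = {"sample_id", "chrom", "start", "end", "sv_type"}
        if not need <= set(reader.fieldnames or []):
            raise ParseError(f"{path}: needs columns {sorted(need)}")
        for i, row in enumerate(reader, start=2):
            try:
                out.append(SVInterval(
                    chrom=row["chrom"],
                    start=int(row["start"]),
                    end=int(row["end"]),
                    sv_type=row["sv_type"],
                    sample_id=row["sample_id"],
                ))
            except ValueError as exc:
                raise ParseError(f"{path}: line {i}: {exc}") from exc
    return out


def write_sv_table(path: str | Path, svs: list[SVInterval]) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tchrom\tstart\tend\tsv_type\n")
        for sv in svs:
            fh.write(f"{sv.sample_id}\t{sv.chrom}\t{sv.start}\t{sv.end}\t{sv.sv_type}\n")
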