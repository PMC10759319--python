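"""Domain model for a case-control rare-disease cohort.

This module holds the in-memory objects that flow through the pipeline —
variants with annotations and per-sample calls, the pedigree, the gene
panel — plus the cohort-level operations that are not filters: reduction
to one index case per family, per-patient zygosity/phase classification,
and interval overlap against the panel.

Coordinate conventions
----------------------
Variant positions are 1-based (VCF convention).  All interval arithmetic
(gene panel, structural variants) is 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "HOM_REF",
    "HET",
    "HOM_ALT",
    "MISSING",
    "VariantKey",
    "VariantCall",
    "AnnotatedVariant",
    "Individual",
    "Pedigree",
    "GenePanel",
    "SVInterval",
    "ZygosityCall",
    "PedigreeError",
    "reduce_to_index",
    "classify_zygosity",
    "coding_overlap",
]

# genotype states for a diploid call
HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
MISSING = "missing"

GENOTYPES = frozenset({HOM_REF, HET, HOM_ALT, MISSING})

REGULATORY_SOURCES = frozenset({"RefSeq", "Ensembl", "Encode", "ORegAnno"})
CONSEQUENCES = frozenset({"synonymous", "nonsynonymous", "splicing", "other"})

_BASES = frozenset("ACGT")


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees or cohort annotations."""


@dataclass(frozen=True, order=True)
class VariantKey:
    """Genomic identity of a bi-allelic small variant (multi-allelic
    records are split before this type exists)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if not (set(self.ref) <= _BASES and set(self.alt) <= _BASES):
            raise ValueError(
                f"ref/alt must be uppercase A/C/G/T: {self.ref}>{self.alt}"
            )

    def __str__(self) -> str:  # chr1:123:G>A
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


@dataclass(frozen=True)
class VariantCall:
    """One sample's genotype at one variant.

    ``allelic_fraction`` is the fraction of reads supporting the alternate
    allele, or ``None`` when no depth information was available.  A call
    with ``None`` is exempt from the allelic-fraction filter: absence of
    depth data is not evidence of an artifact.
    """

    sample_id: str
    genotype: str
    allelic_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        af = self.allelic_fraction
        if af is not None and not (0.0 <= af <= 1.0):
            raise ValueError(f"allelic fraction {af} outside [0, 1]")

    @property
    def is_alt(self) -> bool:
        return self.genotype in (HET, HOM_ALT)

    @property
    def alt_alleles(self) -> int:
        return {HOM_REF: 0, HET: 1, HOM_ALT: 2, MISSING: 0}[self.genotype]


@dataclass
class AnnotatedVariant:
    """A small variant with annotations and per-sample calls.

    ``calls`` maps sample_id -> VariantCall and holds only informative
    calls (het, hom_alt or missing).  Samples absent from ``calls`` are
    homozygous reference; this keeps cohort-scale variant sets sparse.
    """

    key: VariantKey
    gene: str | None = None
    consequence: str = "other"
    regulatory_sources: frozenset[str] = frozenset()
    population_af: float | None = None
    calls: dict[str, VariantCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        unknown = set(self.regulatory_sources) - REGULATORY_SOURCES
        if unknown:
            raise ValueError(f"unknown regulatory sources {sorted(unknown)}")
        if self.population_af is not None and not (0.0 <= self.population_af <= 1.0):
            raise ValueError(f"population_af {self.population_af} outside [0, 1]")
        for sid, call in self.calls.items():
            if call.sample_id != sid:
                raise ValueError("calls must be keyed by their sample_id")

    def genotype_of(self, sample_id: str) -> str:
        """Genotype of ``sample_id``; absent calls are hom_ref."""
        call = self.calls.get(sample_id)
        return call.genotype if call is not None else HOM_REF

    def alt_calls(self) -> list[VariantCall]:
        return [c for c in self.calls.values() if c.is_alt]


@dataclass(frozen=True)
class Individual:
    sample_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"  # male | female | unknown
    affected: bool = False
    cohort: str = "case"  # case | control
    is_index: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female", "unknown"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.cohort not in ("case", "control"):
            raise ValueError(f"unknown cohort {self.cohort!r}")


@dataclass
class Pedigree:
    """Collection of individuals keyed by sample_id.

    Validates: unique ids, resolvable parents of compatible sex, no
    ancestry cycles, and at most one index case per case family.
    """

    individuals: dict[str, Individual]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        ind = self.individuals
        for sid, person in ind.items():
            if person.sample_id != sid:
                raise PedigreeError("individuals must be keyed by sample_id")
            for pid, want_sex in ((person.father_id, "male"), (person.mother_id, "female")):
                if pid is None:
                    continue
                parent = ind.get(pid)
                if parent is None:
                    raise PedigreeError(
                        f"sample {sid}: parent {pid} not in pedigree"
                    )
                if parent.sex not in (want_sex, "unknown"):
                    raise PedigreeError(
                        f"sample {sid}: parent {pid} has incompatible sex"
                    )
        # one index per case family
        index_by_family: dict[str, str] = {}
        for person in ind.values():
            if person.cohort == "case" and person.is_index:
                prev = index_by_family.setdefault(person.family_id, person.sample_id)
                if prev != person.sample_id:
                    raise PedigreeError(
                        f"family {person.family_id}: more than one index case"
                    )
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}  # 0 in progress, 1 done

        def visit(sid: str, stack: list[str]) -> None:
            if state.get(sid) == 1:
                return
            if state.get(sid) == 0:
                raise PedigreeError(f"ancestry cycle involving {sid}")
            state[sid] = 0
            person = self.individuals[sid]
            for pid in (person.father_id, person.mother_id):
                if pid is not None:
                    visit(pid, stack + [sid])
            state[sid] = 1

        for sid in self.individuals:
            visit(sid, [])

    def __iter__(self):
        return iter(self.individuals.values())

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, sample_id: str) -> Individual:
        return self.individuals[sample_id]

    def __contains__(self, sample_id: str) -> bool:
        return sample_id in self.individuals

    def families(self) -> dict[str, list[Individual]]:
        out: dict[str, list[Individual]] = {}
        for person in self.individuals.values():
            out.setdefault(person.family_id, []).append(person)
        return out

    def cases(self) -> list[Individual]:
        return [p for p in self if p.cohort == "case"]

    def controls(self) -> list[Individual]:
        return [p for p in self if p.cohort == "control"]

    def parents_of(self, sample_id: str) -> tuple[Individual | None, Individual | None]:
        """(mother, father), None where unset."""
        person = self.individuals[sample_id]
        mother = self.individuals.get(person.mother_id) if person.mother_id else None
        father = self.individuals.get(person.father_id) if person.father_id else None
        return mother, father


@dataclass
class GenePanel:
    """Mapping gene symbol -> list of (chrom, start, end) 0-based
    half-open intervals.  Symbol lookup is case-insensitive."""

    genes: dict[str, list[tuple[str, int, int]]]

    def __post_init__(self) -> None:
        self._upper = {}
        for gene, ivs in self.genes.items():
            if not ivs:
                raise ValueError(f"gene {gene}: empty interval list")
            for chrom, start, end in ivs:
                if start >= end:
                    raise ValueError(
                        f"gene {gene}: invalid interval {chrom}:{start}-{end}"
                    )
            key = gene.upper()
            if key in self._upper:
                raise ValueError(f"duplicate gene symbol {gene}")
            self._upper[key] = gene

    def __contains__(self, gene: str | None) -> bool:
        return gene is not None and gene.upper() in self._upper

    def __len__(self) -> int:
        return len(self.genes)

    def intervals(self) -> list[tuple[str, int, int]]:
        return [iv for ivs in self.genes.values() for iv in ivs]

    def contains_position(self, chrom: str, pos_1based: int) -> bool:
        """True if the 1-based position falls inside any panel interval."""
        p0 = pos_1based - 1
        return any(
            c == chrom and start <= p0 < end for c, start, end in self.intervals()
        )


@dataclass(frozen=True)
class SVInterval:
    """An already-called structural variant, 0-based half-open."""

    chrom: str
    start: int
    end: int
    sv_type: str
    sample_id: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"SV interval {self.chrom}:{self.start}-{self.end} empty")


@dataclass(frozen=True)
class ZygosityCall:
    """Per-patient, per-gene zygosity/phase classification."""

    sample_id: str
    gene: str | None
    status: str  # homozygous | compound_het_confirmed | biallelic_phase_unknown | single_het | none
    variant_keys: tuple[VariantKey, ...] = ()
    phase_evidence: str = "none"  # trio | none | mendelian_error

    def __post_init__(self) -> None:
        if self.status not in (
            "homozygous",
            "compound_het_confirmed",
            "biallelic_phase_unknown",
            "single_het",
            "none",
        ):
            raise ValueError(f"unknown status {self.status!r}")
        if self.phase_evidence not in ("trio", "none", "mendelian_error"):
            raise ValueError(f"unknown phase evidence {self.phase_evidence!r}")
        if self.status == "compound_het_confirmed" and self.phase_evidence != "trio":
            raise ValueError("compound_het_confirmed requires trio evidence")


def reduce_to_index(pedigree: Pedigree) -> set[str]:
    """Sample ids retained for enrichment: every control plus exactly the
    index case of each case family.

    Eliminating genetic relatedness this way prevents family-shared but
    disease-unrelated variants from masquerading as founder candidates.
    Raises :class:`PedigreeError` for a case family with no index flagged
    (no silent guessing).
    """
    retained = {p.sample_id for p in pedigree.controls()}
    by_family: dict[str, list[Individual]] = {}
    for person in pedigree.cases():
        by_family.setdefault(person.family_id, []).append(person)
    for family_id, members in by_family.items():
        index = [p for p in members if p.is_index]
        if not index:
            raise PedigreeError(f"case family {family_id} has no index case flagged")
        retained.add(index[0].sample_id)
    return retained


def coding_overlap(sv: SVInterval, panel: GenePanel) -> bool:
    """True iff the SV intersects any panel interval on the same
    chromosome (half-open; abutting intervals do not overlap)."""
    return any(
        chrom == sv.chrom and sv.start < end and start < sv.end
        for chrom, start, end in panel.intervals()
    )


def _popaf_sort_key(variant: AnnotatedVariant):
    # missing population frequency means "absent from gnomAD", i.e. rare
    af = variant.population_af if variant.population_af is not None else 0.0
    return (af, variant.key)


def _carries(variant: AnnotatedVariant, sample_id: str) -> bool | None:
    """Does the sample carry >=1 alt allele? None when the genotype is missing."""
    gt = variant.genotype_of(sample_id)
    if gt == MISSING:
        return None
    return gt in (HET, HOM_ALT)


def classify_zygosity(
    variants_of_gene: list[AnnotatedVariant],
    sample_id: str,
    pedigree: Pedigree,
    genotyped_samples: set[str] | None = None,
) -> ZygosityCall:
    """Classify one patient's zygosity/phase state for one gene.

    The decision cascade:

    * hom_alt at any variant -> ``homozygous`` (rarest variant if several);
    * two het variants whose parental origins can be resolved to opposite
      chromosomes -> ``compound_het_confirmed`` (trans configuration);
    * two het variants without informative parents -> ``biallelic_phase_unknown``;
    * one het variant -> ``single_het``; otherwise ``none``.

    With three or more het variants the two with the lowest population
    frequency are phased (deterministic tie-break on genomic key); the
    remainder are still listed in ``variant_keys``.

    Phase resolution uses parental genotypes: a parent "informative" for
    variant A carries A but not B.  With a single genotyped parent
    carrying exactly one of the two variants, the other variant is
    attributed to the untyped parent and the phase counted as trio
    evidence.  A child variant carried by neither genotyped parent is a
    Mendelian inconsistency: flagged, and the status falls back to
    ``biallelic_phase_unknown``.

    ``genotyped_samples`` limits which pedigree members are believed to
    have genotype data (absent calls read as hom_ref only for those);
    ``None`` means every pedigree member.
    """
    genes = {v.gene for v in variants_of_gene}
    if len(genes) > 1:
        raise ValueError(f"variants span multiple genes: {sorted(map(str, genes))}")
    gene = next(iter(genes)) if genes else None

    homs = sorted(
        (v for v in variants_of_gene if v.genotype_of(sample_id) == HOM_ALT),
        key=_popaf_sort_key,
    )
    hets = sorted(
        (v for v in variants_of_gene if v.genotype_of(sample_id) == HET),
        key=_popaf_sort_key,
    )

    if homs:
        return ZygosityCall(sample_id, gene, "homozygous", (homs[0].key,))
    if not hets:
        return ZygosityCall(sample_id, gene, "none")
    if len(hets) == 1:
        return ZygosityCall(sample_id, gene, "single_het", (hets[0].key,))

    var_a, var_b = hets[0], hets[1]
    extra = tuple(v.key for v in hets[2:])
    keys = (var_a.key, var_b.key) + extra

    def typed(parent: Individual | None) -> Individual | None:
        if parent is None:
            return None
        if genotyped_samples is not None and parent.sample_id not in genotyped_samples:
            return None
        return parent

    mother, father = (typed(p) for p in pedigree.parents_of(sample_id))

    if mother is None and father is None:
        return ZygosityCall(sample_id, gene, "biallelic_phase_unknown", keys)

    def carrier_profile(parent: Individual) -> tuple[bool | None, bool | None]:
        return (_carries(var_a, parent.sample_id), _carries(var_b, parent.sample_id))

    profiles = {p.sample_id: carrier_profile(p) for p in (mother, father) if p}

    # Mendelian check: a het variant carried by neither genotyped parent
    # (both parents typed, both definitively non-carrier) is inconsistent.
    if mother is not None and father is not None:
        for i, _var in enumerate((var_a, var_b)):
            statuses = [profiles[p.sample_id][i] for p in (mother, father)]
            if statuses == [False, False]:
                return ZygosityCall(
                    sample_id, gene, "biallelic_phase_unknown", keys, "mendelian_error"
                )

    def opposite(p1: tuple, p2: tuple) -> bool:
        # p1 carries exactly variant A, p2 exactly variant B
        return p1 == (True, False) and p2 == (False, True)

    if mother is not None and father is not None:
        pm, pf = profiles[mother.sample_id], profiles[father.sample_id]
        if opposite(pm, pf) or opposite(pf, pm):
            return ZygosityCall(
                sample_id, gene, "compound_het_confirmed", keys, "trio"
            )
        return ZygosityCall(sample_id, gene, "biallelic_phase_unknown", keys)

    # single genotyped parent: carrying exactly one of the two variants
    # pins that variant to this parent and the other to the untyped one
    parent = mother if mother is not None else father
    pa, pb = profiles[parent.sample_id]
    if (pa, pb) in ((True, False), (False, True)):
        return ZygosityCall(sample_id, gene, "compound_het_confirmed", keys, "trio")
    return ZygosityCall(sample_id, gene, "biallelic_phase_unknown", keys)
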