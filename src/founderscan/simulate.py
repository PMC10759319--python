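"""Seeded generator of synthetic cohorts with planted ground truth.

The generator emulates the structure of a national rare-disease study:
225 case families (234 affected members: mostly singletons, a few trios
and affected sib-pairs) against 649 unrelated controls, genotyped over a
165-gene panel.  One founder variant is planted at a case carrier
frequency of 5% versus 0.3% in controls; a configurable number of null
background variants, low-allelic-fraction artifact calls, a panel-
overlapping structural variant, and a 10-marker microsatellite map with
a conserved founder haplotype over a 0.7 Mb window complete the picture.

Every public entry point takes an explicit seed (through
:class:`SimConfig` or a numpy Generator); identical configuration yields
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cohort import (
    HET,
    HOM_ALT,
    AnnotatedVariant,
    GenePanel,
    Individual,
    Pedigree,
    SVInterval,
    VariantCall,
    VariantKey,
)
from .haplotype import MarkerMap
from . import io as fio

__all__ = [
    "SimConfig",
    "SimTruth",
    "DEFAULT_MARKERS",
    "default_marker_map",
    "make_index_pedigree",
    "sample_enrichment_panel",
    "generate_cohort",
    "generate_marker_data",
]

# The ten dinucleotide-repeat markers flanking the locus, with synthetic
# positions (the real physical positions are not bundled; any map can be
# supplied).  The conserved window D1S2640..D1S2751 spans 0.7 Mb and the
# locus sits between D1S2640 and D1S215.
DEFAULT_MARKERS: tuple[tuple[str, int], ...] = (
    ("D1S416", 200_000),
    ("D1S212", 600_000),
    ("D1S2786", 1_000_000),
    ("D1S460", 1_300_000),
    ("D1S2640", 1_600_000),
    ("D1S215", 1_900_000),
    ("D1S2751", 2_300_000),
    ("D1S2883", 2_600_000),
    ("D1S2818", 2_900_000),
    ("D1S466", 3_200_000),
)
DEFAULT_LOCUS_BP = 1_750_000
DEFAULT_WINDOW = ("D1S2640", "D1S2751")

FOUNDER_GENE = "NPHS2"
FOUNDER_KEY = VariantKey("chr1", 1_750_123, "G", "A")


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; the defaults are the emulated study conditions."""

    seed: int
    n_case_families: int = 225
    trio_fraction: float = 0.05
    sib_pair_fraction: float = 0.04
    n_controls: int = 649
    n_panel_genes: int = 165
    n_background_variants: int = 200
    bg_carrier_prob_cases: float = 0.005
    bg_carrier_prob_controls: float = 0.005
    founder_case_carrier_freq: float = 0.05
    founder_control_carrier_freq: float = 0.003
    founder_hom_fraction: float = 0.15
    artifact_fraction: float = 0.02
    popfreq_common_fraction: float = 0.3
    consequence_mix: tuple[tuple[str, float], ...] = (
        ("nonsynonymous", 0.55),
        ("splicing", 0.10),
        ("synonymous", 0.20),
        ("other", 0.15),
    )
    regulatory_fraction: float = 0.2
    n_marker_alleles: int = 8
    marker_missing_rate: float = 0.0
    ensure_informative_flanks: bool = True
    include_sv: bool = True

    def __post_init__(self) -> None:
        probs = [
            self.trio_fraction, self.sib_pair_fraction,
            self.bg_carrier_prob_cases, self.bg_carrier_prob_controls,
            self.founder_case_carrier_freq, self.founder_control_carrier_freq,
            self.founder_hom_fraction, self.artifact_fraction,
            self.popfreq_common_fraction, self.regulatory_fraction,
            self.marker_missing_rate,
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probability parameters must lie in [0, 1]")
        if abs(sum(w for _, w in self.consequence_mix) - 1.0) > 1e-9:
            raise ValueError("consequence mix must sum to 1")
        if self.n_marker_alleles < 2:
            raise ValueError("need at least two marker alleles")


@dataclass
class SimTruth:
    """Planted ground truth, consistent with the emitted files."""

    founder_key: VariantKey
    carriers: dict[str, str]  # sample_id -> "het" | "hom"
    transmitting_parent: dict[str, str] = field(default_factory=dict)  # family -> mother|father
    phasing_families: list[tuple[str, str, str]] = field(default_factory=list)  # (family, child, hom|het)
    unphased_carriers: list[str] = field(default_factory=list)
    founder_haplotype: dict[str, int] = field(default_factory=dict)
    window_markers: tuple[str, str] = DEFAULT_WINDOW
    background_counts: dict[str, tuple[int, int]] = field(default_factory=dict)
    sv_sample: str | None = None

    def to_json(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["founder_key"] = str(self.founder_key)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def default_marker_map() -> MarkerMap:
    return MarkerMap(
        markers=tuple((name, "chr1", pos) for name, pos in DEFAULT_MARKERS),
        locus_position=DEFAULT_LOCUS_BP,
    )


# ---------------------------------------------------------------------------
# fast in-memory cohort for replicate studies

def make_index_pedigree(n_cases: int = 225, n_controls: int = 649) -> Pedigree:
    """Singleton pedigree of index cases and controls (the post-reduction
    cohort shape), for enrichment replicate studies."""
    individuals = {}
    for i in range(n_cases):
        sid = f"F{i + 1:04d}/I"
        individuals[sid] = Individual(
            sample_id=sid, family_id=f"F{i + 1:04d}", affected=True,
            cohort="case", is_index=True,
        )
    for i in range(n_controls):
        sid = f"C{i + 1:04d}"
        individuals[sid] = Individual(
            sample_id=sid, family_id=f"CF{i + 1:04d}", cohort="control",
        )
    return Pedigree(individuals)


def sample_enrichment_panel(
    pedigree: Pedigree,
    rng: np.random.Generator,
    n_null: int = 200,
    planted: tuple[float, float, float] | None = (0.05, 0.003, 0.15),
) -> tuple[list[AnnotatedVariant], VariantKey | None]:
    """Draw a panel of rare variants with per-sample carrier calls.

    Null variants receive independent Bernoulli(0.005) carriers in each
    cohort; the optional planted variant uses (case_freq, control_freq,
    hom_fraction).  Calls are sparse (carriers only).  Returns the
    variants and the planted key (None when not planted).
    """
    case_ids = np.array(sorted(p.sample_id for p in pedigree.cases() if p.is_index))
    control_ids = np.array(sorted(p.sample_id for p in pedigree.controls()))
    variants: list[AnnotatedVariant] = []
    planted_key: VariantKey | None = None

    def draw(ids: np.ndarray, prob: float) -> np.ndarray:
        k = rng.binomial(len(ids), prob)
        if k == 0:
            return ids[:0]
        return rng.choice(ids, size=k, replace=False)

    if planted is not None:
        case_freq, control_freq, hom_fraction = planted
        planted_key = FOUNDER_KEY
        calls = {}
        for sid in draw(case_ids, case_freq):
            gt = HOM_ALT if rng.random() < hom_fraction else HET
            calls[str(sid)] = VariantCall(str(sid), gt)
        for sid in draw(control_ids, control_freq):
            calls[str(sid)] = VariantCall(str(sid), HET)
        variants.append(AnnotatedVariant(
            key=planted_key, gene=FOUNDER_GENE, consequence="nonsynonymous",
            population_af=0.0001, calls=calls,
        ))
    for i in range(n_null):
        key = VariantKey(f"chr{(i % 22) + 1}", 5_000_000 + 1_000 * i, "C", "T")
        calls = {}
        for sid in draw(case_ids, 0.005):
            calls[str(sid)] = VariantCall(str(sid), HET)
        for sid in draw(control_ids, 0.005):
            calls[str(sid)] = VariantCall(str(sid), HET)
        variants.append(AnnotatedVariant(
            key=key, gene=f"GENE{i + 1:03d}", consequence="nonsynonymous",
            population_af=0.001, calls=calls,
        ))
    return variants, planted_key


# ---------------------------------------------------------------------------
# full cohort with files

def _build_panel(config: SimConfig) -> GenePanel:
    genes: dict[str, list[tuple[str, int, int]]] = {
        FOUNDER_GENE: [("chr1", 1_740_000, 1_766_000)],
    }
    for i in range(1, config.n_panel_genes):
        chrom = f"chr{(i % 22) + 1}"
        start = 5_000_000 + 100_000 * i
        genes[f"GENE{i:03d}"] = [(chrom, start, start + 30_000)]
    return GenePanel(genes)


def _build_pedigree(config: SimConfig, rng: np.random.Generator):
    """Family structures and founder-carrier assignment.

    Carrier status is drawn per index case first (Binomial cohort carrier
    count); the first two carrier families then become the parent-
    available phasing trios — one homozygous proband, one heterozygous —
    mirroring a study design where segregation analysis is done in the
    families where parents could be sampled.
    """
    n = config.n_case_families
    n_trio = round(config.trio_fraction * n)
    n_sib = round(config.sib_pair_fraction * n)

    carrier = rng.random(n) < config.founder_case_carrier_freq
    hom = rng.random(n) < config.founder_hom_fraction
    carrier_families = [i for i in range(n) if carrier[i]]
    phasing: list[tuple[int, str]] = []
    if len(carrier_families) >= 1:
        phasing.append((carrier_families[0], "hom"))
    # the heterozygous phasing trio is only drawn when at least two
    # carriers remain unphased, so boundary-informative recombinants
    # can always be placed among the unphased comparison carriers
    if len(carrier_families) >= 4:
        phasing.append((carrier_families[1], "het"))
    phasing_ids = {i for i, _ in phasing}

    structures: dict[int, str] = {i: "trio" for i in phasing_ids}
    pool = [i for i in range(n) if i not in phasing_ids]
    for i in pool[: max(0, n_trio - len(phasing_ids))]:
        structures[i] = "trio"
    remaining = [i for i in pool if structures.get(i) is None]
    for i in remaining[:n_sib]:
        structures[i] = "sib_pair"

    individuals: dict[str, Individual] = {}
    truth = SimTruth(founder_key=FOUNDER_KEY, carriers={})
    for i in range(n):
        fam = f"F{i + 1:04d}"
        structure = structures.get(i, "singleton")
        index_id = f"{fam}/I"
        forced = dict(phasing).get(i)
        is_carrier = bool(carrier[i])
        is_hom = {"hom": True, "het": False}.get(forced, bool(hom[i]))
        if structure == "trio":
            mother_id, father_id = f"{fam}/M", f"{fam}/F"
            individuals[mother_id] = Individual(mother_id, fam, sex="female", cohort="case")
            individuals[father_id] = Individual(father_id, fam, sex="male", cohort="case")
            individuals[index_id] = Individual(
                index_id, fam, father_id=father_id, mother_id=mother_id,
                affected=True, cohort="case", is_index=True,
            )
            if is_carrier:
                if is_hom:
                    truth.carriers[index_id] = "hom"
                    truth.carriers[mother_id] = "het"
                    truth.carriers[father_id] = "het"
                else:
                    truth.carriers[index_id] = "het"
                    parent = "mother" if rng.random() < 0.5 else "father"
                    truth.transmitting_parent[fam] = parent
                    truth.carriers[mother_id if parent == "mother" else father_id] = "het"
        else:
            individuals[index_id] = Individual(
                index_id, fam, affected=True, cohort="case", is_index=True,
            )
            if is_carrier:
                truth.carriers[index_id] = "hom" if is_hom else "het"
            if structure == "sib_pair":
                sib_id = f"{fam}/II"
                individuals[sib_id] = Individual(
                    sib_id, fam, affected=True, cohort="case",
                )
                if is_carrier and not is_hom and rng.random() < 0.5:
                    truth.carriers[sib_id] = "het"
        if forced is not None:
            truth.phasing_families.append((fam, index_id, forced))
            if forced == "hom":
                truth.transmitting_parent.setdefault(fam, "both")

    for i in range(config.n_controls):
        sid = f"C{i + 1:04d}"
        individuals[sid] = Individual(sid, f"CF{i + 1:04d}", cohort="control")
        if rng.random() < config.founder_control_carrier_freq:
            truth.carriers[sid] = "het"

    phasing_children = {child for _, child, _ in truth.phasing_families}
    truth.unphased_carriers = sorted(
        sid for sid, z in truth.carriers.items()
        if sid.endswith("/I") and sid not in phasing_children
        and individuals[sid].cohort == "case"
    )
    return Pedigree(individuals), truth


def _het_af(rng) -> float:
    return int(rng.integers(3500, 6501)) / 10_000


def _hom_af(rng) -> float:
    return int(rng.integers(9500, 10001)) / 10_000


def _artifact_af(rng) -> float:
    return int(rng.integers(500, 2900)) / 10_000


def generate_cohort(
    config: SimConfig, out_dir: str | Path | None = None
) -> dict:
    """Generate the full synthetic cohort.

    Returns a dict with keys ``variants``, ``samples``, ``pedigree``,
    ``panel``, ``svs``, ``truth`` and, when ``out_dir`` is given, the
    written file ``paths`` (VCF, PED, cohort TSV, annotation TSV, panel
    BED, SV TSV, truth JSON).
    """
    root = np.random.SeedSequence(config.seed)
    cohort_ss, _marker_ss, = root.spawn(2)
    rng = np.random.default_rng(cohort_ss)

    pedigree, truth = _build_pedigree(config, rng)
    panel = _build_panel(config)
    gene_names = list(panel.genes)

    variants: list[AnnotatedVariant] = []
    # planted founder variant
    founder_calls: dict[str, VariantCall] = {}
    for sid, zyg in truth.carriers.items():
        gt = HOM_ALT if zyg == "hom" else HET
        af = _hom_af(rng) if zyg == "hom" else _het_af(rng)
        founder_calls[sid] = VariantCall(sid, gt, af)
    variants.append(AnnotatedVariant(
        key=FOUNDER_KEY, gene=FOUNDER_GENE, consequence="nonsynonymous",
        population_af=0.0001, calls=founder_calls,
    ))

    # null background variants inside panel genes
    case_index_ids = sorted(
        p.sample_id for p in pedigree.cases() if p.is_index
    )
    control_ids = sorted(p.sample_id for p in pedigree.controls())
    cons_names = [c for c, _ in config.consequence_mix]
    cons_weights = np.array([w for _, w in config.consequence_mix])
    for i in range(config.n_background_variants):
        gene = gene_names[1:][i % (len(gene_names) - 1)]
        chrom, start, end = panel.genes[gene][0]
        pos = int(start + 1 + (i * 977) % (end - start - 2))
        ref, alt = [("C", "T"), ("G", "A"), ("A", "G"), ("T", "C")][i % 4]
        key = VariantKey(chrom, pos, ref, alt)
        calls: dict[str, VariantCall] = {}
        for ids, prob in (
            (case_index_ids, config.bg_carrier_prob_cases),
            (control_ids, config.bg_carrier_prob_controls),
        ):
            k = rng.binomial(len(ids), prob)
            for sid in (rng.choice(ids, size=k, replace=False) if k else []):
                calls[str(sid)] = VariantCall(str(sid), HET, _het_af(rng))
        if rng.random() < config.popfreq_common_fraction:
            pop_af = float(np.round(rng.uniform(0.02, 0.10), 4))
        elif rng.random() < 0.2:
            pop_af = None  # absent from the population reference
        else:
            pop_af = float(np.round(rng.uniform(0.0, 0.008), 4))
        consequence = str(rng.choice(cons_names, p=cons_weights))
        sources = frozenset()
        if consequence in ("synonymous", "other") and rng.random() < config.regulatory_fraction:
            sources = frozenset({str(rng.choice(["RefSeq", "Ensembl", "Encode", "ORegAnno"]))})
        truth.background_counts[str(key)] = (
            sum(1 for s in calls if s in set(case_index_ids)),
            sum(1 for s in calls if s in set(control_ids)),
        )
        variants.append(AnnotatedVariant(
            key=key, gene=gene, consequence=consequence,
            regulatory_sources=sources, population_af=pop_af, calls=calls,
        ))

    # low-allelic-fraction artifact calls sprinkled over non-carriers
    all_ids = sorted(pedigree.individuals)
    total_calls = sum(len(v.calls) for v in variants)
    n_artifacts = round(config.artifact_fraction * total_calls)
    for _ in range(n_artifacts):
        v = variants[int(rng.integers(len(variants)))]
        sid = all_ids[int(rng.integers(len(all_ids)))]
        if sid in v.calls:
            continue
        v.calls[sid] = VariantCall(sid, HET, _artifact_af(rng))

    svs: list[SVInterval] = []
    if config.include_sv:
        sv_sample = case_index_ids[int(rng.integers(len(case_index_ids)))]
        svs.append(SVInterval("chr1", 1_741_000, 1_743_500, "DEL", sv_sample))
        truth.sv_sample = sv_sample
        # decoy outside every panel interval
        svs.append(SVInterval("chr2", 100_000, 140_000, "DUP", sv_sample))

    samples = all_ids
    result = {
        "variants": variants,
        "samples": samples,
        "pedigree": pedigree,
        "panel": panel,
        "svs": svs,
        "truth": truth,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out / "cohort.vcf",
            "ped": out / "cohort.ped",
            "cohort": out / "cohort_labels.tsv",
            "annotations": out / "annotations.tsv",
            "panel": out / "panel.bed",
            "svs": out / "svs.tsv",
            "truth": out / "truth.json",
        }
        fio.write_vcf(paths["vcf"], variants, samples)
        fio.write_ped(paths["ped"], pedigree)
        fio.write_cohort_labels(paths["cohort"], pedigree)
        fio.write_annotations(paths["annotations"], variants)
        fio.write_panel_bed(paths["panel"], panel)
        fio.write_sv_table(paths["svs"], svs)
        truth.to_json(paths["truth"])
        result["paths"] = paths
    return result


# ---------------------------------------------------------------------------
# marker haplotypes

def generate_marker_data(
    config: SimConfig,
    truth: SimTruth,
    out_dir: str | Path | None = None,
    marker_map: MarkerMap | None = None,
) -> tuple[MarkerMap, dict[str, dict[str, tuple[int, int] | None]]]:
    """Microsatellite genotypes for the phasing trios and the unphased
    founder carriers.

    Founder chromosomes carry the planted haplotype across the conserved
    window and recombine onto random background haplotypes outside it;
    trio genotypes are Mendelian-consistent by construction.  With
    ``ensure_informative_flanks`` the first two unphased carriers are
    given a recombination immediately outside each window edge plus a
    genotype there that excludes the founder allele, so that a noise-free
    run recovers the window boundaries exactly.
    """
    marker_map = marker_map or default_marker_map()
    names = list(marker_map.names)
    if not set(truth.window_markers) <= set(names):
        raise ValueError("window boundary markers must be on the map")
    w_left = names.index(truth.window_markers[0])
    w_right = names.index(truth.window_markers[1])
    if w_left >= w_right:
        raise ValueError("window markers out of order")

    root = np.random.SeedSequence(config.seed)
    _cohort_ss, marker_ss = root.spawn(2)
    rng = np.random.default_rng(marker_ss)

    n_markers = len(names)
    codes = [150 + 2 * k for k in range(config.n_marker_alleles)]
    freqs = rng.dirichlet(np.ones(config.n_marker_alleles), size=n_markers)
    if not truth.founder_haplotype:
        truth.founder_haplotype = {
            name: int(codes[rng.choice(config.n_marker_alleles, p=freqs[i])])
            for i, name in enumerate(names)
        }
    founder = [truth.founder_haplotype[name] for name in names]

    def background_chrom() -> list[int]:
        return [
            int(codes[rng.choice(config.n_marker_alleles, p=freqs[i])])
            for i in range(n_markers)
        ]

    def founder_chrom(left_ext: int | None = None, right_ext: int | None = None) -> list[int]:
        # founder segment covers marker indices [left_ext, right_ext]
        if left_ext is None:
            left_ext = int(rng.integers(0, w_left + 1))
        if right_ext is None:
            right_ext = int(rng.integers(w_right, n_markers))
        bg = background_chrom()
        return [
            founder[i] if left_ext <= i <= right_ext else bg[i]
            for i in range(n_markers)
        ]

    genotypes: dict[str, dict[str, tuple[int, int] | None]] = {}

    def set_genotype(sid: str, chrom_a: list[int], chrom_b: list[int]) -> None:
        genotypes[sid] = {
            names[i]: (chrom_a[i], chrom_b[i]) for i in range(n_markers)
        }

    def off_alleles(i: int, count: int = 1) -> list[int]:
        return [c for c in codes if c != founder[i]][:count]

    n_unphased = len(truth.unphased_carriers)
    degenerate = config.ensure_informative_flanks and n_unphased == 0

    # phasing trio families
    for fam, child, kind in truth.phasing_families:
        mother_id, father_id = f"{fam}/M", f"{fam}/F"
        if kind == "hom":
            if degenerate:
                # no unphased carriers to delimit the window: let the
                # proband's own chromosomes recombine right at both
                # edges onto distinct alleles, so the consensus itself
                # ends at the window
                fm = founder_chrom(left_ext=w_left, right_ext=w_right)
                ff = founder_chrom(left_ext=w_left, right_ext=w_right)
                for edge, side in ((w_left - 1, "L"), (w_right + 1, "R")):
                    if 0 <= edge < n_markers:
                        pair = off_alleles(edge, 2)
                        fm[edge] = pair[0]
                        ff[edge] = pair[-1] if len(pair) > 1 else pair[0]
            else:
                fm, ff = founder_chrom(), founder_chrom()
            set_genotype(mother_id, fm, background_chrom())
            set_genotype(father_id, ff, background_chrom())
            set_genotype(child, fm, ff)
        else:
            parent = truth.transmitting_parent.get(fam, "mother")
            fc = founder_chrom()
            other_a, other_b = background_chrom(), background_chrom()
            transmitted_other = other_a
            if parent == "mother":
                set_genotype(mother_id, fc, background_chrom())
                set_genotype(father_id, other_a, other_b)
            else:
                set_genotype(father_id, fc, background_chrom())
                set_genotype(mother_id, other_a, other_b)
            set_genotype(child, fc, transmitted_other)

    # unphased carriers; the first one (or two) carry recombinations
    # immediately outside each window edge with a genotype that excludes
    # the founder allele there, so the boundaries are identifiable
    def force_left(fc: list[int], other: list[int]) -> None:
        if w_left > 0:
            off = off_alleles(w_left - 1)[0]
            fc[w_left - 1] = off
            other[w_left - 1] = off

    def force_right(fc: list[int], other: list[int]) -> None:
        if w_right < n_markers - 1:
            off = off_alleles(w_right + 1)[0]
            fc[w_right + 1] = off
            other[w_right + 1] = off

    for idx, sid in enumerate(truth.unphased_carriers):
        is_hom = truth.carriers.get(sid) == "hom"
        if config.ensure_informative_flanks and idx == 0 and n_unphased == 1:
            fc = founder_chrom(left_ext=w_left, right_ext=w_right)
            other = (founder_chrom(left_ext=w_left, right_ext=w_right)
                     if is_hom else background_chrom())
            force_left(fc, other)
            force_right(fc, other)
        elif config.ensure_informative_flanks and idx == 0:
            fc = founder_chrom(left_ext=w_left)
            other = (founder_chrom(left_ext=w_left)
                     if is_hom else background_chrom())
            force_left(fc, other)
        elif config.ensure_informative_flanks and idx == 1:
            fc = founder_chrom(right_ext=w_right)
            other = (founder_chrom(right_ext=w_right)
                     if is_hom else background_chrom())
            force_right(fc, other)
        else:
            fc = founder_chrom()
            other = founder_chrom() if is_hom else background_chrom()
        set_genotype(sid, fc, other)

    if config.marker_missing_rate > 0:
        for sid in truth.unphased_carriers:
            for name in names:
                if rng.random() < config.marker_missing_rate:
                    genotypes[sid][name] = None

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .haplotype import write_marker_genotypes, write_marker_map

        write_marker_map(out / "marker_map.tsv", marker_map)
        write_marker_genotypes(out / "marker_genotypes.tsv", genotypes)
    return marker_map, genotypes
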