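"""Pipeline orchestration and cohort clinical summaries.

The clinical side summarises a per-patient table (ages at first
symptoms, biopsy-confirmed diagnosis, kidney failure, proteinuria and
edema status) by genotype class.  Onset entries may be a number of years
or the token ``childhood``; numeric ages below the adulthood threshold
(18 years) count as childhood onset and are excluded from the
adult-onset mean, reported instead as a separate count — late, mild
presentations are exactly what makes such a founder genotype escape
pediatric ascertainment.

:func:`run_all` chains the whole pipeline — optional simulation,
filtration cascade, enrichment, zygosity, haplotype sharing, clinical
report — and writes a manifest with file hashes for reproducibility.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import pandas as pd

from . import io as fio
from .cohort import HET, HOM_ALT, classify_zygosity
from .filtering import CascadeConfig, run_cascade
from .haplotype import (
    consensus_founder_haplotype,
    phase_homozygote,
    phase_trio,
    read_marker_genotypes,
    read_marker_map,
    shared_region,
)
from .stats import (
    EnrichmentConfig,
    allele_frequency_percent,
    predict_founders,
)

__all__ = [
    "RunConfig",
    "ClinicalTable",
    "ADULT_ONSET_YEARS",
    "demo_clinical_path",
    "round_half_up",
    "summarize_ages",
    "group_summaries",
    "run_all",
]

log = logging.getLogger("founderscan")

ADULT_ONSET_YEARS = 18.0

BIALLELIC_CLASSES = ("biallelic", "biallelic_other")

_CLINICAL_COLUMNS = [
    "family_id", "sample_id", "genotype_class", "is_index", "onset_age",
    "biopsy_fsgs_age", "proteinuria_g_day", "edema_at_onset", "esrd",
    "esrd_age", "ckd_stage",
]


def demo_clinical_path() -> Path:
    """Bundled example clinical table (the worked example of the docs)."""
    return Path(resources.files("founderscan") / "data" / "demo_clinical.tsv")


def round_half_up(value: float, decimals: int = 1) -> float:
    """Round half away from zero, the convention of the printed reports."""
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass
class ClinicalTable:
    """Validated per-patient clinical table."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(_CLINICAL_COLUMNS) - set(self.frame.columns)
        if missing:
            raise ValueError(f"clinical table missing columns {sorted(missing)}")
        for col in ("biopsy_fsgs_age", "esrd_age"):
            ages = pd.to_numeric(self.frame[col], errors="coerce")
            if (ages.dropna() < 0).any():
                raise ValueError(f"negative ages in {col}")

    @classmethod
    def read(cls, path) -> "ClinicalTable":
        frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        frame["is_index"] = frame["is_index"].astype(str).isin(("1", "true", "True"))
        return cls(frame)

    def rows(self, genotype_class: str, index_only: bool = False) -> pd.DataFrame:
        sub = self.frame[self.frame["genotype_class"] == genotype_class]
        if index_only:
            sub = sub[sub["is_index"]]
        return sub


def summarize_ages(values) -> tuple[float, float | None, int]:
    """Arithmetic mean and sample standard deviation (n-1 denominator).

    The SD is undefined for a single value and returned as ``None``.
    """
    values = [float(v) for v in values]
    if not values:
        raise ValueError("no values to summarize")
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        return mean, None, 1
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var), n


def _numeric(series: pd.Series) -> list[float]:
    return [float(v) for v in series if str(v).strip() not in ("", "nan")
            and _is_number(v)]


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def group_summaries(
    clinical: ClinicalTable,
    n_cohort: int | None = None,
    adult_onset_years: float = ADULT_ONSET_YEARS,
) -> dict:
    """Clinical summary per genotype class.

    Biallelic patients (confirmed or phase-unknown two-variant
    genotypes) are summarised over every tabulated family member —
    clinical description does not drop relatives the way enrichment
    statistics must.  Heterozygous-carrier summaries use index cases
    only.  Onset means cover adult onsets (>= ``adult_onset_years``);
    childhood onsets (token or numeric below the threshold) are counted
    separately.  With ``n_cohort`` the biallelic fraction of the full
    cohort is included.
    """
    report: dict = {}
    for cls_name, index_only in (("biallelic", False), ("het", True)):
        rows = clinical.rows(cls_name, index_only=index_only)
        if rows.empty:
            continue
        onset_raw = [str(v).strip() for v in rows["onset_age"]]
        adult = [float(v) for v in onset_raw if _is_number(v)
                 and float(v) >= adult_onset_years]
        childhood = [v for v in onset_raw
                     if v and (not _is_number(v) or float(v) < adult_onset_years)]
        entry: dict = {"n": int(len(rows)), "n_childhood_onset": len(childhood)}
        if adult:
            mean, sd, n = summarize_ages(adult)
            entry["onset_adult_mean"] = mean
            entry["onset_adult_sd"] = sd
            entry["n_adult_onset"] = n
        biopsy = _numeric(rows["biopsy_fsgs_age"])
        if biopsy:
            mean, sd, n = summarize_ages(biopsy)
            entry["biopsy_age_mean"] = mean
            entry["biopsy_age_sd"] = sd
            entry["n_biopsied"] = n
        esrd_ages = _numeric(rows["esrd_age"])
        if esrd_ages:
            mean, sd, n = summarize_ages(esrd_ages)
            entry["esrd_age_mean"] = mean
            entry["esrd_age_sd"] = sd
        edema = [str(v).strip() for v in rows["edema_at_onset"] if str(v).strip()]
        if edema:
            entry["edema_at_onset_fraction"] = edema.count("Y") / len(edema)
        esrd_flags = [str(v).strip() for v in rows["esrd"] if str(v).strip()]
        if esrd_flags:
            entry["esrd_fraction"] = esrd_flags.count("Y") / len(esrd_flags)
        report[cls_name] = entry
    if n_cohort is not None:
        n_biallelic = sum(
            len(clinical.rows(c)) for c in BIALLELIC_CLASSES
        )
        report["biallelic_fraction_of_cohort"] = n_biallelic / n_cohort
        report["n_biallelic"] = n_biallelic
        report["n_cohort"] = n_cohort
    return report


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class RunConfig:
    """Everything :func:`run_all` needs.

    When ``simulate`` is set, inputs are generated into ``out_dir`` first
    and the path fields are ignored.
    """

    out_dir: Path
    vcf: Path | None = None
    annotations: Path | None = None
    ped: Path | None = None
    cohort: Path | None = None
    panel: Path | None = None
    svs: Path | None = None
    marker_map: Path | None = None
    marker_genotypes: Path | None = None
    clinical: Path | None = None
    n_cohort_members: int | None = None
    cascade: CascadeConfig = field(default_factory=CascadeConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    simulate: "object | None" = None  # SimConfig
    report_decimals: int = 2


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(Path(path).read_bytes())
    return digest.hexdigest()


def enrichment_table(results, decimals: int = 2) -> pd.DataFrame:
    rows = []
    for r in results:
        counts = r.counts
        rows.append({
            "chrom": r.key.chrom, "pos": r.key.pos, "ref": r.key.ref,
            "alt": r.key.alt,
            "gene": r.gene,
            "x_cases": counts.x_cases, "n_cases": counts.n_cases,
            "x_controls": counts.x_controls, "n_controls": counts.n_controls,
            "af_cases_pct": allele_frequency_percent(
                counts.a_cases, counts.n_cases, decimals) if counts.n_cases else None,
            "af_controls_pct": allele_frequency_percent(
                counts.a_controls, counts.n_controls, decimals) if counts.n_controls else None,
            "or": r.or_value, "ci_low": r.or_ci_low, "ci_high": r.or_ci_high,
            "p_or": r.p_or_raw, "p_or_bonf": r.p_or_bonf,
            "p_hyper": r.p_hyper_raw, "p_hyper_bonf": r.p_hyper_bonf,
            "founder": r.founder,
        })
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> dict:
    """Simulate (optionally), filter, enrich, classify zygosity, detect
    the shared haplotype region and summarise clinical data.

    Returns the report bundle; all artifacts plus a manifest of file
    hashes land in ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    outputs: dict[str, Path] = {}

    if config.simulate is not None:
        log.info("[simulate] generating synthetic cohort into %s", out)
        from .simulate import generate_cohort, generate_marker_data

        sim = generate_cohort(config.simulate, out_dir=out / "sim")
        generate_marker_data(config.simulate, sim["truth"], out_dir=out / "sim")
        paths = sim["paths"]
        config.vcf = paths["vcf"]
        config.annotations = paths["annotations"]
        config.ped = paths["ped"]
        config.cohort = paths["cohort"]
        config.panel = paths["panel"]
        config.svs = paths["svs"]
        config.marker_map = out / "sim" / "marker_map.tsv"
        config.marker_genotypes = out / "sim" / "marker_genotypes.tsv"

    for name in ("vcf", "annotations", "ped", "cohort", "panel"):
        path = getattr(config, name)
        if path is None or not Path(path).exists():
            raise FileNotFoundError(f"required input {name!r} missing: {path}")

    log.info("[parse] reading inputs")
    variants, samples = fio.parse_vcf(config.vcf, config.annotations)
    pedigree = fio.parse_ped(config.ped, config.cohort)
    panel = fio.read_panel(config.panel)
    svs = fio.read_sv_table(config.svs) if config.svs and Path(config.svs).exists() else []

    log.info("[filter] cascade over %d variants, %d SVs", len(variants), len(svs))
    callset, traces = run_cascade(variants, svs, panel, pedigree, config.cascade)
    trace_frame = pd.DataFrame([
        {"stage": t.stage, "variants_in": t.variants_in,
         "variants_out": t.variants_out, "calls_removed": t.calls_removed}
        for t in traces
    ])
    outputs["filter_trace"] = out / "filter_trace.tsv"
    trace_frame.to_csv(outputs["filter_trace"], sep="\t", index=False)
    report["filter_trace"] = trace_frame.to_dict("records")
    report["final_call_set_size"] = len(callset)
    report["svs_retained"] = len(callset.svs)

    log.info("[enrich] %d variants in final call set", len(callset))
    results = predict_founders(
        callset.variants, pedigree, config.enrichment, index_set=callset.index_set
    )
    table = enrichment_table(results, config.report_decimals)
    outputs["enrichment"] = out / "enrichment.tsv"
    table.to_csv(outputs["enrichment"], sep="\t", index=False)
    outputs["enrichment_json"] = out / "enrichment.json"
    with open(outputs["enrichment_json"], "w") as fh:
        json.dump(table.to_dict("records"), fh, indent=1, default=str)
    founders = [r for r in results if r.founder]
    report["founder_candidates"] = [str(r.key) for r in founders]
    report["top_variant"] = str(results[0].key) if results else None

    # zygosity of the top candidate's gene, per carrier sample
    if results:
        top_key = results[0].key
        top_gene = next(
            (v.gene for v in callset.variants if v.key == top_key), None
        )
        gene_variants = [v for v in callset.variants if v.gene == top_gene]
        carrier_samples = sorted({
            sid for v in gene_variants for sid, c in v.calls.items() if c.is_alt
        })
        zygosity = [
            classify_zygosity(gene_variants, sid, pedigree)
            for sid in carrier_samples
        ]
        report["zygosity"] = [
            {"sample_id": z.sample_id, "status": z.status,
             "variants": [str(k) for k in z.variant_keys],
             "phase_evidence": z.phase_evidence}
            for z in zygosity
        ]

    if config.marker_map and Path(config.marker_map).exists():
        log.info("[haplotype] shared-region detection")
        marker_map = read_marker_map(config.marker_map)
        genotypes = read_marker_genotypes(config.marker_genotypes)
        region = _haplotype_analysis(
            marker_map, genotypes, variants, pedigree, report
        )
        if region is not None:
            outputs["region"] = out / "shared_region.json"
            with open(outputs["region"], "w") as fh:
                json.dump(report["shared_region"], fh, indent=1)

    if config.clinical and Path(config.clinical).exists():
        log.info("[report] clinical summaries")
        clinical = ClinicalTable.read(config.clinical)
        report["clinical"] = group_summaries(
            clinical, n_cohort=config.n_cohort_members
        )

    manifest = {
        name: {"path": str(path), "sha256": _sha256(path)}
        for name, path in outputs.items()
    }
    outputs["manifest"] = out / "manifest.json"
    with open(outputs["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    report["manifest"] = manifest
    return report


def _haplotype_analysis(marker_map, genotypes, variants, pedigree, report):
    """Phase carrier trios at the top locus and extend the shared region."""
    from .simulate import FOUNDER_KEY

    founder_variant = next(
        (v for v in variants if v.key == FOUNDER_KEY), None
    )
    if founder_variant is None:
        candidates = [v for v in variants if v.key.chrom == marker_map.markers[0][1]]
        if not candidates:
            return None
        founder_variant = candidates[0]

    phased = []
    carriers = {}
    for sid, genotype_data in genotypes.items():
        if sid not in pedigree:
            continue
        gt = founder_variant.genotype_of(sid)
        mother, father = pedigree.parents_of(sid)
        if gt == HOM_ALT and (mother or father):
            phased.append(phase_homozygote(genotype_data, marker_map, sample_id=sid))
        elif gt == HET and (mother or father):
            carrier_parent = None
            for parent, label in ((mother, "mother"), (father, "father")):
                if parent and founder_variant.genotype_of(parent.sample_id) in (HET, HOM_ALT):
                    carrier_parent = label
                    break
            if carrier_parent:
                phased.append(phase_trio(
                    genotype_data,
                    genotypes.get(mother.sample_id) if mother else None,
                    genotypes.get(father.sample_id) if father else None,
                    carrier_parent, marker_map, sample_id=sid,
                ))
        elif gt in (HET, HOM_ALT):
            carriers[sid] = genotype_data
    if not phased:
        return None
    consensus = consensus_founder_haplotype(phased)
    region = shared_region(consensus, carriers, marker_map)
    report["shared_region"] = {
        "left_marker": region.left_marker,
        "right_marker": region.right_marker,
        "left_flank": region.left_flank,
        "right_flank": region.right_flank,
        "span_bp": region.span_bp,
        "span_bp_max": region.span_bp_max,
        "n_phased_chromosomes": len(phased),
        "n_unphased_carriers": len(carriers),
        "shared_markers": list(region.shared_markers),
    }
    return region
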