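"""The variant filtration cascade producing the final call set.

Stages (default order, configurable):

1. index reduction — drop calls from non-index case-family members, so
   family-shared variants cannot masquerade as cohort-enriched;
2. allelic-fraction filter — per-sample calls with alt-read fraction
   strictly below 0.3 are artifacts and are blanked (set to missing);
3. panel restriction — keep variants in the disease gene panel;
4. population-frequency filter — keep variants at frequency <= 0.01 in
   the population reference (absent = rare = kept);
5. consequence filter — keep non-synonymous or splicing variants, or any
   variant flagged by a regulatory annotation source.

The allelic-fraction stage edits calls rather than deleting variants, so
one sample's artifact call cannot destroy a variant genuinely carried by
another cohort member; a variant left with no alt call is dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .cohort import (
    MISSING,
    AnnotatedVariant,
    GenePanel,
    Pedigree,
    SVInterval,
    VariantCall,
    coding_overlap,
    reduce_to_index,
)

__all__ = [
    "FilterTrace",
    "CascadeConfig",
    "FinalCallSet",
    "filter_allelic_fraction",
    "filter_panel",
    "filter_population_frequency",
    "filter_consequence",
    "filter_sv",
    "reduce_calls_to_index",
    "run_cascade",
]


@dataclass(frozen=True)
class FilterTrace:
    stage: str
    variants_in: int
    variants_out: int
    calls_removed: int = 0

    def __post_init__(self) -> None:
        if self.variants_out > self.variants_in:
            raise ValueError(f"stage {self.stage}: output exceeds input")
        if min(self.variants_in, self.variants_out, self.calls_removed) < 0:
            raise ValueError(f"stage {self.stage}: negative count")


@dataclass(frozen=True)
class CascadeConfig:
    """Thresholds and stage order for :func:`run_cascade`.

    ``min_vaf`` removes calls with allelic fraction strictly below it;
    ``max_popaf`` keeps variants at population frequency <= the bound.
    """

    min_vaf: float = 0.3
    max_popaf: float = 0.01
    stage_order: tuple[str, ...] = (
        "index_reduction",
        "allelic_fraction",
        "panel",
        "population_frequency",
        "consequence",
    )


@dataclass
class FinalCallSet:
    variants: list[AnnotatedVariant]
    svs: list[SVInterval] = field(default_factory=list)
    index_set: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.variants)


def filter_allelic_fraction(
    variants: list[AnnotatedVariant], threshold: float = 0.3
) -> tuple[list[AnnotatedVariant], FilterTrace]:
    """Blank per-sample calls whose allelic fraction is strictly below
    ``threshold``; drop variants with no surviving alt call.

    Calls without an allelic fraction are exempt (no depth data is not
    evidence of an artifact).  The rule is applied uniformly to het and
    homozygous calls; genuine hom-alt calls sit near fraction 1.0 and are
    unaffected in practice.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside (0, 1]")
    out: list[AnnotatedVariant] = []
    removed = 0
    for v in variants:
        calls: dict[str, VariantCall] = {}
        for sid, call in v.calls.items():
            if (
                call.is_alt
                and call.allelic_fraction is not None
                and call.allelic_fraction < threshold
            ):
                removed += 1
                calls[sid] = replace(call, genotype=MISSING)
            else:
                calls[sid] = call
        if any(c.is_alt for c in calls.values()):
            out.append(replace(v, calls=calls))
    return out, FilterTrace("allelic_fraction", len(variants), len(out), removed)


def filter_panel(
    variants: list[AnnotatedVariant], panel: GenePanel
) -> tuple[list[AnnotatedVariant], FilterTrace]:
    """Keep variants annotated to a panel gene (case-insensitive symbol
    match), with a positional fallback for unannotated variants."""
    if len(panel) == 0:
        raise ValueError("empty gene panel")
    out = [
        v for v in variants
        if v.gene in panel
        or (v.gene is None and panel.contains_position(v.key.chrom, v.key.pos))
    ]
    return out, FilterTrace("panel", len(variants), len(out))


def filter_population_frequency(
    variants: list[AnnotatedVariant], max_af: float = 0.01
) -> tuple[list[AnnotatedVariant], FilterTrace]:
    """Keep variants at population frequency <= ``max_af`` (inclusive) or
    absent from the population reference."""
    if not 0.0 <= max_af <= 1.0:
        raise ValueError(f"max_af {max_af} outside [0, 1]")
    out = [
        v for v in variants
        if v.population_af is None or v.population_af <= max_af
    ]
    return out, FilterTrace("population_frequency", len(variants), len(out))


def filter_consequence(
    variants: list[AnnotatedVariant],
) -> tuple[list[AnnotatedVariant], FilterTrace]:
    """Keep non-synonymous or splicing variants, or variants carrying any
    regulatory-database annotation."""
    out = [
        v for v in variants
        if v.consequence in ("nonsynonymous", "splicing") or v.regulatory_sources
    ]
    return out, FilterTrace("consequence", len(variants), len(out))


def filter_sv(
    svs: list[SVInterval], panel: GenePanel
) -> tuple[list[SVInterval], FilterTrace]:
    """Keep structural variants overlapping the coding structure of any
    panel gene."""
    out = [sv for sv in svs if coding_overlap(sv, panel)]
    return out, FilterTrace("sv_panel_overlap", len(svs), len(out))


def reduce_calls_to_index(
    variants: list[AnnotatedVariant], index_set: set[str]
) -> tuple[list[AnnotatedVariant], FilterTrace]:
    """Drop calls from samples outside the index set; drop variants with
    no remaining alt call (carried only by non-index relatives)."""
    out: list[AnnotatedVariant] = []
    removed = 0
    for v in variants:
        calls = {sid: c for sid, c in v.calls.items() if sid in index_set}
        removed += len(v.calls) - len(calls)
        if any(c.is_alt for c in calls.values()):
            out.append(replace(v, calls=calls))
    return out, FilterTrace("index_reduction", len(variants), len(out), removed)


_STAGES = {
    "index_reduction",
    "allelic_fraction",
    "panel",
    "population_frequency",
    "consequence",
}


def run_cascade(
    variants: list[AnnotatedVariant],
    svs: list[SVInterval],
    panel: GenePanel,
    pedigree: Pedigree,
    config: CascadeConfig | None = None,
) -> tuple[FinalCallSet, list[FilterTrace]]:
    """Apply the full filtration cascade and return the final call set
    plus a per-stage trace with reconciling counts."""
    config = config or CascadeConfig()
    unknown = set(config.stage_order) - _STAGES
    if unknown:
        raise ValueError(f"unknown cascade stages {sorted(unknown)}")
    index_set = reduce_to_index(pedigree)
    traces: list[FilterTrace] = []
    current = variants
    for stage in config.stage_order:
        if stage == "index_reduction":
            current, trace = reduce_calls_to_index(current, index_set)
        elif stage == "allelic_fraction":
            current, trace = filter_allelic_fraction(current, config.min_vaf)
        elif stage == "panel":
            current, trace = filter_panel(current, panel)
        elif stage == "population_frequency":
            current, trace = filter_population_frequency(current, config.max_popaf)
        else:
            current, trace = filter_consequence(current)
        traces.append(trace)
    svs_kept, sv_trace = filter_sv(svs, panel)
    traces.append(sv_trace)
    return FinalCallSet(current, svs_kept, index_set), traces
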