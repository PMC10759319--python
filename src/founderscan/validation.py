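"""Replicate studies validating the pipeline's operating characteristics.

These functions re-run the package end to end under the emulated study
conditions — planted founder recovery, family-wise error on null panels,
confidence-interval coverage, haplotype window recovery — and return
summary rates.  They back both the repository's acceptance checks and
anyone wanting to re-measure the method's behaviour under modified
conditions.

Every study derives its replicate seeds from one master seed through
``numpy.random.SeedSequence`` spawning, so results are reproducible.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats as sps

from .cohort import (
    HET,
    AnnotatedVariant,
    GenePanel,
    Individual,
    Pedigree,
    VariantCall,
    VariantKey,
)
from .filtering import run_cascade
from .haplotype import (
    consensus_founder_haplotype,
    phase_homozygote,
    phase_trio,
    shared_region,
)
from .simulate import (
    SimConfig,
    generate_cohort,
    generate_marker_data,
    make_index_pedigree,
    sample_enrichment_panel,
)
from .stats import CarrierCounts, EnrichmentConfig, HypergeomParams, hypergeometric_model, odds_ratio_model, predict_founders

__all__ = [
    "hypergeometric_enumeration_error",
    "binomial_limit_relative_difference",
    "or_ci_coverage",
    "founder_recovery_rate",
    "null_family_wise_error",
    "haplotype_window_study",
    "cascade_fixture_study",
]


def hypergeometric_enumeration_error(max_N: int = 30) -> float:
    """Max |model - exhaustive enumeration| over all urns with N <= max_N.

    The oracle sums C(K,k) C(N-K,n-k) / C(N,n) directly with exact
    integer combinatorics.
    """
    worst = 0.0
    for N in range(1, max_N + 1):
        for K in range(N + 1):
            for n in range(N + 1):
                xs = np.arange(0, n + 1)
                model = np.array([
                    hypergeometric_model(HypergeomParams(N, K, n, int(x)))
                    for x in xs
                ])
                total = math.comb(N, n)
                enum = np.array([
                    sum(
                        math.comb(K, k) * math.comb(N - K, n - k)
                        for k in range(x, min(n, K) + 1)
                    ) / total
                    for x in xs
                ])
                worst = max(worst, float(np.abs(model - enum).max()))
    return worst


def binomial_limit_relative_difference(
    N_pop: int = 10**8,
    n_draw: int = 225,
    q: float = 2 / 649,
    x_range: tuple[int, ...] = (1, 2, 3, 4, 5, 6),
) -> float:
    """Max relative difference between the hypergeometric tail and its
    binomial limit, over the x range where p crosses the testing
    threshold (the decision-relevant regime)."""
    worst = 0.0
    K = round(q * N_pop)
    for x in x_range:
        hyper = hypergeometric_model(HypergeomParams(N_pop, K, n_draw, x))
        bino = float(sps.binom.sf(x - 1, n_draw, K / N_pop))
        worst = max(worst, abs(hyper - bino) / bino)
    return worst


def or_ci_coverage(
    seed: int,
    reps: int = 2000,
    n_cases: int = 225,
    n_controls: int = 649,
    carrier_prob: float = 0.01,
) -> float:
    """Fraction of 95% odds-ratio CIs containing 1 on tables simulated
    at true OR = 1."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    covered = 0
    for _ in range(reps):
        x_case = int(rng.binomial(n_cases, carrier_prob))
        x_ctrl = int(rng.binomial(n_controls, carrier_prob))
        _, lo, hi, _, _ = odds_ratio_model(
            CarrierCounts(x_case, n_cases, x_ctrl, n_controls)
        )
        if lo <= 1.0 <= hi:
            covered += 1
    return covered / reps


def founder_recovery_rate(
    seed: int,
    reps: int = 200,
    n_null: int = 200,
    planted: tuple[float, float, float] = (0.05, 0.003, 0.15),
    config: EnrichmentConfig | None = None,
) -> float:
    """Fraction of replicates in which the planted founder variant is
    top-ranked with founder=true."""
    config = config or EnrichmentConfig()
    pedigree = make_index_pedigree()
    index_set = set(pedigree.individuals)
    hits = 0
    for child_seed in np.random.SeedSequence(seed).spawn(reps):
        rng = np.random.default_rng(child_seed)
        variants, planted_key = sample_enrichment_panel(
            pedigree, rng, n_null=n_null, planted=planted
        )
        results = predict_founders(variants, pedigree, config, index_set=index_set)
        if results and results[0].key == planted_key and results[0].founder:
            hits += 1
    return hits / reps


def null_family_wise_error(
    seed: int,
    reps: int = 500,
    n_variants: int = 200,
    config: EnrichmentConfig | None = None,
) -> float:
    """Fraction of fully null panels with at least one founder call."""
    config = config or EnrichmentConfig()
    pedigree = make_index_pedigree()
    index_set = set(pedigree.individuals)
    any_founder = 0
    for child_seed in np.random.SeedSequence(seed).spawn(reps):
        rng = np.random.default_rng(child_seed)
        variants, _ = sample_enrichment_panel(
            pedigree, rng, n_null=n_variants, planted=None
        )
        results = predict_founders(variants, pedigree, config, index_set=index_set)
        if any(r.founder for r in results):
            any_founder += 1
    return any_founder / reps


def _recover_window(config: SimConfig):
    """Run the haplotype pipeline on one generated cohort; returns the
    (left, right) recovered markers and the truth window, or None when
    the replicate has no phaseable carrier family."""
    result = generate_cohort(config)
    truth = result["truth"]
    if not truth.phasing_families:
        return None
    marker_map, genotypes = generate_marker_data(config, truth)
    phased = []
    for fam, child, kind in truth.phasing_families:
        if kind == "hom":
            phased.append(phase_homozygote(genotypes[child], marker_map, child))
        else:
            phased.append(phase_trio(
                genotypes[child], genotypes[f"{fam}/M"], genotypes[f"{fam}/F"],
                truth.transmitting_parent[fam], marker_map, child,
            ))
    consensus = consensus_founder_haplotype(phased)
    carriers = {sid: genotypes[sid] for sid in truth.unphased_carriers}
    region = shared_region(consensus, carriers, marker_map)
    names = list(marker_map.names)
    return (
        (region.left_marker, region.right_marker),
        truth.window_markers,
        names,
    )


def haplotype_window_study(
    seed: int,
    reps: int = 200,
    marker_missing_rate: float = 0.0,
) -> dict:
    """Window recovery over seeded replicates.

    Returns exact-recovery and containment rates.  With missing
    genotypes the region can only grow (missing data cannot contradict
    sharing), so containment is the meaningful guarantee there.
    """
    exact = contains = usable = 0
    # small variant panel: the haplotype stage does not use it
    base = dict(n_background_variants=0)
    for i, child_seed in enumerate(np.random.SeedSequence(seed).spawn(reps)):
        rep_seed = int(child_seed.generate_state(1)[0] % (2**31 - 1))
        config = SimConfig(seed=rep_seed,
                           marker_missing_rate=marker_missing_rate, **base)
        out = _recover_window(config)
        if out is None:
            continue
        usable += 1
        (left, right), (want_left, want_right), names = out
        if (left, right) == (want_left, want_right):
            exact += 1
        if (names.index(left) <= names.index(want_left)
                and names.index(right) >= names.index(want_right)):
            contains += 1
    return {
        "replicates": usable,
        "exact_rate": exact / max(usable, 1),
        "containment_rate": contains / max(usable, 1),
    }


def cascade_fixture_study() -> dict:
    """Hand-walked five-variant cascade: one variant survives each stage
    in turn, leaving a single designed survivor with reconciling traces."""
    def call(sid, af):
        return VariantCall(sid, HET, af)

    def variant(pos, gene, consequence, popaf, calls):
        return AnnotatedVariant(
            key=VariantKey("chr1" if gene != "OFFPANEL" else "chr2", pos, "G", "A"),
            gene=gene, consequence=consequence, population_af=popaf,
            calls={sid: call(sid, af) for sid, af in calls},
        )

    variants = [
        variant(1500, "PANG", "nonsynonymous", 0.001,
                [("A1", 0.5), ("A2", 0.45)]),            # survivor
        variant(1510, "PANG", "nonsynonymous", 0.05, [("B1", 0.5)]),   # common
        variant(1520, "PANG", "synonymous", 0.001, [("A1", 0.5)]),     # silent
        variant(1530, "PANG", "nonsynonymous", 0.001, [("A1", 0.1)]),  # artifact
        variant(99, "OFFPANEL", "nonsynonymous", 0.001, [("K1", 0.5)]),
    ]
    people = {
        "A1": Individual("A1", "FA", affected=True, cohort="case", is_index=True),
        "A2": Individual("A2", "FA", affected=True, cohort="case"),
        "B1": Individual("B1", "FB", affected=True, cohort="case", is_index=True),
        "K1": Individual("K1", "CK1", cohort="control"),
        "K2": Individual("K2", "CK2", cohort="control"),
    }
    panel = GenePanel({"PANG": [("chr1", 1000, 2000)]})
    callset, traces = run_cascade(variants, [], panel, Pedigree(people))
    chain = [t for t in traces if t.stage != "sv_panel_overlap"]
    reconciled = all(
        prev.variants_out == nxt.variants_in for prev, nxt in zip(chain, chain[1:])
    )
    monotone = all(t.variants_out <= t.variants_in for t in traces)
    return {
        "survivors": len(callset),
        "survivor_keys": [str(v.key) for v in callset.variants],
        "trace_reconciled": reconciled,
        "trace_monotone": monotone,
    }
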