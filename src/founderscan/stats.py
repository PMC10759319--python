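"""Carrier accounting and the two founder-prediction statistics.

A founder variant is a disease allele whose copies all descend from one
ancestral chromosome; in a case-control design it shows up as a variant
significantly overrepresented among index cases.  Two complementary
models are computed per variant in the final call set:

Odds-ratio model (PS4-style enrichment)
    2x2 carrier table (cases vs controls, carrier vs non-carrier), odds
    ratio with a 95% log-normal (Woolf) confidence interval, two-sided
    Wald p-value on ln(OR).  Zero cells get the Haldane-Anscombe +0.5
    correction applied to every cell, for both the estimate and the CI.
    A variant is flagged when OR exceeds a threshold (default 1.5) and
    the CI excludes 1.

Hypergeometric carrier model
    The control carrier frequency estimates the number of carriers K in
    a modeled general population of size N_pop; the probability of
    drawing at least the observed number of case carriers in a random
    sample of n_cases people is the upper hypergeometric tail
    P(X >= x_obs), X ~ Hypergeometric(N_pop, K, n_cases).  When no
    control carrier was observed the frequency estimate is floored at
    ``zero_control_floor`` observed carriers (default one) — a zero
    plug-in estimate would make every singleton case variant infinitely
    significant.

Both p-values are Bonferroni-corrected by the number of variants tested;
a variant is called a founder candidate when both flags hold.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import stats as sps

from .cohort import AnnotatedVariant, Pedigree, VariantKey

__all__ = [
    "CarrierCounts",
    "EnrichmentResult",
    "HypergeomParams",
    "EnrichmentConfig",
    "carrier_counts",
    "allele_frequency_percent",
    "odds_ratio_model",
    "hypergeometric_model",
    "bonferroni",
    "predict_founders",
]

@dataclass(frozen=True)
class CarrierCounts:
    """Carrier (individual) and allele counts per cohort for one variant.

    Carriers are samples with at least one alt allele; allele counts
    weigh het = 1, hom = 2.  Missing genotypes are excluded from the
    numerators but remain in the denominators, keeping the printed
    per-cohort denominators fixed.
    """

    x_cases: int
    n_cases: int
    x_controls: int
    n_controls: int
    a_cases: int | None = None  # None: all carriers heterozygous
    a_controls: int | None = None

    def __post_init__(self) -> None:
        if self.a_cases is None:
            object.__setattr__(self, "a_cases", self.x_cases)
        if self.a_controls is None:
            object.__setattr__(self, "a_controls", self.x_controls)
        for x, n, a, label in (
            (self.x_cases, self.n_cases, self.a_cases, "cases"),
            (self.x_controls, self.n_controls, self.a_controls, "controls"),
        ):
            if not 0 <= x <= n:
                raise ValueError(f"{label}: carrier count {x} outside [0, {n}]")
            if not x <= a <= 2 * n:
                raise ValueError(f"{label}: allele count {a} outside [{x}, {2*n}]")


@dataclass(frozen=True)
class HypergeomParams:
    """Urn parameters for the hypergeometric carrier model."""

    N_pop: int
    K: int
    n_draw: int
    x_obs: int

    def __post_init__(self) -> None:
        if self.N_pop <= 0:
            raise ValueError("N_pop must be positive")
        if not 0 <= self.K <= self.N_pop:
            raise ValueError(f"K={self.K} outside [0, {self.N_pop}]")
        if not 0 <= self.n_draw <= self.N_pop:
            raise ValueError(f"n_draw={self.n_draw} outside [0, {self.N_pop}]")
        if self.x_obs < 0:
            raise ValueError("x_obs must be non-negative")
        if self.x_obs > self.n_draw:
            raise ValueError(
                f"x_obs={self.x_obs} exceeds cohort size n_draw={self.n_draw}"
            )


@dataclass(frozen=True)
class EnrichmentResult:
    key: VariantKey
    counts: CarrierCounts
    gene: str | None
    or_value: float  # nan when undefined
    or_ci_low: float
    or_ci_high: float
    p_or_raw: float
    p_or_bonf: float
    p_hyper_raw: float
    p_hyper_bonf: float
    flag_or: bool
    flag_hyper: bool

    @property
    def founder(self) -> bool:
        return self.flag_or and self.flag_hyper


@dataclass(frozen=True)
class EnrichmentConfig:
    """Parameters of the two enrichment models.

    N_pop
        modeled general-population size for the hypergeometric urn
        (default ten million, the order of a mid-size European country).
    or_threshold
        minimum odds ratio for the PS4-style flag.  Default 1.5: the
        flag is an *enrichment* rule, so the bound must sit above 1;
        values below 1 are accepted for compatibility experiments.
    unit
        "carriers" counts individuals with >=1 alt allele (the carrier
        models both statistics describe); "alleles" uses allele counts
        with doubled denominators.
    zero_control_floor
        carriers assumed in the control sample when none was observed
        (continuity floor for the hypergeometric frequency estimate;
        0 restores the raw plug-in estimate with its degenerate zero
        p-values).
    model
        "hypergeometric" or its large-population "binomial" limit.
    """

    N_pop: int = 10_000_000
    alpha: float = 0.05
    or_threshold: float = 1.5
    unit: str = "carriers"
    zero_control_floor: float = 1.0
    model: str = "hypergeometric"

    def __post_init__(self) -> None:
        if self.unit not in ("carriers", "alleles"):
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.model not in ("hypergeometric", "binomial"):
            raise ValueError(f"unknown model {self.model!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha outside (0, 1)")


def carrier_counts(
    variant: AnnotatedVariant,
    pedigree: Pedigree,
    index_set: set[str],
) -> CarrierCounts:
    """Count carriers and alt alleles over index cases and all controls.

    Denominators are the index-case and control cohort sizes from the
    pedigree; missing genotypes stay in the denominator.  A call from a
    sample absent from the pedigree is an error.
    """
    for sid in variant.calls:
        if sid not in pedigree:
            raise KeyError(f"call sample {sid} not in pedigree")
    case_ids = {p.sample_id for p in pedigree.cases()} & index_set
    control_ids = {p.sample_id for p in pedigree.controls()}
    return _carrier_counts(variant, case_ids, control_ids)


def _carrier_counts(
    variant: AnnotatedVariant, case_ids: set[str], control_ids: set[str]
) -> CarrierCounts:
    x_cases = a_cases = x_controls = a_controls = 0
    for call in variant.calls.values():
        if not call.is_alt:
            continue
        if call.sample_id in case_ids:
            x_cases += 1
            a_cases += call.alt_alleles
        elif call.sample_id in control_ids:
            x_controls += 1
            a_controls += call.alt_alleles
    return CarrierCounts(
        x_cases, len(case_ids), x_controls, len(control_ids), a_cases, a_controls
    )


def allele_frequency_percent(
    allele_count: int, n_individuals: int, decimals: int = 2
) -> float:
    """Cohort allele frequency as a percentage of 2N chromosomes,
    rounded half-away-from-zero to ``decimals``."""
    if n_individuals <= 0:
        raise ValueError("n_individuals must be positive")
    if not 0 <= allele_count <= 2 * n_individuals:
        raise ValueError(
            f"allele count {allele_count} outside [0, {2 * n_individuals}]"
        )
    pct = Decimal(100 * allele_count) / Decimal(2 * n_individuals)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


def odds_ratio_model(
    counts: CarrierCounts,
    alpha: float = 0.05,
    or_threshold: float = 1.5,
    unit: str = "carriers",
) -> tuple[float, float, float, float, bool]:
    """Odds ratio with Woolf CI and Wald p for one 2x2 table.

    Returns ``(or_value, ci_low, ci_high, p, flag)``.  With any zero
    cell, 0.5 is added to every cell (Haldane-Anscombe) before both the
    estimate and the CI.  ``flag`` is True when OR > or_threshold and
    the CI excludes 1.  A fully empty table yields nan and flag False.
    """
    if unit == "carriers":
        a, c = counts.x_cases, counts.x_controls
        b, d = counts.n_cases - a, counts.n_controls - c
    else:
        a, c = counts.a_cases, counts.a_controls
        b, d = 2 * counts.n_cases - a, 2 * counts.n_controls - c
    if a + b == 0 and c + d == 0:
        return float("nan"), float("nan"), float("nan"), 1.0, False
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = float(np.log((a * d) / (b * c)))
    se = float(np.sqrt(1 / a + 1 / b + 1 / c + 1 / d))
    z = sps.norm.ppf(1 - alpha / 2)
    ci_low = float(np.exp(log_or - z * se))
    ci_high = float(np.exp(log_or + z * se))
    p = float(2 * sps.norm.sf(abs(log_or) / se))
    or_value = float(np.exp(log_or))
    flag = bool(or_value > or_threshold and (ci_low > 1.0 or ci_high < 1.0))
    return or_value, ci_low, ci_high, p, flag


def hypergeometric_model(params: HypergeomParams) -> float:
    """Upper tail P(X >= x_obs) for X ~ Hypergeometric(N_pop, K, n_draw).

    Computed through scipy's log-space survival function; x_obs = 0
    yields 1 by convention, and K = 0 yields 0 for any positive x_obs.
    """
    if params.x_obs == 0:
        return 1.0
    return float(
        sps.hypergeom.sf(params.x_obs - 1, params.N_pop, params.K, params.n_draw)
    )


def _binomial_tail(x_obs: int, n_draw: int, q: float) -> float:
    if x_obs == 0:
        return 1.0
    return float(sps.binom.sf(x_obs - 1, n_draw, q))


def bonferroni(p: float, m: int) -> float:
    """Family-wise corrected p-value min(1, m*p)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return min(1.0, m * p)


def _hyper_p_for(
    counts: CarrierCounts, config: EnrichmentConfig
) -> tuple[float, HypergeomParams | None]:
    if config.unit == "carriers":
        x_obs, n_draw = counts.x_cases, counts.n_cases
        x_ctrl, n_ctrl = counts.x_controls, counts.n_controls
    else:
        x_obs, n_draw = counts.a_cases, 2 * counts.n_cases
        x_ctrl, n_ctrl = counts.a_controls, 2 * counts.n_controls
    if n_ctrl == 0 or n_draw == 0:
        return 1.0, None
    q = max(float(x_ctrl), config.zero_control_floor) / n_ctrl
    q = min(q, 1.0)
    if config.model == "binomial":
        return _binomial_tail(x_obs, n_draw, q), None
    K = int(round(q * config.N_pop))
    if x_ctrl > 0 or config.zero_control_floor > 0:
        K = max(1, K)
    params = HypergeomParams(config.N_pop, K, n_draw, x_obs)
    return hypergeometric_model(params), params


def predict_founders(
    final_call_set: list[AnnotatedVariant],
    pedigree: Pedigree,
    config: EnrichmentConfig | None = None,
    index_set: set[str] | None = None,
) -> list[EnrichmentResult]:
    """Run both enrichment models on every variant of the final call set.

    The Bonferroni multiplier is the number of variants actually tested.
    Results are ranked by corrected hypergeometric p ascending, with ties
    broken by corrected OR p, then genomic key.  A variant is a founder
    candidate when the OR flag holds and its corrected hypergeometric p
    is below alpha.
    """
    config = config or EnrichmentConfig()
    if not final_call_set:
        return []
    from .cohort import reduce_to_index

    if index_set is None:
        index_set = reduce_to_index(pedigree)
    m = len(final_call_set)
    case_ids = {p.sample_id for p in pedigree.cases()} & index_set
    control_ids = {p.sample_id for p in pedigree.controls()}
    results: list[EnrichmentResult] = []
    for variant in final_call_set:
        counts = _carrier_counts(variant, case_ids, control_ids)
        or_value, ci_low, ci_high, p_or, flag_or = odds_ratio_model(
            counts, alpha=config.alpha, or_threshold=config.or_threshold,
            unit=config.unit,
        )
        p_hyper, _ = _hyper_p_for(counts, config)
        p_or_bonf = bonferroni(p_or, m)
        p_hyper_bonf = bonferroni(p_hyper, m)
        flag_hyper = p_hyper_bonf < config.alpha
        results.append(EnrichmentResult(
            key=variant.key,
            counts=counts,
            gene=variant.gene,
            or_value=or_value,
            or_ci_low=ci_low,
            or_ci_high=ci_high,
            p_or_raw=p_or,
            p_or_bonf=p_or_bonf,
            p_hyper_raw=p_hyper,
            p_hyper_bonf=p_hyper_bonf,
            flag_or=flag_or,
            flag_hyper=flag_hyper,
        ))
    results.sort(key=lambda r: (r.p_hyper_bonf, r.p_or_bonf, r.key))
    return results
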