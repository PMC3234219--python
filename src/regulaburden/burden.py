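"""Collapsing (burden) analyses for rare regulatory variants.

Implements the exact 2x2 test and four collapsing strategies:

* undirected collapsing of all rare variants (CAST),
* direction-stratified collapsing informed by reporter-assay calls,
* the exclusivity-filtered variant of the directional test (variants with
  carriers at both phenotypic extremes are dropped), and
* two comparator tests operating on individual-level data: a
  frequency-weighted rank-sum test and a variance-component (C-alpha
  style) test, both with permutation nulls.

The Fisher exact test is computed with exact integer combinatorics; the
two-sided p-value uses the minimum-likelihood definition (sum point
probabilities no larger than the observed one, with a 1e-7 relative tie
tolerance).
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass, field
from math import comb

import numpy as np
from scipy import stats

from .assay import FunctionalCall
from .catalog import CarrierTable, CohortSpec, VariantRecord, count_distinct_carriers
from .errors import ConfigurationError, ValidationError

# Relative tie tolerance for the minimum-likelihood two-sided rule,
# applied as an exact integer comparison: include k whenever
# P(k) <= P(a) * TIE_NUM / TIE_DEN.
TIE_DEN = 10**7
TIE_NUM = TIE_DEN + 1


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 carrier/non-carrier table.

    a = carriers in cohort 1, b = non-carriers in cohort 1,
    c = carriers in cohort 2, d = non-carriers in cohort 2.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("contingency table counts must be non-negative")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def K(self) -> int:
        """Total carriers."""
        return self.a + self.c

    @property
    def n1(self) -> int:
        """Cohort-1 size."""
        return self.a + self.b

    @property
    def n2(self) -> int:
        return self.c + self.d


@dataclass
class BurdenResult:
    test_name: str
    direction: str  # {"any", "decrease", "increase"}
    exclusive: bool
    table: ContingencyTable
    p_value: float
    sidedness: str  # {"one", "two"}
    variants_used: set[str] = field(default_factory=set)
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"p-value {self.p_value} outside (0, 1]")


def fisher_pvalues_for_margins(n1: int, n2: int, K: int):
    """All Fisher p-values for tables with fixed margins (n1, n2, K).

    Returns ``(ks, p_greater, p_less, p_two)`` where ``ks`` is the support
    of a (carriers in cohort 1) and the arrays give, for each attainable a,
    the one-sided upper/lower tail p-values and the minimum-likelihood
    two-sided p-value.  Computed with exact integer combinatorics; the only
    rounding is the final division to float.
    """
    kmin = max(0, K - n2)
    kmax = min(K, n1)
    ks = list(range(kmin, kmax + 1))
    nums = [comb(n1, k) * comb(n2, K - k) for k in ks]
    total = comb(n1 + n2, K)

    # one-sided tails by cumulative sums of exact integers
    upper = [0] * len(ks)
    acc = 0
    for i in range(len(ks) - 1, -1, -1):
        acc += nums[i]
        upper[i] = acc
    lower = [0] * len(ks)
    acc = 0
    for i in range(len(ks)):
        acc += nums[i]
        lower[i] = acc

    # two-sided: sum of point masses <= observed mass (with tie tolerance)
    order = sorted(range(len(ks)), key=nums.__getitem__)
    sorted_nums = [nums[i] for i in order]
    prefix = [0] * (len(ks) + 1)
    for i, v in enumerate(sorted_nums):
        prefix[i + 1] = prefix[i] + v
    p_two = [0.0] * len(ks)
    for i, num_a in enumerate(nums):
        threshold = (num_a * TIE_NUM) // TIE_DEN
        idx = bisect_right(sorted_nums, threshold)
        p_two[i] = min(1.0, prefix[idx] / total)

    p_greater = [min(1.0, u / total) for u in upper]
    p_less = [min(1.0, l / total) for l in lower]
    return ks, p_greater, p_less, p_two


def fisher_exact(
    table: ContingencyTable, sidedness: str = "two", alternative: str = "greater"
) -> float:
    """Exact p-value for a 2x2 table.

    ``sidedness`` is "one" or "two"; for one-sided tests ``alternative``
    chooses the tail ("greater" = carrier enrichment in cohort 1).
    A table with no carriers (or no non-carriers) is degenerate: p = 1
    with a warning.
    """
    if sidedness not in ("one", "two"):
        raise ValidationError(f"sidedness must be 'one' or 'two', got {sidedness!r}")
    if table.K == 0 or table.K == table.N:
        warnings.warn("degenerate table (no carriers or all carriers): p = 1", stacklevel=2)
        return 1.0
    ks, p_greater, p_less, p_two = fisher_pvalues_for_margins(table.n1, table.n2, table.K)
    i = ks.index(table.a)
    if sidedness == "two":
        return p_two[i]
    if alternative == "greater":
        return p_greater[i]
    if alternative == "less":
        return p_less[i]
    raise ValidationError(f"alternative must be 'greater' or 'less', got {alternative!r}")


def _two_cohorts(cohorts: list[CohortSpec]) -> tuple[CohortSpec, CohortSpec]:
    if len(cohorts) != 2:
        raise ConfigurationError(f"burden tests need exactly 2 cohorts, got {len(cohorts)}")
    high = [c for c in cohorts if c.extreme == "high"]
    low = [c for c in cohorts if c.extreme == "low"]
    if len(high) == 1 and len(low) == 1:
        return high[0], low[0]
    return cohorts[0], cohorts[1]


def _collapse(
    test_name: str,
    direction: str,
    exclusive: bool,
    variant_subset: set[str],
    carriers: CarrierTable,
    cohorts: list[CohortSpec],
    sidedness: str,
    alternative: str,
) -> BurdenResult:
    c1, c2 = _two_cohorts(cohorts)
    present = variant_subset & carriers.variant_ids
    a = count_distinct_carriers(carriers, present, c1)
    c = count_distinct_carriers(carriers, present, c2)
    table = ContingencyTable(a, c1.n_individuals - a, c, c2.n_individuals - c)
    degenerate = table.K == 0
    if degenerate:
        p = 1.0
    else:
        p = fisher_exact(table, sidedness=sidedness, alternative=alternative)
    return BurdenResult(
        test_name=test_name,
        direction=direction,
        exclusive=exclusive,
        table=table,
        p_value=p,
        sidedness=sidedness,
        variants_used=set(variant_subset),
        degenerate=degenerate,
    )


def cast(
    catalog: list[VariantRecord],
    carriers: CarrierTable,
    cohorts: list[CohortSpec],
    sidedness: str = "two",
    alternative: str = "greater",
) -> BurdenResult:
    """Undirected collapsing test: all rare variants regardless of function.

    Distinct carriers (de-duplicated across variants) are compared between
    the two cohorts with the Fisher exact test.
    """
    rare = {rec.variant_id for rec in catalog if rec.freq_class == "rare"}
    result = _collapse("cast", "any", False, rare, carriers, cohorts, sidedness, alternative)
    if result.degenerate:
        warnings.warn("no rare-variant carriers in either cohort; degenerate CAST", stacklevel=2)
    return result


def directional_cast(
    catalog: list[VariantRecord],
    carriers: CarrierTable,
    calls: dict[str, FunctionalCall],
    direction: str,
    exclusive: bool = False,
    cohorts: list[CohortSpec] | None = None,
    sidedness: str = "two",
) -> BurdenResult:
    """Function-informed collapsing test.

    Keeps rare variants whose reporter-assay call matches ``direction``
    (null-direction variants are discounted).  With ``exclusive=True``,
    variants with carriers in both cohorts are additionally dropped.  An
    individual carrying variants of both directions contributes to both
    directional tests.  One-sided tests use the tail implied by the
    direction: 'decrease' looks for enrichment in the high cohort,
    'increase' in the low cohort.
    """
    if direction not in ("decrease", "increase"):
        raise ConfigurationError(f"direction must be 'decrease' or 'increase', got {direction!r}")
    if cohorts is None:
        raise ConfigurationError("cohorts are required")
    rare = [rec for rec in catalog if rec.freq_class == "rare"]
    missing = [rec.variant_id for rec in rare if rec.variant_id not in calls]
    if missing:
        raise ConfigurationError(f"missing functional calls for rare variants: {sorted(missing)}")

    selected = {rec.variant_id for rec in rare if calls[rec.variant_id].direction == direction}
    if exclusive:
        shared = {rec.variant_id for rec in rare if len(rec.cohorts_with_carriers()) > 1}
        selected -= shared

    alternative = "greater" if direction == "decrease" else "less"
    return _collapse(
        f"directional_cast[{direction}]",
        direction,
        exclusive,
        selected,
        carriers,
        cohorts,
        sidedness,
        alternative,
    )


# ---------------------------------------------------------------------------
# Comparator tests on individual-level genotypes
# ---------------------------------------------------------------------------


@dataclass
class PermutationTestResult:
    test_name: str
    statistic: float
    p_value: float
    n_permutations: int


def weighted_sum_test(
    genotypes: np.ndarray,
    is_case: np.ndarray,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> PermutationTestResult:
    """Frequency-weighted rank-sum collapsing test with a permutation null.

    ``genotypes`` is an (n_individuals, n_variants) minor-allele count
    matrix, ``is_case`` a boolean cohort-1 indicator.  Each variant is
    down-weighted by ``w_v = sqrt(n_ctrl * q_v * (1 - q_v))`` where ``q_v``
    is its smoothed control-group frequency; individuals are scored by
    their weighted mutation counts, and the statistic is the rank-sum of
    case scores.  Weights are recomputed for every permuted labelling.
    The permutation p-value is (b + 1) / (B + 1), upper tail.
    """
    if seed is None:
        raise ConfigurationError("weighted_sum_test requires an explicit seed")
    G = np.asarray(genotypes, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    n, V = G.shape
    if V == 0 or G.sum() == 0:
        return PermutationTestResult("weighted_sum", 0.0, 1.0, 0)

    def statistic(labels: np.ndarray) -> float:
        ctrl = ~labels
        n_ctrl = int(ctrl.sum())
        m = G[ctrl].sum(axis=0)  # minor alleles among controls
        q = (m + 1.0) / (2.0 * n_ctrl + 2.0)
        w = np.sqrt(n_ctrl * q * (1.0 - q))
        scores = G @ (1.0 / w)
        ranks = stats.rankdata(scores)
        return float(ranks[labels].sum())

    observed = statistic(is_case)
    rng = np.random.default_rng(seed)
    b = 0
    labels = is_case.copy()
    for _ in range(n_permutations):
        rng.shuffle(labels)
        if statistic(labels) >= observed:
            b += 1
    p = (b + 1) / (n_permutations + 1)
    return PermutationTestResult("weighted_sum", observed, p, n_permutations)


def c_alpha_statistic(y: np.ndarray, n: np.ndarray, p0: float) -> float:
    """Variance-deviation statistic over per-variant carrier splits.

    T = sum_v [(y_v - n_v p0)^2 - n_v p0 (1 - p0)], where y_v is the
    number of the variant's n_v carriers falling in cohort 1 and p0 the
    cohort-1 sampling fraction.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    return float((((y - n * p0) ** 2) - n * p0 * (1.0 - p0)).sum())


def c_alpha_test(
    incidence: np.ndarray,
    is_case: np.ndarray,
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> PermutationTestResult:
    """C-alpha style test with a permutation null.

    ``incidence`` is an (n_individuals, n_variants) boolean carrier matrix.
    The asymptotic null is avoided deliberately: with singleton variants it
    is unreliable, so significance is assessed by permuting cohort labels.
    Upper-tail p = (b + 1) / (B + 1).
    """
    if seed is None:
        raise ConfigurationError("c_alpha_test requires an explicit seed")
    X = np.asarray(incidence, dtype=float)
    is_case = np.asarray(is_case, dtype=bool)
    n_ind, V = X.shape
    n_v = X.sum(axis=0)
    keep = n_v > 0
    if V == 0 or not keep.any():
        return PermutationTestResult("c_alpha", 0.0, 1.0, 0)
    X = X[:, keep]
    n_v = n_v[keep]
    p0 = is_case.mean()

    observed = c_alpha_statistic(X[is_case].sum(axis=0), n_v, p0)
    rng = np.random.default_rng(seed)
    # vectorized permutations in blocks: labels as 0/1 rows
    B = n_permutations
    b = 0
    block = 2000
    base = is_case.astype(float)
    done = 0
    while done < B:
        m = min(block, B - done)
        perm = np.empty((m, n_ind))
        for i in range(m):
            perm[i] = rng.permutation(base)
        y = perm @ X  # (m, V) carriers in permuted cohort 1
        T = (((y - n_v * p0) ** 2) - n_v * p0 * (1.0 - p0)).sum(axis=1)
        b += int((T >= observed - 1e-12).sum())
        done += m
    p = (b + 1) / (B + 1)
    return PermutationTestResult("c_alpha", observed, p, B)
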