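"""Synthetic-data generator for extreme-phenotype regulatory-variant studies.

Generative model
----------------
A population of ``population_n`` individuals carries ``n_rare_variants``
biallelic variants, each with a minor-allele frequency drawn from
``carrier_freq_range`` and a true direction of effect on promoter
activity (decrease / null / increase, mixed per ``direction_mix``).
Expression acts multiplicatively: a variant with relative activity
``a_v`` shifts an individual's log plasma-enzyme level by
``el_coupling * log(a_v)`` per minor-allele copy.  The plasma enzyme (EL)
is lognormal; the trait of interest (HDL) decreases linearly in EL with
Gaussian residual noise, so expression-lowering variants raise the trait.
Cohorts are ascertained from the trait tails at the configured
percentiles.  Reporter plates, a two-locus genotype table at a target
r^2, and all the pipeline's TSV inputs can be emitted from one study.

All randomness flows from ``SimConfig.seed`` through a single Generator,
so identical configs produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assay as assay_mod
from . import burden as burden_mod
from .assay import ReporterWell
from .catalog import CarrierTable, CohortSpec
from .errors import ConfigurationError, SamplingError, ValidationError
from .ld import TwoLocusGenotypes

DIRECTION_CODES = ("decrease", "null", "increase")


@dataclass
class SimConfig:
    """Full parameterization of the synthetic study.

    Defaults mirror the dimensions of the motivating study: population
    10,000; tail cohorts of 195 (high) and 193 (low) at the 95th/25th
    percentiles; 17 rare variants; 6 reporter replicates per construct.
    """

    seed: int = 0
    population_n: int = 10_000
    n_rare_variants: int = 17
    carrier_freq_range: tuple[float, float] = (0.001, 0.004)
    direction_mix: tuple[float, float, float] = (0.25, 0.5, 0.25)  # decrease, null, increase
    effect_decrease: float = 0.5
    effect_increase: float = 1.5
    el_coupling: float = 1.0
    hdl_coupling: float = 10.0
    noise_sd: float = 5.0
    el_noise_sd: float = 0.3
    hdl_mean: float = 50.0
    hi_percentile: float = 95.0
    lo_percentile: float = 25.0
    n_high: int = 195
    n_low: int = 193
    assay_replicates: int = 6
    assay_cv: float = 0.15
    ld_maf1: float = 0.278
    ld_maf2: float = 0.279
    ld_target_r2: float = 0.8
    ld_n: int = 761

    def __post_init__(self) -> None:
        if abs(sum(self.direction_mix) - 1.0) > 1e-9:
            raise ValidationError("direction_mix proportions must sum to 1")
        lo, hi = self.carrier_freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValidationError("carrier_freq_range must lie in (0, 1)")
        if not (self.lo_percentile < self.hi_percentile):
            raise ValidationError("lo_percentile must be below hi_percentile")
        if not (0.0 < self.ld_maf1 < 1.0 and 0.0 < self.ld_maf2 < 1.0):
            raise ValidationError("LD minor allele frequencies must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("carrier_freq_range", "direction_mix"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["carrier_freq_range"] = list(data["carrier_freq_range"])
        data["direction_mix"] = list(data["direction_mix"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class SyntheticStudy:
    config: SimConfig
    cohorts: list[CohortSpec]
    variant_ids: list[str]
    directions: list[str]
    activities: np.ndarray
    population_genotypes: np.ndarray  # (population_n, V)
    expression: np.ndarray
    el: np.ndarray
    hdl: np.ndarray
    high_idx: np.ndarray
    low_idx: np.ndarray
    wells: list[ReporterWell]
    two_locus: TwoLocusGenotypes
    ld_genotypes: pd.DataFrame = field(repr=False, default=None)

    @property
    def cohort_individuals(self) -> pd.DataFrame:
        rows = []
        for rank, i in enumerate(self.high_idx):
            rows.append({"individual_id": f"S{i:06d}", "cohort": "HIGH", "pop_index": int(i)})
        for rank, i in enumerate(self.low_idx):
            rows.append({"individual_id": f"S{i:06d}", "cohort": "LOW", "pop_index": int(i)})
        return pd.DataFrame(rows)

    def cohort_genotype_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(genotypes, is_high) for the sampled cohort members."""
        idx = np.concatenate([self.high_idx, self.low_idx])
        is_high = np.zeros(idx.size, dtype=bool)
        is_high[: self.high_idx.size] = True
        return self.population_genotypes[idx], is_high

    # ---- TSV emission -----------------------------------------------------

    def variants_frame(self) -> pd.DataFrame:
        G, is_high = self.cohort_genotype_matrix()
        rows = []
        for v, vid in enumerate(self.variant_ids):
            for cohort, mask in (("HIGH", is_high), ("LOW", ~is_high)):
                g = G[mask, v]
                rows.append(
                    {
                        "variant_id": vid,
                        "position": -1700 + v * 100,
                        "ref": "A",
                        "alt": "G",
                        "cohort": cohort,
                        "n_het": int((g == 1).sum()),
                        "n_hom_minor": int((g == 2).sum()),
                    }
                )
        return pd.DataFrame(rows)

    def carriers_frame(self) -> pd.DataFrame:
        members = self.cohort_individuals
        idx = members["pop_index"].to_numpy()
        rows = []
        for _, r in members.iterrows():
            g = self.population_genotypes[r["pop_index"]]
            for v in np.nonzero(g > 0)[0]:
                rows.append(
                    {
                        "individual_id": r["individual_id"],
                        "cohort": r["cohort"],
                        "variant_id": self.variant_ids[v],
                    }
                )
        return pd.DataFrame(rows, columns=["individual_id", "cohort", "variant_id"])

    def phenotypes_frame(self) -> pd.DataFrame:
        members = self.cohort_individuals
        idx = members["pop_index"].to_numpy()
        return pd.DataFrame(
            {
                "individual_id": members["individual_id"],
                "cohort": members["cohort"],
                "hdl": np.round(self.hdl[idx], 6),
                "el": np.round(self.el[idx], 6),
            }
        )

    def cohorts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": "HIGH",
                    "n_individuals": self.config.n_high,
                    "extreme": "high",
                    "percentile_bound": self.config.hi_percentile,
                    "trait_floor": "",
                },
                {
                    "name": "LOW",
                    "n_individuals": self.config.n_low,
                    "extreme": "low",
                    "percentile_bound": self.config.lo_percentile,
                    "trait_floor": "",
                },
            ]
        )

    def write(self, outdir) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        paths["variants"] = outdir / "variants.tsv"
        self.variants_frame().to_csv(paths["variants"], sep="\t", index=False)
        paths["carriers"] = outdir / "carriers.tsv"
        self.carriers_frame().to_csv(paths["carriers"], sep="\t", index=False)
        paths["cohorts"] = outdir / "cohorts.tsv"
        self.cohorts_frame().to_csv(paths["cohorts"], sep="\t", index=False)
        paths["phenotypes"] = outdir / "phenotypes.tsv"
        self.phenotypes_frame().to_csv(paths["phenotypes"], sep="\t", index=False, float_format="%.6f")
        paths["assay"] = outdir / "assay.tsv"
        assay_mod.save_wells(self.wells, paths["assay"])
        paths["genotypes"] = outdir / "genotypes.tsv"
        self.ld_genotypes.to_csv(paths["genotypes"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# Core generative steps (shared between simulate_study and power_study)
# ---------------------------------------------------------------------------


def _draw_variants(config: SimConfig, rng: np.random.Generator):
    V = config.n_rare_variants
    lo, hi = config.carrier_freq_range
    freqs = rng.uniform(lo, hi, size=V)
    directions = rng.choice(DIRECTION_CODES, size=V, p=list(config.direction_mix))
    activity = np.where(
        directions == "decrease",
        config.effect_decrease,
        np.where(directions == "increase", config.effect_increase, 1.0),
    )
    return freqs, directions, activity


def _simulate_population(config: SimConfig, rng: np.random.Generator):
    freqs, directions, activity = _draw_variants(config, rng)
    N = config.population_n
    G = rng.binomial(2, freqs, size=(N, freqs.size))
    log_expr = G @ np.log(activity)
    log_el = config.el_coupling * log_expr + rng.normal(0.0, config.el_noise_sd, size=N)
    el = np.exp(log_el)
    hdl = config.hdl_mean - config.hdl_coupling * el + rng.normal(0.0, config.noise_sd, size=N)
    expression = np.exp(log_expr)
    return G, directions, activity, expression, el, hdl


def _sample_cohorts(hdl: np.ndarray, config: SimConfig, rng: np.random.Generator):
    hi_cut = np.percentile(hdl, config.hi_percentile)
    lo_cut = np.percentile(hdl, config.lo_percentile)
    hi_pool = np.nonzero(hdl >= hi_cut)[0]
    lo_pool = np.nonzero(hdl <= lo_cut)[0]
    if hi_pool.size < config.n_high:
        raise SamplingError(
            f"high tail has {hi_pool.size} individuals < requested cohort {config.n_high}"
        )
    if lo_pool.size < config.n_low:
        raise SamplingError(
            f"low tail has {lo_pool.size} individuals < requested cohort {config.n_low}"
        )
    high_idx = np.sort(rng.choice(hi_pool, size=config.n_high, replace=False))
    low_idx = np.sort(rng.choice(lo_pool, size=config.n_low, replace=False))
    return high_idx, low_idx


def generate_assay_plates(
    variant_ids: list[str],
    activities: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    n_replicates: int | None = None,
) -> list[ReporterWell]:
    """One plate per variant construct: WT wells plus variant wells with
    multiplicative lognormal measurement noise at the configured CV."""
    reps = config.assay_replicates if n_replicates is None else n_replicates
    sigma = config.assay_cv
    wells: list[ReporterWell] = []
    for vid, act in zip(variant_ids, activities):
        plate = f"plate_{vid}"
        renilla = 1000.0 * np.exp(rng.normal(0.0, 0.05, size=2 * reps))
        ratios_wt = np.exp(rng.normal(0.0, sigma, size=reps))
        ratios_v = act * np.exp(rng.normal(0.0, sigma, size=reps))
        for k in range(reps):
            wells.append(ReporterWell(plate, "WT", float(ratios_wt[k] * renilla[k]), float(renilla[k])))
        for k in range(reps):
            wells.append(
                ReporterWell(plate, vid, float(ratios_v[k] * renilla[reps + k]), float(renilla[reps + k]))
            )
    return wells


def max_attainable_r2(maf1: float, maf2: float) -> float:
    """Feasibility bound for positive-D coupling of the two minor alleles."""
    d_max = min(maf1 * (1 - maf2), (1 - maf1) * maf2)
    return d_max**2 / (maf1 * (1 - maf1) * maf2 * (1 - maf2))


def simulate_two_locus(
    maf1: float, maf2: float, target_r2: float, n: int, seed: int
) -> TwoLocusGenotypes:
    """Draw n diploid genotypes from the 4-haplotype distribution with the
    given minor allele frequencies and the (positive) D implied by
    ``target_r2``.  Haplotypes are paired at random (HWE)."""
    if not (0.0 <= target_r2 <= 1.0):
        raise ConfigurationError(f"target r^2 {target_r2} outside [0, 1]")
    bound = max_attainable_r2(maf1, maf2)
    if target_r2 > bound + 1e-9:
        raise ConfigurationError(
            f"target r^2 {target_r2:.4g} infeasible for MAFs ({maf1}, {maf2}); "
            f"maximum attainable r^2 is {bound:.4g}"
        )
    D = np.sqrt(target_r2 * maf1 * (1 - maf1) * maf2 * (1 - maf2))
    p = np.array(
        [
            maf1 * maf2 + D,  # AB
            maf1 * (1 - maf2) - D,  # Ab
            (1 - maf1) * maf2 - D,  # aB
            (1 - maf1) * (1 - maf2) + D,  # ab
        ]
    )
    p = np.clip(p, 0.0, None)
    p = p / p.sum()
    rng = np.random.default_rng(seed)
    haps = rng.choice(4, size=2 * n, p=p)
    # haplotype k carries the A minor allele iff k in {0,1}; B iff k in {0,2}
    a_copies = np.isin(haps, (0, 1)).astype(int)
    b_copies = np.isin(haps, (0, 2)).astype(int)
    ga = a_copies[:n] + a_copies[n:]
    gb = b_copies[:n] + b_copies[n:]
    counts = np.zeros((3, 3), dtype=int)
    np.add.at(counts, (ga, gb), 1)
    return TwoLocusGenotypes(counts)


def simulate_study(config: SimConfig) -> SyntheticStudy:
    """Generate a full synthetic study (population, cohorts, assay plates,
    two-locus genotypes).  Deterministic given the config seed."""
    rng = np.random.default_rng(config.seed)
    G, directions, activity, expression, el, hdl = _simulate_population(config, rng)
    high_idx, low_idx = _sample_cohorts(hdl, config, rng)
    variant_ids = [f"v{v + 1:03d}" for v in range(config.n_rare_variants)]
    wells = generate_assay_plates(variant_ids, activity, config, rng)
    ld_seed = int(rng.integers(0, 2**31 - 1))
    two_locus = simulate_two_locus(
        config.ld_maf1, config.ld_maf2, config.ld_target_r2, config.ld_n, ld_seed
    )
    # long-format genotype frame for the LD pair
    rows = []
    counts = two_locus.counts
    k = 0
    for i in range(3):
        for j in range(3):
            for _ in range(counts[i, j]):
                rows.append({"individual_id": f"L{k:05d}", "variant_id": "locusA", "genotype": i})
                rows.append({"individual_id": f"L{k:05d}", "variant_id": "locusB", "genotype": j})
                k += 1
    ld_genotypes = pd.DataFrame(rows, columns=["individual_id", "variant_id", "genotype"])
    cohorts = [
        CohortSpec("HIGH", config.n_high, "high", config.hi_percentile),
        CohortSpec("LOW", config.n_low, "low", config.lo_percentile),
    ]
    return SyntheticStudy(
        config=config,
        cohorts=cohorts,
        variant_ids=variant_ids,
        directions=list(directions),
        activities=activity,
        population_genotypes=G,
        expression=expression,
        el=el,
        hdl=hdl,
        high_idx=high_idx,
        low_idx=low_idx,
        wells=wells,
        two_locus=two_locus,
        ld_genotypes=ld_genotypes,
    )


# ---------------------------------------------------------------------------
# Power / type-I-error engine
# ---------------------------------------------------------------------------

KNOWN_TESTS = ("cast", "directional_decrease", "directional_increase", "weighted_sum", "c_alpha")


def _run_test_fast(
    name: str,
    G: np.ndarray,
    is_high: np.ndarray,
    directions: np.ndarray,
    n1: int,
    n2: int,
    seed: int,
    n_permutations: int,
) -> float:
    """p-value of one registered burden test on cohort-level arrays."""
    carriers = G > 0
    if name == "cast":
        cols = np.ones(G.shape[1], dtype=bool)
    elif name == "directional_decrease":
        cols = directions == "decrease"
    elif name == "directional_increase":
        cols = directions == "increase"
    elif name == "weighted_sum":
        return burden_mod.weighted_sum_test(G, is_high, n_permutations, seed).p_value
    elif name == "c_alpha":
        return burden_mod.c_alpha_test(carriers, is_high, n_permutations, seed).p_value
    else:
        raise ConfigurationError(f"unknown test {name!r}; known: {KNOWN_TESTS}")
    any_carrier = carriers[:, cols].any(axis=1)
    a = int((any_carrier & is_high).sum())
    c = int((any_carrier & ~is_high).sum())
    table = burden_mod.ContingencyTable(a, n1 - a, c, n2 - c)
    if table.K == 0:
        return 1.0
    return burden_mod.fisher_exact(table, sidedness="two")


def power_study(
    config: SimConfig,
    tests: list[str],
    n_sims: int,
    alpha: float = 0.05,
    seed: int = 0,
    n_permutations: int = 200,
) -> pd.DataFrame:
    """Monte-Carlo rejection rates (type-I error or power) per test.

    Each replicate simulates a fresh population from ``config`` (the
    config seed is ignored; ``seed`` drives the whole study), samples the
    extreme cohorts and applies every requested test at level ``alpha``.
    ``directional`` also reports the paper-style combined rule: reject if
    either directional test rejects.  Returns one row per test with the
    rejection fraction and its 95% Clopper-Pearson interval.
    """
    from scipy.stats import beta as beta_dist

    for t in tests:
        if t not in KNOWN_TESTS and t != "directional":
            raise ConfigurationError(f"unknown test {t!r}; known: {KNOWN_TESTS + ('directional',)}")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(2 * n_sims, dtype=np.uint32)
    rejections = {t: 0 for t in tests}
    for rep in range(n_sims):
        rng = np.random.default_rng(int(child_seeds[2 * rep]))
        perm_seed = int(child_seeds[2 * rep + 1])
        G, directions, *_rest, hdl = _simulate_population(config, rng)
        directions = np.asarray(directions)
        high_idx, low_idx = _sample_cohorts(hdl, config, rng)
        idx = np.concatenate([high_idx, low_idx])
        is_high = np.zeros(idx.size, dtype=bool)
        is_high[: high_idx.size] = True
        Gc = G[idx]
        cache: dict[str, float] = {}

        def pval(name: str) -> float:
            if name not in cache:
                cache[name] = _run_test_fast(
                    name, Gc, is_high, directions, config.n_high, config.n_low,
                    perm_seed, n_permutations,
                )
            return cache[name]

        for t in tests:
            if t == "directional":
                rejected = (pval("directional_decrease") < alpha) or (
                    pval("directional_increase") < alpha
                )
            else:
                rejected = pval(t) < alpha
            rejections[t] += int(rejected)

    rows = []
    for t in tests:
        k = rejections[t]
        lo = 0.0 if k == 0 else float(beta_dist.ppf(0.025, k, n_sims - k + 1))
        hi = 1.0 if k == n_sims else float(beta_dist.ppf(0.975, k + 1, n_sims - k))
        rows.append(
            {
                "test": t,
                "n_sims": n_sims,
                "rejections": k,
                "rate": k / n_sims,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)


def calls_from_study(study: SyntheticStudy, alpha: float = 0.05):
    """Run the reporter-assay pipeline on the study's generated plates."""
    return assay_mod.call_variants(study.wells, alpha=alpha)


def carrier_table_from_study(study: SyntheticStudy) -> CarrierTable:
    df = study.carriers_frame()
    members = study.cohort_individuals
    # ensure non-carrier individuals are represented too
    base = pd.DataFrame(
        {"individual_id": members["individual_id"], "cohort": members["cohort"]}
    )
    table = CarrierTable.from_long(df) if len(df) else None
    if table is None:
        incidence = pd.DataFrame(index=base["individual_id"])
        return CarrierTable(incidence.astype(bool), base.set_index("individual_id")["cohort"])
    incidence = table.incidence.reindex(base["individual_id"], fill_value=False)
    cohort_of = base.set_index("individual_id")["cohort"]
    return CarrierTable(incidence, cohort_of)
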