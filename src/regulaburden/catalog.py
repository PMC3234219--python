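"""Variant catalog data model and I/O.

The catalog covers a resequenced regulatory region described in
TSS-relative coordinates (negative = upstream promoter, positive =
transcribed 5' UTR; position 0 is disallowed by convention).  Variants
carry per-cohort genotype counts, a minor-allele-frequency class, and an
optional per-individual carrier table used for de-duplicated carrier
counting in the burden analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

from .errors import SchemaError, UnknownVariantError, ValidationError

#: Default sequenced-region bounds in TSS-relative coordinates.
POSITION_MIN = -1755
POSITION_MAX = 252

#: Frequency-class thresholds on minor allele frequency.
RARE_MAF = 0.01
COMMON_MAF = 0.05

VARIANTS_COLUMNS = ["variant_id", "position", "ref", "alt", "cohort", "n_het", "n_hom_minor"]
CARRIERS_COLUMNS = ["individual_id", "cohort", "variant_id"]
COHORTS_COLUMNS = ["name", "n_individuals", "extreme", "percentile_bound", "trait_floor"]


@dataclass(frozen=True)
class CohortSpec:
    """One extreme-phenotype sequencing cohort."""

    name: str
    n_individuals: int
    extreme: str  # {"high", "low"}
    percentile_bound: float
    trait_floor: float | None = None

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValidationError(f"cohort {self.name!r}: n_individuals must be > 0")
        if self.extreme not in ("high", "low"):
            raise ValidationError(f"cohort {self.name!r}: extreme must be 'high' or 'low'")
        if self.extreme == "high" and self.percentile_bound < 50:
            raise ValidationError(
                f"cohort {self.name!r}: high-extreme cohort with percentile bound "
                f"{self.percentile_bound} < 50"
            )
        if self.extreme == "low" and self.percentile_bound > 50:
            raise ValidationError(
                f"cohort {self.name!r}: low-extreme cohort with percentile bound "
                f"{self.percentile_bound} > 50"
            )


@dataclass(frozen=True)
class GenotypeCounts:
    """Minor-allele genotype counts within one cohort."""

    n_het: int = 0
    n_hom_minor: int = 0

    def __post_init__(self) -> None:
        if self.n_het < 0 or self.n_hom_minor < 0:
            raise ValidationError("genotype counts must be non-negative")

    @property
    def n_carriers(self) -> int:
        return self.n_het + self.n_hom_minor

    @property
    def n_minor_alleles(self) -> int:
        return self.n_het + 2 * self.n_hom_minor


@dataclass
class VariantRecord:
    """One regulatory variant with TSS-relative position and per-cohort counts."""

    variant_id: str
    position: int
    ref_allele: str
    alt_allele: str
    counts: dict[str, GenotypeCounts] = field(default_factory=dict)
    freq_class: str | None = None

    def __post_init__(self) -> None:
        # structural invariants always hold; region bounds are checked in
        # validate() so loaders can override them
        if self.position == 0:
            raise ValidationError(
                f"variant {self.variant_id!r}: position 0 is disallowed "
                "(TSS-relative convention has no zero)"
            )
        if not self.ref_allele or not self.alt_allele:
            raise ValidationError(f"variant {self.variant_id!r}: alleles must be non-empty")
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"variant {self.variant_id!r}: ref and alt alleles identical")

    def validate(self, position_min: int = POSITION_MIN, position_max: int = POSITION_MAX) -> None:
        if not (position_min <= self.position <= position_max):
            raise ValidationError(
                f"variant {self.variant_id!r}: position {self.position} outside "
                f"sequenced region [{position_min}, {position_max}]"
            )

    def carriers_in(self, cohort: str) -> int:
        return self.counts.get(cohort, GenotypeCounts()).n_carriers

    @property
    def total_carriers(self) -> int:
        return sum(c.n_carriers for c in self.counts.values())

    def cohorts_with_carriers(self) -> set[str]:
        return {name for name, c in self.counts.items() if c.n_carriers > 0}


def compute_maf(n_hom_minor: int, n_het: int, n_individuals: int) -> float:
    """Allele-based minor allele frequency, (2*hom + het) / (2*N).

    Warns (does not error) if the computed frequency exceeds 0.5, which
    indicates a minor/major allele flip in the analyzed sample.
    """
    if n_hom_minor < 0 or n_het < 0 or n_individuals < 0:
        raise ValidationError("counts must be non-negative")
    if n_hom_minor + n_het > n_individuals:
        raise ValidationError(
            f"carrier count {n_hom_minor + n_het} exceeds cohort size {n_individuals}"
        )
    if n_individuals == 0:
        return 0.0
    maf = (2 * n_hom_minor + n_het) / (2 * n_individuals)
    if maf > 0.5:
        warnings.warn(
            f"computed allele frequency {maf:.4f} > 0.5; 'minor' allele may be flipped",
            stacklevel=2,
        )
    return maf


def classify_frequency(maf: float) -> str:
    """Map a minor allele frequency to {'rare', 'intermediate', 'common'}.

    rare: maf < 1%; common: maf >= 5%; the gap class is 'intermediate'.
    """
    if not (0.0 <= maf <= 1.0):
        raise ValidationError(f"allele frequency {maf} outside [0, 1]")
    if maf < RARE_MAF:
        return "rare"
    if maf >= COMMON_MAF:
        return "common"
    return "intermediate"


def load_cohorts(path) -> list[CohortSpec]:
    """Read a cohort definition TSV (columns: name, n_individuals, extreme,
    percentile_bound, trait_floor)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"name": str})
    missing = set(COHORTS_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing cohort columns {sorted(missing)}")
    cohorts = []
    for _, row in df.iterrows():
        floor = row["trait_floor"]
        cohorts.append(
            CohortSpec(
                name=str(row["name"]),
                n_individuals=int(row["n_individuals"]),
                extreme=str(row["extreme"]),
                percentile_bound=float(row["percentile_bound"]),
                trait_floor=None if pd.isna(floor) else float(floor),
            )
        )
    return cohorts


def save_cohorts(cohorts: list[CohortSpec], path) -> None:
    rows = [
        {
            "name": c.name,
            "n_individuals": c.n_individuals,
            "extreme": c.extreme,
            "percentile_bound": c.percentile_bound,
            "trait_floor": "" if c.trait_floor is None else c.trait_floor,
        }
        for c in cohorts
    ]
    pd.DataFrame(rows, columns=COHORTS_COLUMNS).to_csv(path, sep="\t", index=False)


def load_catalog(
    path,
    cohorts: list[CohortSpec],
    *,
    position_min: int = POSITION_MIN,
    position_max: int = POSITION_MAX,
) -> list[VariantRecord]:
    """Read a variant TSV (one row per variant x cohort) into VariantRecords.

    Every malformed row is reported with its (1-based, header-inclusive)
    line number; all problems are gathered before raising so a single run
    reports the full damage.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"variant_id": str, "cohort": str})
    missing = set(VARIANTS_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")

    cohort_sizes = {c.name: c.n_individuals for c in cohorts}
    records: dict[str, VariantRecord] = {}
    problems: list[str] = []
    for idx, row in df.iterrows():
        line_no = idx + 2  # header is line 1
        try:
            vid = str(row["variant_id"])
            cohort = str(row["cohort"])
            if cohort not in cohort_sizes:
                raise ValidationError(f"unknown cohort {cohort!r}")
            counts = GenotypeCounts(int(row["n_het"]), int(row["n_hom_minor"]))
            if counts.n_carriers > cohort_sizes[cohort]:
                raise ValidationError(
                    f"variant {vid!r}: {counts.n_carriers} carriers exceed cohort "
                    f"{cohort!r} size {cohort_sizes[cohort]}"
                )
            if vid in records:
                rec = records[vid]
                if int(row["position"]) != rec.position:
                    raise ValidationError(f"variant {vid!r}: inconsistent position across rows")
                if cohort in rec.counts:
                    raise ValidationError(f"variant {vid!r}: duplicate row for cohort {cohort!r}")
                rec.counts[cohort] = counts
            else:
                rec = VariantRecord(
                    variant_id=vid,
                    position=int(row["position"]),
                    ref_allele=str(row["ref"]),
                    alt_allele=str(row["alt"]),
                    counts={cohort: counts},
                )
                rec.validate(position_min, position_max)
                records[vid] = rec
        except (ValidationError, ValueError) as exc:
            problems.append(f"line {line_no}: {exc}")
    if problems:
        raise ValidationError(f"{path}: " + "; ".join(problems))

    assign_freq_classes(list(records.values()), cohorts)
    return list(records.values())


def assign_freq_classes(
    records: list[VariantRecord],
    cohorts: list[CohortSpec],
    per_cohort: str | None = None,
) -> None:
    """Set freq_class on each record.

    By default the MAF is computed over the combined sequencing sample;
    pass ``per_cohort`` to classify within a single named cohort instead.
    """
    if per_cohort is None:
        n_total = sum(c.n_individuals for c in cohorts)
        for rec in records:
            hom = sum(c.n_hom_minor for c in rec.counts.values())
            het = sum(c.n_het for c in rec.counts.values())
            rec.freq_class = classify_frequency(compute_maf(hom, het, n_total))
    else:
        sizes = {c.name: c.n_individuals for c in cohorts}
        for rec in records:
            counts = rec.counts.get(per_cohort, GenotypeCounts())
            maf = compute_maf(counts.n_hom_minor, counts.n_het, sizes[per_cohort])
            rec.freq_class = classify_frequency(maf)


def save_catalog(records: list[VariantRecord], path) -> None:
    """Write records back to the variant TSV schema (round-trips load_catalog)."""
    rows = []
    for rec in records:
        for cohort, counts in rec.counts.items():
            rows.append(
                {
                    "variant_id": rec.variant_id,
                    "position": rec.position,
                    "ref": rec.ref_allele,
                    "alt": rec.alt_allele,
                    "cohort": cohort,
                    "n_het": counts.n_het,
                    "n_hom_minor": counts.n_hom_minor,
                }
            )
    pd.DataFrame(rows, columns=VARIANTS_COLUMNS).to_csv(path, sep="\t", index=False)


class CarrierTable:
    """Individual x variant incidence with one cohort label per individual."""

    def __init__(self, incidence: pd.DataFrame, cohort_of: pd.Series):
        # incidence: boolean frame indexed by individual_id, columns variant_id
        self.incidence = incidence.astype(bool)
        self.cohort_of = cohort_of
        if not self.incidence.index.equals(cohort_of.index):
            raise ValidationError("incidence index and cohort labels disagree")

    @classmethod
    def from_long(cls, df: pd.DataFrame) -> "CarrierTable":
        missing = set(CARRIERS_COLUMNS) - set(df.columns)
        if missing:
            raise SchemaError(f"carrier table missing columns {sorted(missing)}")
        cohort_of = df.groupby("individual_id")["cohort"].agg(set)
        multi = cohort_of[cohort_of.map(len) > 1]
        if len(multi):
            raise ValidationError(
                f"individuals assigned to multiple cohorts: {sorted(multi.index)}"
            )
        cohort_of = cohort_of.map(lambda s: next(iter(s)))
        incidence = pd.crosstab(df["individual_id"], df["variant_id"]).astype(bool)
        incidence = incidence.reindex(cohort_of.index)
        return cls(incidence, cohort_of)

    @classmethod
    def load(cls, path) -> "CarrierTable":
        df = pd.read_csv(
            path, sep="\t", comment="#", dtype={"individual_id": str, "variant_id": str}
        )
        return cls.from_long(df)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for ind, row in self.incidence.iterrows():
            for vid in self.incidence.columns[row.values]:
                rows.append(
                    {
                        "individual_id": ind,
                        "cohort": self.cohort_of[ind],
                        "variant_id": vid,
                    }
                )
        return pd.DataFrame(rows, columns=CARRIERS_COLUMNS)

    def save(self, path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)

    @property
    def variant_ids(self) -> set[str]:
        return set(self.incidence.columns)

    def carrier_count(self, variant_id: str, cohort: str) -> int:
        if variant_id not in self.incidence.columns:
            raise UnknownVariantError(variant_id)
        mask = self.cohort_of == cohort
        return int(self.incidence.loc[mask, variant_id].sum())

    def validate_against(self, records: list[VariantRecord]) -> None:
        """Check that per-cohort incidence column sums equal catalog carrier counts."""
        for rec in records:
            if rec.variant_id not in self.incidence.columns:
                if rec.total_carriers:
                    raise ValidationError(
                        f"variant {rec.variant_id!r} has catalog carriers but no "
                        "carrier-table entries"
                    )
                continue
            for cohort, counts in rec.counts.items():
                observed = self.carrier_count(rec.variant_id, cohort)
                if observed != counts.n_carriers:
                    raise ValidationError(
                        f"variant {rec.variant_id!r} cohort {cohort!r}: carrier table "
                        f"has {observed} carriers, catalog says {counts.n_carriers}"
                    )


def count_distinct_carriers(
    carriers: CarrierTable, variant_subset: set[str], cohort: CohortSpec | str
) -> int:
    """Number of distinct individuals in `cohort` carrying >= 1 subset variant.

    An individual carrying several subset variants is counted once.
    """
    cohort_name = cohort.name if isinstance(cohort, CohortSpec) else cohort
    unknown = set(variant_subset) - carriers.variant_ids
    if unknown:
        raise UnknownVariantError(f"unknown variant ids: {sorted(unknown)}")
    if not variant_subset:
        return 0
    mask = carriers.cohort_of == cohort_name
    sub = carriers.incidence.loc[mask, sorted(variant_subset)]
    return int(sub.any(axis=1).sum())
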