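"""Dual-luciferase reporter normalization and per-variant direction calling.

Each well reports a firefly (experimental) and a Renilla (transfection
control) luminescence reading.  Within a plate, every well's
firefly/Renilla ratio is divided by the mean ratio of the wild-type
construct wells on the same plate, yielding relative promoter activities
on a scale where the wild-type mean is exactly 1.  A variant's direction
of effect is called from an unpaired two-sample t-test of its relative
activities against the wild-type replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, NormalizationError, SchemaError, ValidationError

WT_CONSTRUCT = "WT"
EMPTY_VECTOR = "empty"

ASSAY_COLUMNS = ["plate_id", "construct", "firefly", "renilla"]
CALLS_COLUMNS = ["variant_id", "direction", "relative_activity", "p_value", "n_replicates"]

DIRECTIONS = ("decrease", "null", "increase")


@dataclass(frozen=True)
class ReporterWell:
    plate_id: str
    construct: str
    firefly: float
    renilla: float

    def __post_init__(self) -> None:
        if self.firefly < 0:
            raise ValidationError("firefly luminescence must be >= 0")
        # renilla == 0 wells are rejected at normalization time with a warning,
        # so only flat-out negative readings are an error here.
        if self.renilla < 0:
            raise ValidationError("renilla luminescence must be positive")


@dataclass(frozen=True)
class FunctionalCall:
    variant_id: str
    relative_activity: float
    p_value: float
    direction: str
    n_replicates: int

    def __post_init__(self) -> None:
        if self.relative_activity < 0:
            raise ValidationError("relative activity must be >= 0")
        if self.direction not in DIRECTIONS:
            raise ValidationError(f"unknown direction {self.direction!r}")


def normalize_plate(wells: list[ReporterWell]) -> dict[str, np.ndarray]:
    """Per-construct relative activities for one plate.

    Returns {construct: array of per-well relative activities}.  Requires
    at least one wild-type well; wells with renilla == 0 are dropped with
    a warning.
    """
    if not wells:
        raise NormalizationError("empty plate")
    plate_ids = {w.plate_id for w in wells}
    if len(plate_ids) != 1:
        raise NormalizationError(f"wells from multiple plates: {sorted(plate_ids)}")

    usable = []
    for w in wells:
        if w.renilla == 0:
            warnings.warn(
                f"plate {w.plate_id}: rejecting {w.construct} well with renilla == 0",
                stacklevel=2,
            )
            continue
        usable.append(w)

    wt_ratios = [w.firefly / w.renilla for w in usable if w.construct == WT_CONSTRUCT]
    if not wt_ratios:
        raise NormalizationError(f"plate {next(iter(plate_ids))}: no usable wild-type well")
    wt_mean = float(np.mean(wt_ratios))

    out: dict[str, list[float]] = {}
    for w in usable:
        out.setdefault(w.construct, []).append((w.firefly / w.renilla) / wt_mean)
    return {construct: np.asarray(vals, dtype=float) for construct, vals in out.items()}


def classify_direction(
    variant_acts,
    wt_acts,
    alpha: float = 0.05,
    *,
    variant_id: str = "",
    equal_var: bool = True,
) -> FunctionalCall:
    """Call a variant's direction from replicate relative activities.

    Two-sided pooled-variance Student's t-test by default (Welch via
    ``equal_var=False``).  p < alpha with variant mean above/below the
    wild-type mean gives 'increase'/'decrease'; otherwise 'null'.
    """
    v = np.asarray(variant_acts, dtype=float)
    w = np.asarray(wt_acts, dtype=float)
    if v.size < 2 or w.size < 2:
        raise InsufficientDataError("need >= 2 replicates in each group for a t-test")
    res = stats.ttest_ind(v, w, equal_var=equal_var)
    p = float(res.pvalue)
    if np.isnan(p):  # zero variance in both groups, identical means
        p = 1.0
    if p < alpha:
        direction = "increase" if v.mean() > w.mean() else "decrease"
    else:
        direction = "null"
    return FunctionalCall(
        variant_id=variant_id,
        relative_activity=float(v.mean()),
        p_value=p,
        direction=direction,
        n_replicates=int(v.size),
    )


def call_variants(
    wells: list[ReporterWell], alpha: float = 0.05, *, equal_var: bool = True
) -> dict[str, FunctionalCall]:
    """One FunctionalCall per construct across all plates.

    Calls are made independently per plate and then required to agree; if
    plates disagree the variant is called 'null' with a warning (the
    aggregation rule for replicate experiments).  Relative activity and
    replicate count are pooled over plates; the reported p-value is the
    largest per-plate p for agreeing calls (the most conservative of the
    agreeing experiments).
    """
    by_plate: dict[str, list[ReporterWell]] = {}
    for w in wells:
        by_plate.setdefault(w.plate_id, []).append(w)

    per_variant: dict[str, list[FunctionalCall]] = {}
    for plate_wells in by_plate.values():
        acts = normalize_plate(plate_wells)
        wt = acts.get(WT_CONSTRUCT)
        if wt is None:  # pragma: no cover - normalize_plate already errors
            continue
        for construct, vals in acts.items():
            if construct in (WT_CONSTRUCT, EMPTY_VECTOR):
                continue
            call = classify_direction(
                vals, wt, alpha, variant_id=construct, equal_var=equal_var
            )
            per_variant.setdefault(construct, []).append(call)

    out: dict[str, FunctionalCall] = {}
    for vid, calls in per_variant.items():
        directions = {c.direction for c in calls}
        rel = float(np.mean([c.relative_activity for c in calls]))
        n = int(sum(c.n_replicates for c in calls))
        if len(directions) == 1:
            direction = directions.pop()
            p = max(c.p_value for c in calls)
        else:
            warnings.warn(
                f"variant {vid}: plates disagree on direction {sorted(directions)}; "
                "calling null",
                stacklevel=2,
            )
            direction, p = "null", max(c.p_value for c in calls)
        if direction != "null" and p >= alpha:  # pragma: no cover - defensive
            direction = "null"
        out[vid] = FunctionalCall(vid, rel, p, direction, n)
    return out


def load_wells(path) -> list[ReporterWell]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"plate_id": str, "construct": str})
    missing = set(ASSAY_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing assay columns {sorted(missing)}")
    return [
        ReporterWell(str(r.plate_id), str(r.construct), float(r.firefly), float(r.renilla))
        for r in df.itertuples()
    ]


def save_wells(wells: list[ReporterWell], path) -> None:
    pd.DataFrame(
        [
            {"plate_id": w.plate_id, "construct": w.construct, "firefly": w.firefly, "renilla": w.renilla}
            for w in wells
        ],
        columns=ASSAY_COLUMNS,
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_calls(path) -> dict[str, FunctionalCall]:
    # keep_default_na: the literal direction "null" must not become NaN
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype={"variant_id": str, "direction": str},
        keep_default_na=False,
    )
    missing = set(CALLS_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing call columns {sorted(missing)}")
    calls = {}
    for r in df.itertuples():
        calls[str(r.variant_id)] = FunctionalCall(
            variant_id=str(r.variant_id),
            relative_activity=float(r.relative_activity),
            p_value=float(r.p_value),
            direction=str(r.direction),
            n_replicates=int(r.n_replicates),
        )
    return calls


def save_calls(calls: dict[str, FunctionalCall], path) -> None:
    pd.DataFrame(
        [
            {
                "variant_id": c.variant_id,
                "direction": c.direction,
                "relative_activity": c.relative_activity,
                "p_value": c.p_value,
                "n_replicates": c.n_replicates,
            }
            for c in calls.values()
        ],
        columns=["variant_id", "direction", "relative_activity", "p_value", "n_replicates"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
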