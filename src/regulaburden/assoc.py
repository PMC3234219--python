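"""Quantitative-trait association stages.

Two operations used around the burden analysis: phenotype
residualization/standardization (stratified OLS residuals rescaled to
mean 0, SD 1) and additive-genotype linear regression of a possibly
log-transformed trait on minor-allele count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegeneratePredictorError, ValidationError

PHENOTYPES_COLUMNS = ["individual_id", "trait"]


@dataclass(frozen=True)
class AssociationResult:
    variant_id: str
    beta: float
    se: float
    p_value: float
    n: int
    transform: str  # {"identity", "log"}


def residualize_standardize(
    df: pd.DataFrame,
    trait: str,
    covariates: list[str] | None = None,
    stratify_by: str | None = None,
) -> pd.Series:
    """Standardized OLS residuals of ``trait`` on ``covariates``, per stratum.

    Within each stratum the trait is regressed on an intercept plus the
    covariates; residuals are rescaled to mean 0, SD 1 (sample SD).
    Strata with fewer rows than parameters are skipped with a warning
    (their entries are NaN).  With no covariates this reduces to
    per-stratum z-scores.
    """
    covariates = covariates or []
    if trait not in df.columns:
        raise ValidationError(f"trait column {trait!r} not in frame")
    for c in covariates:
        if c not in df.columns:
            raise ValidationError(f"covariate column {c!r} not in frame")
    if stratify_by is not None and stratify_by not in df.columns:
        raise ValidationError(f"stratum column {stratify_by!r} not in frame")

    out = pd.Series(np.nan, index=df.index, name=f"{trait}_std_resid")
    groups = [(None, df)] if stratify_by is None else list(df.groupby(stratify_by))
    n_params = len(covariates) + 1
    for label, sub in groups:
        if len(sub) <= n_params:
            warnings.warn(
                f"stratum {label!r}: {len(sub)} rows <= {n_params} parameters; skipped",
                stacklevel=2,
            )
            continue
        y = sub[trait].to_numpy(dtype=float)
        if not np.isfinite(y).all():
            raise ValidationError(f"non-finite trait values in stratum {label!r}")
        X = np.column_stack([np.ones(len(sub))] + [sub[c].to_numpy(dtype=float) for c in covariates])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        sd = resid.std(ddof=1)
        if sd == 0:
            warnings.warn(f"stratum {label!r}: zero residual variance; skipped", stacklevel=2)
            continue
        out.loc[sub.index] = (resid - resid.mean()) / sd
    return out


def additive_regression(
    genotypes,
    trait,
    transform: str = "identity",
    variant_id: str = "",
) -> AssociationResult:
    """Slope of (possibly log-transformed) trait on minor-allele count.

    Returns the per-copy effect with its standard error and two-sided
    p-value from the t distribution.  Warns if the coded allele is not
    the minor allele in the analyzed sample.
    """
    g = np.asarray(genotypes, dtype=float)
    y = np.asarray(trait, dtype=float)
    if g.shape != y.shape:
        raise ValidationError("genotype and trait vectors differ in length")
    if transform not in ("identity", "log"):
        raise ValidationError(f"unknown transform {transform!r}")
    if np.var(g) == 0:
        raise DegeneratePredictorError("genotype has zero variance (monomorphic)")
    if g.mean() > 1.0:
        warnings.warn(
            "coded allele frequency > 0.5 in this sample; minor allele flipped "
            "versus the catalog",
            stacklevel=2,
        )
    if transform == "log":
        if (y <= 0).any():
            raise ValidationError("log transform requires strictly positive trait values")
        y = np.log(y)
    res = stats.linregress(g, y)
    n = g.size
    return AssociationResult(
        variant_id=variant_id,
        beta=float(res.slope),
        se=float(res.stderr),
        p_value=float(res.pvalue),
        n=int(n),
        transform=transform,
    )
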