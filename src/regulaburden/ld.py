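"""Pairwise linkage disequilibrium from unphased diploid genotypes.

Haplotype frequencies for a pair of biallelic loci are estimated by EM
over the 3x3 genotype count table (copies of the minor allele at each
locus).  Only the double-heterozygote cell is phase-ambiguous; its mass
is fractionally assigned between the two phase resolutions each E-step.
From the fitted frequencies the standard D, D' and r^2 are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConvergenceError, UndefinedStatisticError, ValidationError

GENOTYPES_COLUMNS = ["individual_id", "variant_id", "genotype"]


@dataclass(frozen=True)
class TwoLocusGenotypes:
    """3x3 genotype count table; entry (i, j) counts individuals with i
    copies of the locus-A minor allele and j copies at locus B."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 3):
            raise ValidationError("two-locus genotype table must be 3x3")
        if (c < 0).any():
            raise ValidationError("genotype counts must be non-negative")
        object.__setattr__(self, "counts", c.astype(int))

    @property
    def n_individuals(self) -> int:
        return int(self.counts.sum())

    @property
    def maf_a(self) -> float:
        i = np.arange(3)[:, None]
        return float((i * self.counts).sum() / (2 * self.n_individuals))

    @property
    def maf_b(self) -> float:
        j = np.arange(3)[None, :]
        return float((j * self.counts).sum() / (2 * self.n_individuals))


@dataclass(frozen=True)
class HaplotypeFreqs:
    pAB: float
    pAb: float
    paB: float
    pab: float
    log_likelihood: float
    n_iterations: int

    def __post_init__(self) -> None:
        freqs = (self.pAB, self.pAb, self.paB, self.pab)
        if any(f < -1e-12 for f in freqs):
            raise ValidationError("haplotype frequencies must be non-negative")
        if abs(sum(freqs) - 1.0) > 1e-9:
            raise ValidationError("haplotype frequencies must sum to 1")

    @property
    def pA(self) -> float:
        return self.pAB + self.pAb

    @property
    def pB(self) -> float:
        return self.pAB + self.paB


@dataclass(frozen=True)
class LDStats:
    D: float
    D_prime: float
    r2: float


def genotype_log_likelihood(p: np.ndarray, g: TwoLocusGenotypes) -> float:
    """Multinomial log-likelihood (constant dropped) of haplotype frequencies
    p = (pAB, pAb, paB, pab) given the genotype table."""
    pAB, pAb, paB, pab = p
    cell = np.empty((3, 3))
    cell[2, 2] = pAB**2
    cell[2, 1] = 2 * pAB * pAb
    cell[2, 0] = pAb**2
    cell[1, 2] = 2 * pAB * paB
    cell[1, 1] = 2 * (pAB * pab + pAb * paB)
    cell[1, 0] = 2 * pAb * pab
    cell[0, 2] = paB**2
    cell[0, 1] = 2 * paB * pab
    cell[0, 0] = pab**2
    counts = g.counts
    with np.errstate(divide="ignore"):
        logs = np.log(cell)
    mask = counts > 0
    if np.any(np.isneginf(logs[mask])):
        return -np.inf
    return float((counts[mask] * logs[mask]).sum())


def _fixed_gamete_counts(counts: np.ndarray) -> tuple[float, float, float, float, float]:
    """Phase-unambiguous gamete counts (AB, Ab, aB, ab) plus the
    double-heterozygote count."""
    nAB = 2 * counts[2, 2] + counts[2, 1] + counts[1, 2]
    nAb = 2 * counts[2, 0] + counts[2, 1] + counts[1, 0]
    naB = 2 * counts[0, 2] + counts[1, 2] + counts[0, 1]
    nab = 2 * counts[0, 0] + counts[1, 0] + counts[0, 1]
    ndh = counts[1, 1]
    return float(nAB), float(nAb), float(naB), float(nab), float(ndh)


def em_haplotype_freq(
    g: TwoLocusGenotypes, tol: float = 1e-10, max_iter: int = 1000
) -> HaplotypeFreqs:
    """Maximum-likelihood haplotype frequencies by EM.

    Initialized at linkage equilibrium (pAB = pA * pB); converges when the
    largest absolute frequency change drops below ``tol``.  With no
    double heterozygotes there is no ambiguity and the direct gamete
    counts are returned after a single step.
    """
    n = g.n_individuals
    if n == 0:
        raise ValidationError("empty genotype table")
    nAB, nAb, naB, nab, ndh = _fixed_gamete_counts(g.counts)
    two_n = 2.0 * n

    if ndh == 0:
        p = np.array([nAB, nAb, naB, nab]) / two_n
        ll = genotype_log_likelihood(p, g)
        return HaplotypeFreqs(*p, log_likelihood=ll, n_iterations=1)

    pA, pB = g.maf_a, g.maf_b
    p = np.array([pA * pB, pA * (1 - pB), (1 - pA) * pB, (1 - pA) * (1 - pB)])
    prev_ll = genotype_log_likelihood(p, g)
    for it in range(1, max_iter + 1):
        pAB, pAb, paB, pab = p
        denom = pAB * pab + pAb * paB
        frac = 0.5 if denom == 0 else (pAB * pab) / denom
        new = (
            np.array(
                [nAB + ndh * frac, nAb + ndh * (1 - frac), naB + ndh * (1 - frac), nab + ndh * frac]
            )
            / two_n
        )
        ll = genotype_log_likelihood(new, g)
        if ll < prev_ll - 1e-9:  # pragma: no cover - EM guarantees monotonicity
            raise ConvergenceError(f"log-likelihood decreased at iteration {it}")
        delta = float(np.abs(new - p).max())
        p, prev_ll = new, ll
        if delta < tol:
            return HaplotypeFreqs(*p, log_likelihood=prev_ll, n_iterations=it)
    raise ConvergenceError(
        f"EM did not converge in {max_iter} iterations (last delta {delta:.3e})"
    )


def ld_stats(h: HaplotypeFreqs) -> LDStats:
    """D, D' and r^2 from haplotype frequencies.

    Raises if either locus is monomorphic (allele frequency 0 or 1), where
    the normalized statistics are undefined.
    """
    pA, pB = h.pA, h.pB
    denom = pA * (1 - pA) * pB * (1 - pB)
    if denom <= 0:
        raise UndefinedStatisticError(
            f"LD undefined for allele frequencies pA={pA:.4g}, pB={pB:.4g}"
        )
    D = h.pAB - pA * pB
    r2 = D * D / denom
    if D > 0:
        d_max = min(pA * (1 - pB), (1 - pA) * pB)
    elif D < 0:
        d_max = min(pA * pB, (1 - pA) * (1 - pB))
    else:
        d_max = 1.0  # D' = 0 regardless
    return LDStats(D=D, D_prime=abs(D) / d_max, r2=r2)


def pair_ld(g: TwoLocusGenotypes, tol: float = 1e-10, max_iter: int = 1000):
    """Convenience: EM fit plus LD statistics for one genotype table.

    For a monomorphic locus the EM result is still returned but the LD
    statistics carry D = 0 with D'/r^2 flagged as NaN (undefined).
    """
    h = em_haplotype_freq(g, tol=tol, max_iter=max_iter)
    try:
        return h, ld_stats(h)
    except UndefinedStatisticError:
        return h, LDStats(D=0.0, D_prime=float("nan"), r2=float("nan"))


def table_from_long(df: pd.DataFrame, variant_a: str, variant_b: str) -> TwoLocusGenotypes:
    """Build the 3x3 table for a variant pair from a long genotype frame
    (individual_id, variant_id, genotype in {0,1,2}).  Individuals missing
    a genotype at either locus are dropped pairwise."""
    missing = set(GENOTYPES_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"genotype frame missing columns {sorted(missing)}")
    wide = df.pivot_table(index="individual_id", columns="variant_id", values="genotype")
    for v in (variant_a, variant_b):
        if v not in wide.columns:
            raise ValidationError(f"variant {v!r} not present in genotype table")
    sub = wide[[variant_a, variant_b]].dropna()
    counts = np.zeros((3, 3), dtype=int)
    for ga, gb in sub.itertuples(index=False):
        counts[int(ga), int(gb)] += 1
    return TwoLocusGenotypes(counts)
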