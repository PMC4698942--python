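"""Seeded synthetic case-control cohorts.

Stands in for the (non-redistributable) genome-privacy challenge
datasets that motivated the pipeline: biallelic SNP panels over two
equal groups of n individuals, genotypes drawn per individual as
Binomial(2, q) copies of the minor allele under Hardy-Weinberg
equilibrium, with a configurable fraction of truly associated SNPs
whose case-group allele frequency is shifted by a fixed delta.  No
linkage disequilibrium, population structure, or missingness is
modeled — the downstream test is per-SNP, so independent SNPs exercise
the same code paths.

Defaults mirror the shape of the challenge's first panel: 311 SNPs,
200 individuals per group, roughly 8% associated SNPs (about two dozen
signals), null minor-allele frequencies uniform on [0.05, 0.5], and a
0.15 case-control frequency shift, which at n = 200 puts associated
SNPs far into the rejection region of the 1-df chi-square test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError
from .gwas_chi2 import SNPCounts

__all__ = ["CohortSpec", "Cohort", "generate_cohort", "generate_null_counts"]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic case-control cohort."""

    n_snps: int = 311
    n: int = 200  # individuals per group
    assoc_frac: float = 0.08
    maf_range: tuple[float, float] = (0.05, 0.5)
    effect_delta: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_snps < 1 or self.n < 1:
            raise InputError("n_snps and n must be >= 1")
        if not 0.0 <= self.assoc_frac <= 1.0:
            raise InputError(f"assoc_frac must be in [0, 1], got {self.assoc_frac}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InputError(f"maf_range must sit inside (0, 0.5], got {self.maf_range}")
        if self.effect_delta < 0:
            raise InputError("effect_delta must be >= 0")


@dataclass(frozen=True)
class Cohort:
    """Genotype matrix (SNP x individual, 0/1/2 copies of allele 'a'),
    per-individual group labels, and per-SNP association truth."""

    genotypes: np.ndarray
    groups: tuple[str, ...]
    truth: np.ndarray  # bool per SNP: truly associated
    maf: np.ndarray    # null (control) minor-allele frequency per SNP
    spec: CohortSpec = field(repr=False)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a cohort under the spec; bit-reproducible for a fixed seed.

    Associated SNPs use allele frequency min(q + delta, 0.999) in the
    case group and q in controls; null SNPs share q across groups.
    """
    rng = np.random.default_rng(spec.seed)
    S, n = spec.n_snps, spec.n
    q = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=S)
    n_assoc = int(round(spec.assoc_frac * S))
    truth = np.zeros(S, dtype=bool)
    if n_assoc:
        truth[rng.choice(S, size=n_assoc, replace=False)] = True
    q_case = np.where(truth, np.minimum(q + spec.effect_delta, 0.999), q)
    cases = rng.binomial(2, q_case[:, None], size=(S, n))
    controls = rng.binomial(2, q[:, None], size=(S, n))
    genotypes = np.concatenate([cases, controls], axis=1).astype(np.int8)
    groups = ("case",) * n + ("control",) * n
    return Cohort(genotypes=genotypes, groups=groups, truth=truth, maf=q, spec=spec)


def generate_null_counts(
    n_snps: int, n: int, seed: int, q: float = 0.3
) -> list[SNPCounts]:
    """Direct count-level nulls: O11, O21 ~ Binomial(2n, q), shared q.

    Bypasses genotypes entirely; used to calibrate the type-I error of
    the exact statistic at scale (the allele-count margins O11 + O12 =
    2n hold by construction).  Monomorphic draws are representable and
    flagged by :class:`SNPCounts`.
    """
    if n_snps < 1 or n < 1:
        raise InputError("n_snps and n must be >= 1")
    if not 0.0 < q < 1.0:
        raise InputError(f"allele frequency q must be in (0, 1), got {q}")
    rng = np.random.default_rng(seed)
    o11 = rng.binomial(2 * n, q, size=n_snps)
    o21 = rng.binomial(2 * n, q, size=n_snps)
    return [
        SNPCounts(f"snp{i}", int(a), 2 * n - int(a), int(b), 2 * n - int(b))
        for i, (a, b) in enumerate(zip(o11, o21))
    ]
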