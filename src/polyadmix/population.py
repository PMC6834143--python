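"""Diploid populations and the multiplicative polygenic risk score.

Individuals are stored column-compactly as two phased haplotype bit matrices
(one row per individual, one column per architecture locus; 1 = risk allele).
Phased storage is required because meiotic recombination operates on
haplotypes. The PRS is computed in natural-log units:
``beta_i = sum_k a_ki ln(r_k)`` with ``a_ki = hap_a[k] + hap_b[k]``, so that
``exp(beta_i)`` is the individual's relative risk ``R_i = prod_k r_k^{a_ki}``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .architecture import Architecture
from .errors import InvalidParameterError, StructuralError

__all__ = ["Individual", "Population", "init_population", "prs", "population_moments"]

FEMALE, MALE = 0, 1

_CHUNK = 16384


@dataclass
class Individual:
    """A single diploid individual (a row view into a :class:`Population`)."""

    haplotype_a: np.ndarray
    haplotype_b: np.ndarray
    sex: int  # 0 = F, 1 = M
    pop_label: int

    @property
    def dosage(self) -> np.ndarray:
        """Risk-allele counts a_k in {0, 1, 2} per locus."""
        return self.haplotype_a.astype(np.int64) + self.haplotype_b


class Population:
    """A collection of diploid individuals sharing one architecture.

    Parameters
    ----------
    hap_a, hap_b : (N, L) uint8 matrices of phased risk-allele indicators.
    sex : (N,) array, 0 = female, 1 = male.
    arch : the shared :class:`Architecture`.
    pop_label : population label in {1, 2}.
    """

    def __init__(self, hap_a, hap_b, sex, arch: Architecture, pop_label: int = 1):
        self.hap_a = np.ascontiguousarray(hap_a, dtype=np.uint8)
        self.hap_b = np.ascontiguousarray(hap_b, dtype=np.uint8)
        self.sex = np.asarray(sex, dtype=np.uint8)
        self.arch = arch
        self.pop_label = int(pop_label)
        if self.hap_a.shape != self.hap_b.shape:
            raise StructuralError("haplotype matrices must have equal shape")
        if self.hap_a.shape[1] != arch.n_loci:
            raise StructuralError(
                f"haplotype length {self.hap_a.shape[1]} does not match architecture ({arch.n_loci} loci)"
            )
        if self.hap_a.shape[0] != self.sex.shape[0]:
            raise StructuralError("sex array length must equal population size")
        if self.size < 1:
            raise InvalidParameterError("population must contain at least one individual")

    @property
    def size(self) -> int:
        return int(self.hap_a.shape[0])

    @property
    def n_loci(self) -> int:
        return int(self.hap_a.shape[1])

    def individual(self, i: int) -> Individual:
        return Individual(self.hap_a[i], self.hap_b[i], int(self.sex[i]), self.pop_label)

    def prs_values(self) -> np.ndarray:
        """PRS beta_i for every individual, in natural-log(RR) units."""
        eff = self.arch.effect
        out = np.empty(self.size)
        for s in range(0, self.size, _CHUNK):
            e = min(s + _CHUNK, self.size)
            a = self.hap_a[s:e].astype(np.float64)
            a += self.hap_b[s:e]
            out[s:e] = a @ eff
        return out

    def allele_frequencies(self) -> np.ndarray:
        """Realized risk-allele frequency per locus."""
        return (
            self.hap_a.sum(axis=0, dtype=np.int64) + self.hap_b.sum(axis=0, dtype=np.int64)
        ) / (2.0 * self.size)

    def genotype_counts(self) -> np.ndarray:
        """(L, 3) counts of genotypes 0/1/2 per locus."""
        dos = self.hap_a.astype(np.int64) + self.hap_b
        return np.stack([(dos == g).sum(axis=0) for g in (0, 1, 2)], axis=1)

    def to_frame(self):
        """One row per individual: id, pop, sex, prs (haplotypes omitted)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "id": np.arange(self.size),
                "pop": self.pop_label,
                "sex": np.where(self.sex == MALE, "M", "F"),
                "prs": self.prs_values(),
            }
        )


def init_population(
    N: int,
    arch: Architecture,
    pop_index: int = 1,
    sex_ratio: float = 0.5,
    seed=None,
) -> Population:
    """Initialize a Hardy-Weinberg population from architecture frequencies.

    Each haplotype bit at locus k is an independent Bernoulli(p_k) draw using
    the frequency column for ``pop_index``; sexes are i.i.d. with
    ``P(female) = sex_ratio``.
    """
    if N < 1:
        raise InvalidParameterError(f"population size must be positive, got {N}")
    if not 0.0 <= sex_ratio <= 1.0:
        raise InvalidParameterError(f"sex_ratio must be in [0,1], got {sex_ratio}")
    rng = np.random.default_rng(seed)
    # a single-column architecture serves both populations
    p = arch.freq[:, min(pop_index, arch.n_populations) - 1]
    L = arch.n_loci

    p32 = p.astype(np.float32)
    hap_a = np.empty((N, L), dtype=np.uint8)
    hap_b = np.empty((N, L), dtype=np.uint8)
    for s in range(0, N, _CHUNK):
        e = min(s + _CHUNK, N)
        hap_a[s:e] = rng.random((e - s, L), dtype=np.float32) < p32
        hap_b[s:e] = rng.random((e - s, L), dtype=np.float32) < p32
    sex = (rng.random(N) >= sex_ratio).astype(np.uint8)  # 0=F with prob sex_ratio
    return Population(hap_a, hap_b, sex, arch, pop_label=pop_index)


def prs(ind: Individual, arch: Architecture) -> float:
    """PRS of a single individual: beta = sum_k a_k ln(r_k)."""
    if ind.haplotype_a.shape[0] != arch.n_loci:
        raise StructuralError("genotype length does not match architecture")
    return float(ind.dosage @ arch.effect)


class Moments(NamedTuple):
    mean: float
    variance: float
    expected_variance: float  # linkage-equilibrium sum 2 p(1-p) beta^2 at realized freqs


def population_moments(pop: Population) -> Moments:
    """Sample mean/variance of the PRS, plus the linkage-equilibrium variance
    expected from the current realized allele frequencies (their gap measures
    cross-locus linkage disequilibrium)."""
    if pop.size < 2:
        raise InvalidParameterError("need at least two individuals for a variance")
    values = pop.prs_values()
    phat = pop.allele_frequencies()
    exp_var = float(np.sum(2.0 * phat * (1.0 - phat) * pop.arch.effect**2))
    return Moments(float(values.mean()), float(values.var(ddof=1)), exp_var)
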