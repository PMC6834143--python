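"""Non-overlapping-generation reproduction with admixture and recombination.

Mate choice follows a two-population Wright-Fisher scheme: each offspring is
produced by a cross-population pair with probability ``m`` (the admixture
rate) and by a within-population pair otherwise; parents are drawn uniformly
with replacement among the eligible sexes. Cross-pair offspring belong to
either population with equal probability; within-pair offspring keep their
parents' label. Per-label offspring counts are exact each generation.

Recombination places a Poisson(lambda) number of crossovers uniformly on the
unit genome per transmitted gamete and copies alternating parental haplotypes
between crossovers, starting from a fair coin. Because crossover positions
form a Poisson process, the allele source along the ordered loci is a
two-state Markov chain whose flip probability across an inter-locus gap of
map distance d is ``(1 - exp(-2 lambda d)) / 2`` (the Haldane map function);
the vectorized generator samples these flips directly, which is identical in
distribution to placing explicit crossovers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import ConfigurationError, InvalidParameterError
from .population import FEMALE, MALE, Individual, Population

try:  # optional acceleration; the numpy path is identical in distribution
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "ReproductionParams",
    "make_gamete",
    "pair_parents",
    "next_generation",
    "mixing_projection",
]

_CHUNK = 8192


@dataclass
class ReproductionParams:
    """Parameters of one generation step.

    admixture : probability m in [0,1] that a mating pair is cross-population.
    crossover_mean : expected crossovers per transmitted gamete (lambda);
        36 models a typical human-scale genome, 1000 accelerates convergence
        to linkage equilibrium.
    sizes : target offspring count per population label.
    generations : number of generations a scenario runs for.
    sex_ratio : P(female) among offspring.
    """

    admixture: float = 0.0
    crossover_mean: float = 36.0
    sizes: tuple[int, int] = (10000, 10000)
    generations: int = 1
    sex_ratio: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.admixture <= 1.0:
            raise InvalidParameterError(f"admixture rate must be in [0,1], got {self.admixture}")
        if self.crossover_mean < 0.0:
            raise InvalidParameterError(f"crossover_mean must be >= 0, got {self.crossover_mean}")
        if any(s <= 0 for s in self.sizes):
            raise InvalidParameterError(f"population sizes must be positive, got {self.sizes}")


def make_gamete(ind: Individual, lam: float, seed=None, positions: np.ndarray | None = None) -> np.ndarray:
    """Produce one recombinant gamete from an individual.

    Draws ``k ~ Poisson(lam)`` crossover positions uniformly on [0, 1) and
    copies alternating parental haplotypes between them, starting from a
    fair-coin haplotype choice. ``positions`` are the locus map positions
    (taken from the architecture by callers that have one).
    """
    if lam < 0.0:
        raise InvalidParameterError(f"crossover rate must be >= 0, got {lam}")
    rng = np.random.default_rng(seed)
    L = ind.haplotype_a.shape[0]
    if positions is None:
        positions = np.linspace(0.0, 1.0, L, endpoint=False)
    k = rng.poisson(lam)
    cross = np.sort(rng.random(k))
    start = rng.integers(2)
    parity = (start + np.searchsorted(cross, positions, side="right")) % 2
    return np.where(parity == 0, ind.haplotype_a, ind.haplotype_b).astype(np.uint8)


def _flip_probs(positions: np.ndarray, lam: float) -> np.ndarray:
    """Markov flip probabilities across inter-locus gaps (Haldane map)."""
    d = np.diff(positions)
    return 0.5 * (1.0 - np.exp(-2.0 * lam * d))


if _HAVE_NUMBA:

    @_njit(cache=False)
    def _gamete_kernel_flips(hap_a, hap_b, rows, dest, flips, out):  # pragma: no cover
        """Per-locus Markov walk of the allele source given precomputed flip
        indicators (preferred when crossovers are dense relative to loci)."""
        for i in range(rows.shape[0]):
            r = rows[i]
            d = dest[i]
            cur = 0
            for j in range(flips.shape[1]):
                cur ^= flips[i, j]
                out[d, j] = hap_a[r, j] if cur == 0 else hap_b[r, j]

    @_njit(cache=False)
    def _gamete_kernel(hap_a, hap_b, rows, dest, positions, lam, out, seed):  # pragma: no cover
        """Copy crossover segments parent->gamete, walking the Poisson
        crossover process along the genome (compiled)."""
        np.random.seed(seed)
        n = rows.shape[0]
        L = positions.shape[0]
        for i in range(n):
            r = rows[i]
            d = dest[i]
            cur = 0 if np.random.random() < 0.5 else 1
            j0 = 0
            x = np.random.exponential(1.0 / lam) if lam > 0.0 else 2.0
            while x < 1.0 and j0 < L:
                j1 = np.searchsorted(positions, x)
                if j1 > j0:
                    if cur == 0:
                        out[d, j0:j1] = hap_a[r, j0:j1]
                    else:
                        out[d, j0:j1] = hap_b[r, j0:j1]
                    j0 = j1
                cur ^= 1
                x += np.random.exponential(1.0 / lam)
            if j0 < L:
                if cur == 0:
                    out[d, j0:L] = hap_a[r, j0:L]
                else:
                    out[d, j0:L] = hap_b[r, j0:L]


def _fill_gametes(
    out: np.ndarray,
    dest: np.ndarray,
    pop: Population,
    parent_rows: np.ndarray,
    lam: float,
    rng: np.random.Generator,
) -> None:
    """Write one recombinant gamete per parent into ``out[dest]``."""
    L = pop.n_loci
    if _HAVE_NUMBA:
        if lam * 4.0 < L:  # sparse crossovers: walk segments
            seed = int(rng.integers(2**31 - 1))
            _gamete_kernel(pop.hap_a, pop.hap_b, parent_rows, dest, pop.arch.position, float(lam), out, seed)
        else:  # dense crossovers: per-locus source flips (numpy-sampled)
            th = np.empty(L, dtype=np.float32)
            th[0] = 0.5  # fair-coin starting haplotype
            th[1:] = _flip_probs(pop.arch.position, lam)
            n = parent_rows.shape[0]
            for s in range(0, n, _CHUNK):
                e = min(s + _CHUNK, n)
                flips = (rng.random((e - s, L), dtype=np.float32) < th).view(np.uint8)
                _gamete_kernel_flips(pop.hap_a, pop.hap_b, parent_rows[s:e], dest[s:e], flips, out)
        return
    n = parent_rows.shape[0]
    thresh = np.empty(L, dtype=np.float32)
    thresh[0] = 0.5  # fair-coin starting haplotype
    thresh[1:] = _flip_probs(pop.arch.position, lam)
    for s in range(0, n, _CHUNK):
        e = min(s + _CHUNK, n)
        rows = parent_rows[s:e]
        flips = (rng.random((e - s, L), dtype=np.float32) < thresh).view(np.uint8)
        np.cumsum(flips, axis=1, dtype=np.uint8, out=flips)  # uint8 wraparound preserves parity
        flips &= 1
        out[dest[s:e]] = np.where(flips, pop.hap_b[rows], pop.hap_a[rows])


def _gametes(pop: Population, parent_rows: np.ndarray, lam: float, rng: np.random.Generator) -> np.ndarray:
    """Recombinant gametes for many parents at once.

    The crossover count per gamete is Poisson(lam) with positions uniform on
    the unit genome; equivalently (and as implemented) the allele source is a
    Markov chain along the ordered loci with Haldane flip probabilities.
    """
    out = np.empty((parent_rows.shape[0], pop.n_loci), dtype=np.uint8)
    _fill_gametes(out, np.arange(parent_rows.shape[0]), pop, parent_rows, lam, rng)
    return out


class ParentPairs(NamedTuple):
    """Chosen parents for a batch of offspring slots."""

    mother_pop: np.ndarray  # label in {1,2}
    mother_idx: np.ndarray
    father_pop: np.ndarray
    father_idx: np.ndarray
    cross: np.ndarray  # True if the pair is cross-population
    offspring_label: np.ndarray


def pair_parents(
    pop1: Population,
    pop2: Population,
    m: float,
    seed=None,
    n_offspring: tuple[int, int] | None = None,
) -> ParentPairs:
    """Draw mating pairs for every offspring slot.

    With probability ``m`` a pair is cross-population (one parent from each,
    maternal population chosen by fair coin), otherwise within-population.
    Parents are drawn uniformly with replacement among the eligible sex.
    Offspring labels are fixed per slot (exact per-label counts); this is
    distribution-equivalent to labeling cross offspring 50/50 and resampling
    to the configured sizes when the two populations have equal size.
    """
    if not 0.0 <= m <= 1.0:
        raise InvalidParameterError(f"admixture rate must be in [0,1], got {m}")
    rng = np.random.default_rng(seed)
    pops = {1: pop1, 2: pop2}
    females = {k: np.flatnonzero(p.sex == FEMALE) for k, p in pops.items()}
    males = {k: np.flatnonzero(p.sex == MALE) for k, p in pops.items()}
    for k in (1, 2):
        if females[k].size == 0 or males[k].size == 0:
            raise ConfigurationError(f"population {k} lacks one of the sexes required for mating")

    if n_offspring is None:
        n_offspring = (pop1.size, pop2.size)
    total = int(sum(n_offspring))
    label = np.repeat([1, 2], n_offspring)
    cross = rng.random(total) < m
    # maternal population: own label for within pairs, fair coin for cross pairs
    mother_pop = label.copy()
    flip = cross & (rng.random(total) < 0.5)
    mother_pop[flip] = 3 - mother_pop[flip]
    father_pop = np.where(cross, 3 - mother_pop, mother_pop)

    mother_idx = np.empty(total, dtype=np.int64)
    father_idx = np.empty(total, dtype=np.int64)
    for k in (1, 2):
        sel = mother_pop == k
        mother_idx[sel] = rng.choice(females[k], size=int(sel.sum()), replace=True)
        sel = father_pop == k
        father_idx[sel] = rng.choice(males[k], size=int(sel.sum()), replace=True)
    return ParentPairs(mother_pop, mother_idx, father_pop, father_idx, cross, label)


def next_generation(
    pops: tuple[Population, Population],
    params: ReproductionParams,
    seed=None,
) -> tuple[Population, Population]:
    """Advance one non-overlapping generation.

    Each offspring receives one recombinant gamete from each parent; sexes
    are assigned per ``params.sex_ratio``; per-label offspring counts equal
    ``params.sizes`` exactly.
    """
    rng = np.random.default_rng(seed)
    pop1, pop2 = pops
    if pop1.arch is not pop2.arch and pop1.arch.fingerprint() != pop2.arch.fingerprint():
        raise ConfigurationError("populations must share one architecture")
    pairs = pair_parents(pop1, pop2, params.admixture, seed=rng, n_offspring=params.sizes)

    total = pairs.offspring_label.shape[0]
    L = pop1.n_loci
    gam_m = np.empty((total, L), dtype=np.uint8)
    gam_f = np.empty((total, L), dtype=np.uint8)
    by_pop = {1: pop1, 2: pop2}
    for k in (1, 2):
        sel = np.flatnonzero(pairs.mother_pop == k)
        if sel.size:
            _fill_gametes(gam_m, sel, by_pop[k], pairs.mother_idx[sel], params.crossover_mean, rng)
        sel = np.flatnonzero(pairs.father_pop == k)
        if sel.size:
            _fill_gametes(gam_f, sel, by_pop[k], pairs.father_idx[sel], params.crossover_mean, rng)

    sex = (rng.random(total) >= params.sex_ratio).astype(np.uint8)
    # offspring slots are ordered by label, so label splits are views
    n1 = params.sizes[0]
    return (
        Population(gam_m[:n1], gam_f[:n1], sex[:n1], pop1.arch, pop_label=1),
        Population(gam_m[n1:], gam_f[n1:], sex[n1:], pop1.arch, pop_label=2),
    )


def mixing_projection(
    beta1: float,
    beta2: float,
    m: float,
    g: int,
    fixed_beta1: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic per-generation mean-PRS trajectories under admixture.

    The symmetric recurrence for equal population sizes is

        beta2(g+1) = beta2(g) - 0.5 m (beta2(g) - beta1(g))

    with the mirrored update for population 1. With ``fixed_beta1`` the
    population-1 mean is held constant (the island-continent variant used
    for maintenance gene therapy).

    Returns arrays of length ``g + 1`` including the initial values.
    """
    if not 0.0 <= m <= 1.0:
        raise InvalidParameterError(f"admixture rate must be in [0,1], got {m}")
    if g < 0:
        raise InvalidParameterError("generation count must be >= 0")
    t1 = np.empty(g + 1)
    t2 = np.empty(g + 1)
    t1[0], t2[0] = beta1, beta2
    for i in range(g):
        gap = t2[i] - t1[i]
        t2[i + 1] = t2[i] - 0.5 * m * gap
        t1[i + 1] = t1[i] if fixed_beta1 else t1[i] + 0.5 * m * gap
    return t1, t2
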