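"""Genetic architectures for common low-effect polygenic diseases.

A disease architecture is a set of causal biallelic loci on a single linear
genome of map length 1.0. Each locus carries a per-risk-allele relative risk
``r_k > 1``; the additive effect on the log-relative-risk scale is
``beta_k = ln(r_k)``. An individual's polygenic risk score (PRS) is
``beta_i = sum_k a_ki * beta_k`` with ``a_ki`` in {0, 1, 2}, so that
``exp(beta_i)`` is the individual's multiplicative relative risk.

The number of loci is calibrated so that the population PRS variance under
Hardy-Weinberg / linkage equilibrium,

    V = sum_k 2 p_k (1 - p_k) beta_k^2,

equals the liability-scale target ``V(h2) = (h2 / (1 - h2)) * pi^2 / 3``,
i.e. the residual (environmental) liability is standard logistic. With a mean
relative risk of 1.1 and minor-allele frequencies uniform on (0.05, 0.5) this
yields roughly 920 loci at h2 = 0.5, 1380 at 0.6 and 3690 at 0.8, and an
average of ~510 carried risk alleles per individual at h2 = 0.5.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidParameterError

__all__ = [
    "RiskLocus",
    "Architecture",
    "liability_prs_variance",
    "build_architecture",
    "split_differing",
    "add_high_risk_subset",
]

#: default half-width of the uniform relative-risk distribution around mean_rr
RR_HALFWIDTH = 0.05

_PMF_TRIM = 1e-15


def liability_prs_variance(heritability: float) -> float:
    """Target PRS variance V(h2) = (h2/(1-h2)) * pi^2/3.

    The environmental liability component is standard logistic (variance
    pi^2/3); the genetic component then contributes a fraction h2 of the
    total liability variance.
    """
    if not 0.0 < heritability < 1.0:
        raise InvalidParameterError(f"heritability must be in (0,1), got {heritability}")
    return heritability / (1.0 - heritability) * np.pi**2 / 3.0


def _mean_2pq(maf_lo: float, maf_hi: float) -> float:
    """E[2 p (1-p)] for p ~ U(maf_lo, maf_hi), in closed form."""
    m1 = (maf_lo + maf_hi) / 2.0
    m2 = (maf_hi**3 - maf_lo**3) / (3.0 * (maf_hi - maf_lo))
    return 2.0 * (m1 - m2)


def _mean_log_rr_sq(rr_lo: float, rr_hi: float) -> float:
    """E[(ln r)^2] for r ~ U(rr_lo, rr_hi), in closed form.

    Antiderivative of (ln r)^2 is r[(ln r)^2 - 2 ln r + 2].
    """

    def antideriv(r: float) -> float:
        lr = np.log(r)
        return r * (lr * lr - 2.0 * lr + 2.0)

    return (antideriv(rr_hi) - antideriv(rr_lo)) / (rr_hi - rr_lo)


@dataclass(frozen=True)
class RiskLocus:
    """A single causal locus (a convenience view into an :class:`Architecture`)."""

    locus_id: int
    position: float
    rr: float
    effect: float
    freq: np.ndarray  # one risk-allele frequency per population

    def __post_init__(self):
        if self.rr <= 1.0:
            raise InvalidParameterError(f"relative risk must be > 1, got {self.rr}")
        if abs(self.effect - np.log(self.rr)) > 1e-12:
            raise InvalidParameterError("effect must equal ln(rr)")
        f = np.asarray(self.freq, dtype=float)
        if np.any(f < 0.0) or np.any(f > 1.0):
            raise InvalidParameterError("allele frequencies must lie in [0,1]")


@dataclass
class Architecture:
    """An ordered set of causal risk loci with per-population frequencies.

    Attributes
    ----------
    locus_id : (L,) int array of unique locus identifiers.
    position : (L,) float array, strictly increasing in [0, 1).
    rr : (L,) float array of per-allele relative risks (> 1).
    effect : (L,) float array, ``ln(rr)``.
    freq : (L, n_populations) float array of risk-allele frequencies.
    heritability_target : the h2 the locus count was calibrated for.
    mean_rr : configured mean relative risk.
    lineage : hex token identifying the base architecture this one derives
        from; preserved by :func:`split_differing` and
        :func:`add_high_risk_subset` so that a PRS-probability mapping
        calibrated on the base architecture remains applicable.
    """

    locus_id: np.ndarray
    position: np.ndarray
    rr: np.ndarray
    effect: np.ndarray
    freq: np.ndarray
    heritability_target: float
    mean_rr: float
    lineage: str = ""

    def __post_init__(self):
        self.locus_id = np.asarray(self.locus_id, dtype=np.int64)
        self.position = np.asarray(self.position, dtype=float)
        self.rr = np.asarray(self.rr, dtype=float)
        self.effect = np.asarray(self.effect, dtype=float)
        self.freq = np.atleast_2d(np.asarray(self.freq, dtype=float))
        if self.freq.shape[0] != self.rr.shape[0]:
            self.freq = self.freq.T
        L = self.rr.shape[0]
        if not (self.locus_id.shape[0] == self.position.shape[0] == self.effect.shape[0] == L):
            raise InvalidParameterError("architecture arrays must have equal length")
        if np.unique(self.locus_id).size != L:
            raise InvalidParameterError("locus_ids must be unique")
        if np.any(self.rr <= 1.0):
            raise InvalidParameterError("all relative risks must be > 1")
        if not np.allclose(self.effect, np.log(self.rr), atol=1e-12, rtol=0.0):
            raise InvalidParameterError("effect must equal ln(rr) to machine precision")
        if np.any(np.diff(self.position) <= 0.0):
            raise InvalidParameterError("positions must be strictly increasing")
        if np.any(self.freq < 0.0) or np.any(self.freq > 1.0):
            raise InvalidParameterError("allele frequencies must lie in [0,1]")
        if not self.lineage:
            self.lineage = self.fingerprint()

    # ------------------------------------------------------------------ #

    @property
    def n_loci(self) -> int:
        return int(self.rr.shape[0])

    @property
    def n_populations(self) -> int:
        return int(self.freq.shape[1])

    def locus(self, i: int) -> RiskLocus:
        return RiskLocus(
            locus_id=int(self.locus_id[i]),
            position=float(self.position[i]),
            rr=float(self.rr[i]),
            effect=float(self.effect[i]),
            freq=self.freq[i].copy(),
        )

    def fingerprint(self) -> str:
        """Hash of the full locus table (positions, effects, frequencies)."""
        h = hashlib.sha256()
        for a in (self.position, self.effect, self.freq):
            h.update(np.ascontiguousarray(a, dtype=float).tobytes())
        return h.hexdigest()[:16]

    # -- linkage-equilibrium expectations ------------------------------ #

    def expected_mean_prs(self, pop_index: int = 1) -> float:
        """E[beta] = sum_k 2 p_k beta_k under Hardy-Weinberg."""
        p = self.freq[:, pop_index - 1]
        return float(np.sum(2.0 * p * self.effect))

    def expected_prs_variance(self, pop_index: int = 1) -> float:
        """Var[beta] = sum_k 2 p_k (1-p_k) beta_k^2 under linkage equilibrium."""
        p = self.freq[:, pop_index - 1]
        return float(np.sum(2.0 * p * (1.0 - p) * self.effect**2))

    def expected_risk_alleles(self, pop_index: int = 1) -> float:
        """Mean number of risk alleles carried per individual, 2 * sum_k p_k."""
        return float(2.0 * np.sum(self.freq[:, pop_index - 1]))

    # -- exact PRS distribution (linkage equilibrium) ------------------- #

    def prs_pmf(self, pop_index: int = 1, step: float = 0.002):
        """Exact PRS probability mass function on a regular grid.

        The PRS of a Hardy-Weinberg individual is a sum of independent
        per-locus contributions taking values {0, beta, 2 beta} with
        trinomial probabilities {(1-p)^2, 2p(1-p), p^2}; the distribution is
        computed by sequential convolution. Off-grid shifts are split
        linearly between adjacent bins, which keeps the mean exact and adds
        at most ``step^2/4`` of spurious variance per locus (negligible at
        the default step).

        Returns
        -------
        (grid, pmf) : arrays of PRS values (bin centers) and probabilities.
        """
        p = self.freq[:, pop_index - 1]
        beta = self.effect
        active = p > 0.0
        p, beta = p[active], beta[active]

        # each convolution extends support by ceil(2 beta/step) + 1 bins
        max_len = int(np.ceil(2.0 * beta.sum() / step)) + 2 * beta.size + 4
        pmf = np.zeros(max_len)
        pmf[0] = 1.0
        lo, hi = 0, 1  # live slice of pmf
        start = 0.0  # PRS value of bin 0

        for pk, bk in zip(p, beta):
            w0 = (1.0 - pk) ** 2
            w1 = 2.0 * pk * (1.0 - pk)
            w2 = pk * pk
            s1 = bk / step
            k1, f1 = int(s1), s1 - int(s1)
            k2, f2 = 2 * k1, 2.0 * f1
            if f2 >= 1.0:
                k2, f2 = k2 + 1, f2 - 1.0
            cur = pmf[lo:hi].copy()
            new_hi = hi + k2 + 2
            pmf[lo:new_hi] = 0.0
            pmf[lo : lo + cur.size] = w0 * cur
            pmf[lo + k1 : lo + k1 + cur.size] += w1 * (1.0 - f1) * cur
            pmf[lo + k1 + 1 : lo + k1 + 1 + cur.size] += w1 * f1 * cur
            pmf[lo + k2 : lo + k2 + cur.size] += w2 * (1.0 - f2) * cur
            pmf[lo + k2 + 1 : lo + k2 + 1 + cur.size] += w2 * f2 * cur
            hi = new_hi
            # trim negligible tails to keep the window narrow
            nz = np.nonzero(pmf[lo:hi] > _PMF_TRIM)[0]
            if nz.size:
                new_lo = lo + int(nz[0])
                hi = lo + int(nz[-1]) + 1
                start += (new_lo - lo) * step
                lo = new_lo

        grid = start + step * np.arange(hi - lo)
        out = pmf[lo:hi]
        return grid, out / out.sum()

    def sample_prs(self, size: int, pop_index: int = 1, rng=None, step: float = 0.002):
        """Draw PRS values from the exact linkage-equilibrium distribution."""
        rng = np.random.default_rng(rng)
        grid, pmf = self.prs_pmf(pop_index=pop_index, step=step)
        cdf = np.cumsum(pmf)
        cdf[-1] = 1.0
        idx = np.searchsorted(cdf, rng.random(size), side="left")
        return grid[idx]

    # -- serialization --------------------------------------------------- #

    def to_frame(self) -> pd.DataFrame:
        cols = {"locus_id": self.locus_id, "position": self.position, "rr": self.rr, "effect": self.effect}
        for j in range(self.n_populations):
            cols[f"freq_pop{j + 1}"] = self.freq[:, j]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        buf = io.StringIO()
        buf.write(f"# heritability_target={self.heritability_target}\n")
        buf.write(f"# mean_rr={self.mean_rr}\n")
        buf.write(f"# lineage={self.lineage}\n")
        self.to_frame().to_csv(buf, index=False)
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_csv(cls, path) -> "Architecture":
        meta = {}
        with open(path) as fh:
            lines = fh.readlines()
        body = []
        for ln in lines:
            if ln.startswith("#"):
                k, v = ln[1:].strip().split("=", 1)
                meta[k.strip()] = v.strip()
            else:
                body.append(ln)
        df = pd.read_csv(io.StringIO("".join(body)))
        fcols = [c for c in df.columns if c.startswith("freq_pop")]
        return cls(
            locus_id=df["locus_id"].to_numpy(),
            position=df["position"].to_numpy(),
            rr=df["rr"].to_numpy(),
            effect=df["effect"].to_numpy(),
            freq=df[fcols].to_numpy(),
            heritability_target=float(meta["heritability_target"]),
            mean_rr=float(meta["mean_rr"]),
            lineage=meta.get("lineage", ""),
        )


# ---------------------------------------------------------------------- #


def _unique_sorted_positions(n: int, rng: np.random.Generator) -> np.ndarray:
    pos = np.sort(rng.random(n))
    while np.any(np.diff(pos) <= 0.0):  # pragma: no cover - float collisions
        pos = np.sort(rng.random(n))
    return pos


def build_architecture(
    heritability: float,
    mean_rr: float = 1.1,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed=None,
    rr_halfwidth: float = RR_HALFWIDTH,
) -> Architecture:
    """Build a single-population common low-effect architecture.

    Relative risks are drawn uniformly on ``mean_rr +/- rr_halfwidth`` and
    risk-allele frequencies uniformly on ``maf_range``. Loci are appended
    until the cumulative linkage-equilibrium PRS variance
    ``sum 2 p (1-p) beta^2`` reaches the target ``V(h2)``, which calibrates
    the locus count to the heritability (final overshoot is at most one
    locus, well inside 1%).
    """
    if not 0.0 < heritability < 1.0:
        raise InvalidParameterError(f"heritability must be in (0,1), got {heritability}")
    if mean_rr <= 1.0:
        raise InvalidParameterError(f"mean_rr must be > 1, got {mean_rr}")
    lo, hi = maf_range
    if not (0.0 < lo < hi < 1.0):
        raise InvalidParameterError(
            f"maf_range must satisfy 0 < lo < hi < 1 (monomorphic loci carry no variance), got {maf_range}"
        )
    if mean_rr - rr_halfwidth <= 1.0:
        raise InvalidParameterError("mean_rr - rr_halfwidth must exceed 1")

    rng = np.random.default_rng(seed)
    target_v = liability_prs_variance(heritability)
    per_locus = _mean_2pq(lo, hi) * _mean_log_rr_sq(mean_rr - rr_halfwidth, mean_rr + rr_halfwidth)
    n_guess = int(target_v / per_locus * 1.2) + 32

    rr = np.empty(0)
    p = np.empty(0)
    while True:
        rr = np.concatenate([rr, rng.uniform(mean_rr - rr_halfwidth, mean_rr + rr_halfwidth, n_guess)])
        p = np.concatenate([p, rng.uniform(lo, hi, n_guess)])
        cum = np.cumsum(2.0 * p * (1.0 - p) * np.log(rr) ** 2)
        if cum[-1] >= target_v:
            n = int(np.searchsorted(cum, target_v)) + 1
            break
    rr, p = rr[:n], p[:n]

    pos = _unique_sorted_positions(n, rng)
    return Architecture(
        locus_id=np.arange(n),
        position=pos,
        rr=rr,
        effect=np.log(rr),
        freq=p[:, None],
        heritability_target=heritability,
        mean_rr=mean_rr,
    )


def split_differing(arch: Architecture, fraction_diff: float, seed=None) -> Architecture:
    """Split a shared architecture into two populations with partially
    disjoint causal-SNP sets of equal liability.

    A randomly chosen subset of loci contributing ``fraction_diff`` of the
    total mean PRS becomes population-1-specific (frequency zero in
    population 2); an effect-matched twin of each such locus (same rr and
    frequency, new genome position) is appended as population-2-specific.
    Both populations therefore have identical expected mean PRS and expected
    PRS variance, while ``fraction_diff`` of each population's mean PRS is
    carried by loci absent from the other population.
    """
    if not 0.0 <= fraction_diff <= 1.0:
        raise InvalidParameterError(f"fraction_diff must be in [0,1], got {fraction_diff}")
    if arch.n_populations != 1:
        raise InvalidParameterError("split_differing expects a single-population architecture")

    rng = np.random.default_rng(seed)
    p = arch.freq[:, 0]
    contrib = 2.0 * p * arch.effect
    total = contrib.sum()

    perm = rng.permutation(arch.n_loci)
    cum = np.cumsum(contrib[perm])
    # subset size minimizing |subset mean PRS - fraction_diff * total|
    k = int(np.argmin(np.abs(cum - fraction_diff * total)) + 1) if fraction_diff > 0 else 0
    if fraction_diff == 1.0:
        k = arch.n_loci
    spec = np.zeros(arch.n_loci, dtype=bool)
    if k:
        spec[perm[:k]] = True

    freq2 = np.column_stack([p, p.copy()])
    freq2[spec, 1] = 0.0  # specific loci absent from population 2

    # effect-matched twins owned by population 2
    twin_rr = arch.rr[spec]
    twin_eff = arch.effect[spec]
    twin_freq = np.column_stack([np.zeros(k), p[spec]])
    twin_pos = rng.random(k)
    twin_ids = arch.locus_id.max() + 1 + np.arange(k) if k else np.empty(0, dtype=np.int64)

    locus_id = np.concatenate([arch.locus_id, twin_ids])
    position = np.concatenate([arch.position, twin_pos])
    rr = np.concatenate([arch.rr, twin_rr])
    effect = np.concatenate([arch.effect, twin_eff])
    freq = np.vstack([freq2, twin_freq])

    order = np.argsort(position, kind="stable")
    return Architecture(
        locus_id=locus_id[order],
        position=position[order],
        rr=rr[order],
        effect=effect[order],
        freq=freq[order],
        heritability_target=arch.heritability_target,
        mean_rr=arch.mean_rr,
        lineage=arch.lineage,
    )


def add_high_risk_subset(
    arch: Architecture,
    delta_prs: float,
    common_freq: float = 0.5,
    rare_freq: float = 0.001,
    seed=None,
    max_extra_loci: int = 20000,
) -> Architecture:
    """Append a subset of loci common in population 2 and rare in
    population 1, raising population 2's expected mean PRS by ``delta_prs``.

    Appended loci carry the architecture's mean relative risk; the last
    locus's effect is trimmed so that the expected mean-PRS difference
    ``sum 2 (p2 - p1) beta`` equals ``delta_prs`` exactly. For
    ``delta_prs = ln 10`` on a mean-RR-1.1 architecture this appends ~25
    loci.
    """
    if delta_prs < 0.0:
        raise InvalidParameterError(f"delta_prs must be >= 0, got {delta_prs}")
    if not rare_freq < common_freq:
        raise InvalidParameterError("rare_freq must be below common_freq")

    freq = arch.freq
    if freq.shape[1] == 1:
        freq = np.column_stack([freq[:, 0], freq[:, 0]])
    elif freq.shape[1] != 2:
        raise InvalidParameterError("architecture must have one or two populations")

    if delta_prs == 0.0:
        return Architecture(
            locus_id=arch.locus_id.copy(),
            position=arch.position.copy(),
            rr=arch.rr.copy(),
            effect=arch.effect.copy(),
            freq=freq,
            heritability_target=arch.heritability_target,
            mean_rr=arch.mean_rr,
            lineage=arch.lineage,
        )

    rng = np.random.default_rng(seed)
    beta = np.log(arch.mean_rr)
    per_locus = 2.0 * (common_freq - rare_freq) * beta
    n_full = int(delta_prs // per_locus)
    remainder = delta_prs - n_full * per_locus

    effs = [beta] * n_full
    if remainder > 1e-12 * max(delta_prs, 1.0):
        effs.append(remainder / (2.0 * (common_freq - rare_freq)))
    n_extra = len(effs)
    if n_extra > max_extra_loci:
        raise ConfigurationError(
            f"delta_prs={delta_prs} needs {n_extra} extra loci, exceeding max_extra_loci={max_extra_loci}"
        )

    new_eff = np.asarray(effs)
    new_rr = np.exp(new_eff)
    new_pos = rng.random(n_extra)
    new_ids = arch.locus_id.max() + 1 + np.arange(n_extra)
    new_freq = np.column_stack([np.full(n_extra, rare_freq), np.full(n_extra, common_freq)])

    locus_id = np.concatenate([arch.locus_id, new_ids])
    position = np.concatenate([arch.position, new_pos])
    rr = np.concatenate([arch.rr, new_rr])
    effect = np.concatenate([arch.effect, new_eff])
    freq = np.vstack([freq, new_freq])

    order = np.argsort(position, kind="stable")
    return Architecture(
        locus_id=locus_id[order],
        position=position[order],
        rr=rr[order],
        effect=effect[order],
        freq=freq[order],
        heritability_target=arch.heritability_target,
        mean_rr=arch.mean_rr,
        lineage=arch.lineage,
    )
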