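"""Empirical mapping from PRS to individual disease probability.

For a disease of prevalence K, diagnosed individuals are drawn from a large
calibration sample *without replacement with probability proportional to the
individual relative risk* ``R_i = exp(beta_i)`` until ``n = N K`` are drawn.
Sorting the whole sample into narrow PRS bands of width ``delta_beta`` and
taking, per band, the fraction of its members that were diagnosed yields the
band-wise probability ``pi(beta, beta + delta_beta)``. Averaged over
replicates and smoothed isotonically, the resulting curve is logistic-shaped
(it reproduces the liability-threshold model's logistic distribution of
probabilities) and re-applying it to the calibration population returns K.

The weighted sampling without replacement is realized with exponential-race
keys (``E_i / R_i`` with ``E_i ~ Exp(1)``, keep the n smallest), which is
identical in distribution to successive draws proportional to the remaining
weights.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from sklearn.isotonic import IsotonicRegression
from sklearn.linear_model import LogisticRegression

from .architecture import Architecture
from .errors import (
    CalibrationError,
    FingerprintMismatchError,
    InvalidParameterError,
    StructuralError,
)
from .population import Population

__all__ = [
    "MappingTable",
    "weighted_sample_without_replacement",
    "calibrate_mapping",
    "apply_mapping",
    "save_mapping",
    "load_mapping",
]

#: prevalences above this trigger a model-domain warning (the approach is
#: intended for diseases with single-digit prevalence and below)
HIGH_PREVALENCE_WARNING = 0.10


@dataclass
class MappingTable:
    """Calibrated band-wise PRS -> disease-probability table.

    band_edges : (B+1,) ascending PRS grid of width delta_beta.
    band_prob : (B,) probability of disease per band (isotonic-smoothed).
    band_n : (B,) calibration individuals per band (summed over replicates).
    prevalence : the K the table was calibrated for.
    logit_slope, logit_intercept : logistic fit used to extrapolate beyond
        the calibrated PRS range (clamped to [0, 1]).
    arch_lineage : lineage token of the architecture family the calibration
        sample came from.
    """

    band_edges: np.ndarray
    band_prob: np.ndarray
    band_n: np.ndarray
    prevalence: float
    delta_beta: float
    n_reference: int
    reps: int
    logit_slope: float
    logit_intercept: float
    arch_lineage: str = ""

    def probability(self, beta: np.ndarray) -> np.ndarray:
        """pi(beta): band value in range, clamped logistic outside."""
        beta = np.asarray(beta, dtype=float)
        idx = np.searchsorted(self.band_edges, beta, side="right") - 1
        inside = (idx >= 0) & (idx < self.band_prob.shape[0])
        out = np.empty(beta.shape)
        out[inside] = self.band_prob[np.clip(idx[inside], 0, None)]
        if np.any(~inside):
            out[~inside] = expit(self.logit_slope * beta[~inside] + self.logit_intercept)
        return np.clip(out, 0.0, 1.0)


def weighted_sample_without_replacement(
    log_weights: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of n items drawn without replacement, proportional to weights.

    Exponential-race keying: item i gets key ``E_i / w_i``; the n smallest
    keys win. Computed in log space for numerical safety with large PRS.
    """
    lw = np.asarray(log_weights, dtype=float)
    if not 0 < n <= lw.shape[0]:
        raise InvalidParameterError(f"cannot draw {n} of {lw.shape[0]} items")
    keys = np.log(rng.exponential(size=lw.shape[0])) - lw
    if n == lw.shape[0]:
        return np.arange(lw.shape[0])
    return np.argpartition(keys, n)[:n]


def calibrate_mapping(
    prs_sample: np.ndarray,
    K: float,
    delta_beta: float = 0.1,
    reps: int = 5,
    seed=None,
    arch: Architecture | None = None,
) -> MappingTable:
    """Calibrate the PRS -> disease-probability mapping for prevalence K.

    Per replicate, ``n = round(N K)`` distinct individuals are diagnosed by
    weighted sampling without replacement with weight ``exp(beta_i)``; band
    probabilities are diagnosed/members per PRS band of width ``delta_beta``,
    averaged over replicates. Isotonic regression (count-weighted, hence
    conserving the overall diagnosis rate) smooths the bands; a
    count-weighted logistic fit provides extrapolation beyond the sampled
    PRS range.
    """
    if not 0.0 < K < 1.0:
        raise InvalidParameterError(f"prevalence K must be in (0,1), got {K}")
    if delta_beta <= 0.0:
        raise InvalidParameterError(f"delta_beta must be positive, got {delta_beta}")
    if reps < 1:
        raise InvalidParameterError("at least one calibration replicate is required")
    if K > HIGH_PREVALENCE_WARNING:
        warnings.warn(
            f"prevalence K={K:.3g} is high; the PRS-probability mapping is intended "
            "for diseases with single-digit prevalence and below",
            stacklevel=2,
        )
    beta = np.asarray(prs_sample, dtype=float)
    N = beta.shape[0]
    n = int(round(N * K))
    if n < 1:
        raise CalibrationError(f"N*K = {N * K:.3g} < 1: calibration sample too small for K={K}")

    rng = np.random.default_rng(seed)
    lo = np.floor(beta.min() / delta_beta) * delta_beta
    hi = np.ceil(beta.max() / delta_beta) * delta_beta
    if hi <= lo:  # degenerate sample spread: keep at least one band
        hi = lo + delta_beta
    edges = np.arange(lo, hi + delta_beta * 0.5, delta_beta)
    if edges[-1] <= beta.max():
        edges = np.append(edges, edges[-1] + delta_beta)
    members, _ = np.histogram(beta, bins=edges)

    diagnosed = np.zeros(members.shape[0], dtype=np.int64)
    for _ in range(reps):
        idx = weighted_sample_without_replacement(beta, n, rng)
        d, _ = np.histogram(beta[idx], bins=edges)
        diagnosed += d

    total = members * reps
    occupied = total > 0
    centers = 0.5 * (edges[:-1] + edges[1:])
    pi_raw = np.zeros(members.shape[0])
    pi_raw[occupied] = diagnosed[occupied] / total[occupied]

    # isotonic smoothing; count weights preserve the overall diagnosis rate
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    pi_iso = np.empty_like(pi_raw)
    pi_iso[occupied] = iso.fit_transform(
        centers[occupied], pi_raw[occupied], sample_weight=total[occupied]
    )
    if np.any(~occupied):  # interior gaps: monotone interpolation of the fit
        pi_iso[~occupied] = np.interp(centers[~occupied], centers[occupied], pi_iso[occupied])

    slope, intercept = _fit_logistic(centers[occupied], diagnosed[occupied], total[occupied], K)

    return MappingTable(
        band_edges=edges,
        band_prob=pi_iso,
        band_n=total,
        prevalence=K,
        delta_beta=delta_beta,
        n_reference=N,
        reps=reps,
        logit_slope=slope,
        logit_intercept=intercept,
        arch_lineage=arch.lineage if arch is not None else "",
    )


def _fit_logistic(centers, successes, totals, K) -> tuple[float, float]:
    """Count-weighted logistic fit pi(beta) = expit(a*beta + b)."""
    X = np.concatenate([centers, centers])[:, None]
    y = np.concatenate([np.ones_like(centers), np.zeros_like(centers)])
    w = np.concatenate([successes, totals - successes]).astype(float)
    keep = w > 0
    if np.unique(y[keep]).size < 2:  # degenerate: all or none diagnosed
        return 0.0, float(logit(np.clip(K, 1e-12, 1 - 1e-12)))
    clf = LogisticRegression(C=1e10, solver="lbfgs", max_iter=1000, tol=1e-8)
    clf.fit(X[keep], y[keep], sample_weight=w[keep])
    return float(clf.coef_[0, 0]), float(clf.intercept_[0])


def apply_mapping(
    mapping: MappingTable,
    pop: "Population | np.ndarray",
    mode: str = "expected",
    seed=None,
    mean_shift: float = 0.0,
):
    """Population prevalence under a calibrated mapping.

    ``expected`` mode returns ``mean(pi(beta_i))``; ``sampled`` mode draws
    Bernoulli(pi(beta_i)) diagnosis flags and returns ``(prevalence, flags)``.
    ``mean_shift`` is added to every PRS before lookup (used for
    drift-adjusted prevalence estimates). PRS values beyond the calibrated
    range use the clamped logistic extrapolation, never an error.
    """
    if isinstance(pop, Population):
        if mapping.arch_lineage and pop.arch.lineage != mapping.arch_lineage:
            raise StructuralError(
                "population architecture lineage does not match the mapping calibration"
            )
        beta = pop.prs_values()
    else:
        beta = np.asarray(pop, dtype=float)
    pi = mapping.probability(beta + mean_shift)
    if mode == "expected":
        return float(pi.mean())
    if mode == "sampled":
        rng = np.random.default_rng(seed)
        flags = rng.random(pi.shape[0]) < pi
        return float(flags.mean()), flags
    raise InvalidParameterError(f"mode must be 'expected' or 'sampled', got {mode!r}")


def expected_prevalence_from_pmf(mapping: MappingTable, grid: np.ndarray, pmf: np.ndarray, mean_shift: float = 0.0) -> float:
    """Expected-mode prevalence of an analytic PRS distribution."""
    return float(np.sum(pmf * mapping.probability(grid + mean_shift)))


def save_mapping(mapping: MappingTable, path) -> None:
    """Write the mapping as CSV (band_lo, band_hi, pi, n_in_band) with a
    metadata header; the round-trip is bit-stable."""
    buf = io.StringIO()
    for k in ("prevalence", "delta_beta", "n_reference", "reps", "logit_slope", "logit_intercept"):
        buf.write(f"# {k}={getattr(mapping, k)!r}\n")  # repr round-trips floats exactly
    buf.write(f"# arch_lineage={mapping.arch_lineage}\n")
    df = pd.DataFrame(
        {
            "band_lo": mapping.band_edges[:-1],
            "band_hi": mapping.band_edges[1:],
            "pi": mapping.band_prob,
            "n_in_band": mapping.band_n,
        }
    )
    df.to_csv(buf, index=False, float_format="%.17g")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


def load_mapping(path, arch: Architecture | None = None) -> MappingTable:
    """Load a saved mapping; refuses if ``arch`` has a different lineage."""
    meta = {}
    body = []
    with open(path) as fh:
        for ln in fh:
            if ln.startswith("#"):
                k, v = ln[1:].strip().split("=", 1)
                meta[k.strip()] = v.strip()
            else:
                body.append(ln)
    df = pd.read_csv(io.StringIO("".join(body)), float_precision="round_trip")
    lineage = meta.get("arch_lineage", "")
    if arch is not None and lineage and arch.lineage != lineage:
        raise FingerprintMismatchError(
            f"mapping was calibrated for lineage {lineage}, architecture has {arch.lineage}"
        )
    edges = np.append(df["band_lo"].to_numpy(), df["band_hi"].to_numpy()[-1])
    return MappingTable(
        band_edges=edges,
        band_prob=df["pi"].to_numpy(),
        band_n=df["n_in_band"].to_numpy(),
        prevalence=float(meta["prevalence"]),
        delta_beta=float(meta["delta_beta"]),
        n_reference=int(meta["n_reference"]),
        reps=int(meta["reps"]),
        logit_slope=float(meta["logit_slope"]),
        logit_intercept=float(meta["logit_intercept"]),
        arch_lineage=lineage,
    )
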