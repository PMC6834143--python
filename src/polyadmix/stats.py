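"""Per-generation population summary statistics.

Prevalence (expected mode by default), PRS moments, Hudson's Fst with the
sample-size-corrected numerator (genome-wide value as the ratio of averages,
as recommended for this estimator), and the mean absolute allele-frequency
difference (AFD).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .architecture import Architecture
from .errors import InvalidParameterError
from .mapping import MappingTable, apply_mapping
from .population import Population

__all__ = [
    "hudson_fst",
    "afd",
    "expected_prs_variance",
    "generation_stats",
    "aggregate_replicates",
]


def hudson_fst(freqs1, freqs2, n1: int, n2: int):
    """Hudson's Fst between two populations from per-locus allele frequencies.

    Per locus the numerator is ``(p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)``
    and the denominator ``p1(1-p2) + p2(1-p1)``; the genome-wide estimate is
    the ratio of sums. Loci monomorphic in both populations (zero
    denominator) are excluded.

    Returns (per-locus array with NaN at excluded loci, genome-wide value).
    """
    if n1 < 2 or n2 < 2:
        raise InvalidParameterError("Hudson Fst requires sample sizes >= 2")
    p1 = np.asarray(freqs1, dtype=float)
    p2 = np.asarray(freqs2, dtype=float)
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = den > 0
    per_locus = np.full(p1.shape, np.nan)
    per_locus[ok] = num[ok] / den[ok]
    overall = float(num[ok].sum() / den[ok].sum()) if ok.any() else np.nan
    return per_locus, overall


def afd(freqs1, freqs2) -> float:
    """Mean absolute allele-frequency difference over loci."""
    p1 = np.asarray(freqs1, dtype=float)
    p2 = np.asarray(freqs2, dtype=float)
    return float(np.mean(np.abs(p1 - p2)))


def expected_prs_variance(arch: Architecture, freqs=None, pop_index: int = 1) -> float:
    """Linkage-equilibrium additive PRS variance sum 2 p (1-p) beta^2.

    ``freqs`` overrides the architecture's frequency column (e.g. realized
    frequencies of an evolving population)."""
    p = arch.freq[:, pop_index - 1] if freqs is None else np.asarray(freqs, dtype=float)
    return float(np.sum(2.0 * p * (1.0 - p) * arch.effect**2))


def generation_stats(
    pop1: Population,
    pop2: Population,
    mapping: MappingTable | None,
    generation: int,
    theory_means: tuple[float, float] | None = None,
) -> list[dict]:
    """Summary rows (population 1, population 2, combined) for one generation.

    If ``theory_means`` (analytic Eq-1 mean-PRS trajectory values) is given,
    a drift-adjusted prevalence is also computed by recentring each
    population's PRS on its analytic mean before applying the mapping — a
    control variate that removes finite-population drift of the mean at
    desk-scale N (the modeled populations are nominally large enough for
    drift to be imperceptible).
    """
    f1 = pop1.allele_frequencies()
    f2 = pop2.allele_frequencies()
    _, fst = hudson_fst(f1, f2, 2 * pop1.size, 2 * pop2.size)
    afd_val = afd(f1, f2)

    rows = []
    prs = {1: pop1.prs_values(), 2: pop2.prs_values()}
    pops = {1: pop1, 2: pop2}
    for label in (1, 2):
        beta = prs[label]
        row = {
            "generation": generation,
            "pop": str(label),
            "N": pops[label].size,
            "mean_prs": float(beta.mean()),
            "var_prs": float(beta.var(ddof=1)),
            "fst": fst,
            "afd": afd_val,
        }
        if mapping is not None:
            row["prevalence"] = apply_mapping(mapping, beta)
            if theory_means is not None:
                shift = theory_means[label - 1] - row["mean_prs"]
                row["prevalence_adj"] = apply_mapping(mapping, beta, mean_shift=shift)
        rows.append(row)

    both = np.concatenate([prs[1], prs[2]])
    row = {
        "generation": generation,
        "pop": "combined",
        "N": pop1.size + pop2.size,
        "mean_prs": float(both.mean()),
        "var_prs": float(both.var(ddof=1)),
        "fst": fst,
        "afd": afd_val,
    }
    if mapping is not None:
        w = np.array([pop1.size, pop2.size], dtype=float)
        row["prevalence"] = float(np.average([rows[0]["prevalence"], rows[1]["prevalence"]], weights=w))
        if theory_means is not None:
            row["prevalence_adj"] = float(
                np.average([rows[0]["prevalence_adj"], rows[1]["prevalence_adj"]], weights=w)
            )
    rows.append(row)
    return rows


def aggregate_replicates(stats: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD across replicates for every (generation, pop) statistic.

    With a single replicate the SD columns are NaN (empty).
    """
    value_cols = [
        c for c in stats.columns if c not in ("replicate", "generation", "pop", "N")
    ]
    g = stats.groupby(["generation", "pop"], sort=True)
    mean = g[value_cols].mean().add_suffix("_mean")
    sd = g[value_cols].std(ddof=1).add_suffix("_sd")
    n = g.size().rename("replicates")
    return pd.concat([mean, sd, n], axis=1).reset_index()
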