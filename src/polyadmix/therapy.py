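"""Preventive germline editing of risk alleles.

Editing turns carried risk alleles to the neutral (non-risk) state, one
allele at a time, until the cumulative removed effect reaches a per-individual
PRS improvement target. Two scenario modes are supported: ``single_shot``
(each treated individual improved by a fixed amount, once) and
``maintenance`` (per-generation top-up edits holding the treated population's
mean PRS at a configured level). Because Hardy-Weinberg equilibrium is
restored after one generation of random mating, any allocation of the same
total removed effect across treated individuals yields the same
next-generation population mean PRS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .architecture import Architecture
from .errors import InvalidParameterError
from .population import Population

__all__ = ["TherapyPlan", "edit_individual", "apply_therapy", "plan_edits"]


@dataclass
class TherapyPlan:
    """Germline-editing plan for population 1.

    mode : 'single_shot' edits every treated individual by
        ``target_delta_prs`` once; 'maintenance' holds the population mean
        PRS at ``initial mean + target_delta_prs`` with per-generation edits.
    target_delta_prs : PRS improvement, <= 0 (e.g. -2.30 for a 10-fold
        relative-risk reduction).
    coverage : fraction of the population treated per generation.
    selection_policy : 'uniform_random' (default; alleles edited in random
        order) or 'largest_effect_first'.
    locus_ids : optional explicit set of editable loci.
    start_generation : first generation the plan acts on.
    """

    mode: str = "single_shot"
    target_delta_prs: float = -2.302585092994046
    coverage: float = 1.0
    selection_policy: str = "uniform_random"
    locus_ids: list[int] | None = None
    start_generation: int = 1

    def __post_init__(self):
        if self.mode not in ("single_shot", "maintenance"):
            raise InvalidParameterError(f"unknown therapy mode {self.mode!r}")
        if self.target_delta_prs > 0.0:
            raise InvalidParameterError("target_delta_prs must be <= 0 (an improvement)")
        if not 0.0 < self.coverage <= 1.0:
            raise InvalidParameterError(f"coverage must be in (0,1], got {self.coverage}")
        if self.selection_policy not in ("uniform_random", "largest_effect_first"):
            raise InvalidParameterError(f"unknown selection policy {self.selection_policy!r}")


def _editable_alleles(pop: Population, i: int, locus_mask: np.ndarray | None):
    """Carried risk-allele list for individual i as (haplotype, locus) pairs."""
    cols_a = np.flatnonzero(pop.hap_a[i])
    cols_b = np.flatnonzero(pop.hap_b[i])
    if locus_mask is not None:
        cols_a = cols_a[locus_mask[cols_a]]
        cols_b = cols_b[locus_mask[cols_b]]
    hap = np.concatenate([np.zeros(cols_a.size, dtype=np.int8), np.ones(cols_b.size, dtype=np.int8)])
    loci = np.concatenate([cols_a, cols_b])
    return hap, loci


def edit_individual(
    pop: Population,
    i: int,
    target: float,
    policy: str = "uniform_random",
    seed=None,
    locus_mask: np.ndarray | None = None,
) -> int:
    """Turn off carried risk alleles of individual ``i`` until the removed
    effect reaches ``target`` (log-RR units, >= 0); returns the edit count.

    Alleles are switched one at a time in policy order; the stop rule crosses
    the target, so the realized PRS decrease is >= target whenever enough
    risk alleles are carried (otherwise every editable allele is removed).
    """
    k, _reached = _edit(pop, i, target, policy, np.random.default_rng(seed), locus_mask)
    return k


def _edit(pop, i, target, policy, rng, locus_mask) -> tuple[int, bool]:
    """Core edit step; returns (edit count, whether the target was reached)."""
    if target < 0.0:
        raise InvalidParameterError(f"edit target must be >= 0, got {target}")
    if target == 0.0:
        return 0, True
    hap, loci = _editable_alleles(pop, i, locus_mask)
    if loci.size == 0:
        return 0, False
    eff = pop.arch.effect[loci]
    if policy == "uniform_random":
        order = rng.permutation(loci.size)
    elif policy == "largest_effect_first":
        order = np.argsort(-eff, kind="stable")
    else:
        raise InvalidParameterError(f"unknown selection policy {policy!r}")
    cum = np.cumsum(eff[order])
    reached = cum[-1] >= target - 1e-12
    k = int(np.searchsorted(cum, target - 1e-12)) + 1
    k = min(k, loci.size)
    chosen = order[:k]
    a_sel = chosen[hap[chosen] == 0]
    b_sel = chosen[hap[chosen] == 1]
    pop.hap_a[i, loci[a_sel]] = 0
    pop.hap_b[i, loci[b_sel]] = 0
    return k, reached


def apply_therapy(
    pop: Population,
    plan: TherapyPlan,
    mapping=None,
    seed=None,
    maintain_level: float | None = None,
) -> dict:
    """Apply one generation of a therapy plan to a population, in place.

    single_shot: every treated individual is edited by ``-target_delta_prs``.
    maintenance: the population mean-PRS deficit above ``maintain_level`` is
    distributed uniformly over treated individuals.

    Returns a summary dict with treated count, total and mean edits, and the
    number of individuals that ran out of editable risk alleles (shortfall).
    """
    rng = np.random.default_rng(seed)
    N = pop.size
    n_treated = max(1, int(round(plan.coverage * N)))
    treated = rng.choice(N, size=n_treated, replace=False) if n_treated < N else np.arange(N)

    locus_mask = None
    if plan.locus_ids is not None:
        locus_mask = np.isin(pop.arch.locus_id, np.asarray(plan.locus_ids))

    if plan.mode == "single_shot":
        per_target = -plan.target_delta_prs
    else:
        if maintain_level is None:
            raise InvalidParameterError("maintenance mode requires maintain_level")
        deficit = float(pop.prs_values().mean()) - maintain_level
        if deficit <= 0.0:
            return {"individuals_treated": 0, "total_edits": 0, "mean_edits": 0.0, "shortfall": 0}
        per_target = deficit * N / n_treated

    total = 0
    shortfall = 0
    for i in treated:
        k, reached = _edit(pop, int(i), per_target, plan.selection_policy, rng, locus_mask)
        total += k
        shortfall += not reached
    return {
        "individuals_treated": int(n_treated),
        "total_edits": int(total),
        "mean_edits": total / n_treated,
        "shortfall": shortfall,
    }


def plan_edits(arch: Architecture, rr_reduction: float, pop_index: int = 1) -> float:
    """Expected edits per individual to cut the relative risk ``rr_reduction``-fold.

    The expected effect of a carried risk allele is the frequency-weighted
    mean ``sum 2 p beta / sum 2 p``; the expected edit count is
    ``ln(rr_reduction)`` divided by it (~15 for a 4-fold and ~24 for a
    10-fold reduction on the mean-RR-1.1 architecture).
    """
    if rr_reduction < 1.0:
        raise InvalidParameterError(f"rr_reduction must be >= 1, got {rr_reduction}")
    if rr_reduction == 1.0:
        return 0.0
    p = arch.freq[:, pop_index - 1]
    mean_carried_effect = float(np.sum(2.0 * p * arch.effect) / np.sum(2.0 * p))
    return float(np.log(rr_reduction) / mean_carried_effect)
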