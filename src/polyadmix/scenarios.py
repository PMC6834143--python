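"""Config-driven scenario runner.

A scenario couples a genetic-architecture variant (shared, partially
differing causal-SNP sets, a high-risk frequency subset, or a named disease
preset), two populations, an admixture/recombination schedule, and an
optional germline-editing plan, and advances them through discrete
generations with replicate averaging. Outputs are long-format CSV time
series (one row per replicate x generation x population), an aggregate
table, the calibrated PRS-probability mapping, and a machine-readable run
manifest. All randomness derives from one master seed.

Generation indexing: generation 0 is initialization; generation 1 is the
first round of reproduction (within-population); admixture begins at
``blend_start`` (default 2).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from . import __version__
from .architecture import (
    Architecture,
    add_high_risk_subset,
    build_architecture,
    split_differing,
)
from .errors import CalibrationError, ConfigurationError
from .evolution import ReproductionParams, next_generation
from .mapping import (
    MappingTable,
    apply_mapping,
    calibrate_mapping,
    expected_prevalence_from_pmf,
    save_mapping,
)
from .population import init_population
from .stats import aggregate_replicates, generation_stats
from .therapy import TherapyPlan, apply_therapy

__all__ = [
    "DiseasePreset",
    "ScenarioConfig",
    "ScenarioResult",
    "DISEASE_PRESETS",
    "load_config",
    "run_scenario",
    "builtin_scenarios",
    "solve_high_risk_offset",
]

logger = logging.getLogger("polyadmix")

LN10 = float(np.log(10.0))


@dataclass(frozen=True)
class DiseasePreset:
    """A disease with contrasting prevalence between two source populations.

    The high-prevalence group is modeled as population 2 (a common-frequency
    high-risk allele subset that is rare in population 1); heritabilities and
    prevalences are the published estimates for each disease.
    """

    name: str
    heritability: float
    prevalence_low: float  # population 1 (reference)
    prevalence_high: float  # population 2


#: Dupuytren's disease, rheumatoid arthritis, lupus erythematosus
DISEASE_PRESETS = {
    "DD": DiseasePreset("DD", 0.80, 0.0025, 0.25),
    "RA": DiseasePreset("RA", 0.60, 0.0030, 0.030),
    "LE": DiseasePreset("LE", 0.44, 0.0010, 0.0035),
}


@dataclass
class ScenarioConfig:
    name: str = "scenario"
    # architecture block — at most one of fraction_diff / delta_prs / preset
    heritability: float = 0.5
    mean_rr: float = 1.1
    maf_min: float = 0.05
    maf_max: float = 0.5
    fraction_diff: float | None = None
    delta_prs: float | None = None
    preset: str | None = None
    # populations block
    size: int = 100_000
    sex_ratio: float = 0.5
    prevalence_pop1: float = 0.01
    # evolution block
    admixture: float = 1.0
    crossover_mean: float = 36.0
    generations: int = 25
    blend_start: int = 2
    # therapy block
    therapy: TherapyPlan | None = None
    # run block
    replicates: int = 10
    seed: int = 0
    out_dir: str | None = None
    mapping_samples: int = 2_000_000
    mapping_reps: int = 5
    delta_beta: float = 0.1
    drift_adjust: bool = True

    def validate(self) -> None:
        problems = []
        variants = [v is not None for v in (self.fraction_diff, self.delta_prs, self.preset)]
        if sum(variants) > 1:
            problems.append("architecture: set at most one of fraction_diff, delta_prs, preset")
        if self.preset is not None and self.preset not in DISEASE_PRESETS:
            problems.append(f"architecture.preset: unknown preset {self.preset!r} (choose from {sorted(DISEASE_PRESETS)})")
        if not 0.0 < self.heritability < 1.0:
            problems.append(f"architecture.heritability: must be in (0,1), got {self.heritability}")
        if not 0.0 < self.prevalence_pop1 < 1.0:
            problems.append(f"populations.prevalence_pop1: must be in (0,1), got {self.prevalence_pop1}")
        if self.size < 2:
            problems.append(f"populations.size: must be >= 2, got {self.size}")
        if not 0.0 <= self.admixture <= 1.0:
            problems.append(f"evolution.admixture: must be in [0,1], got {self.admixture}")
        if self.generations < 0:
            problems.append(f"evolution.generations: must be >= 0, got {self.generations}")
        if self.blend_start < 1:
            problems.append(f"evolution.blend_start: must be >= 1, got {self.blend_start}")
        if self.replicates < 1:
            problems.append(f"run.replicates: must be >= 1, got {self.replicates}")
        if problems:
            raise ConfigurationError("invalid scenario config: " + "; ".join(problems))


@dataclass
class ScenarioResult:
    config: ScenarioConfig
    arch: Architecture
    mapping: MappingTable
    stats: pd.DataFrame  # one row per replicate x generation x population
    aggregate: pd.DataFrame
    edits: pd.DataFrame | None
    manifest: dict


# ------------------------------------------------------------------ #


def load_config(path) -> ScenarioConfig:
    """Read a YAML scenario file into a validated :class:`ScenarioConfig`."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known_blocks = {"scenario", "architecture", "populations", "evolution", "therapy", "run"}
    unknown = set(raw) - known_blocks
    if unknown:
        raise ConfigurationError(f"unknown config blocks: {sorted(unknown)}")

    kw: dict = {}
    if "scenario" in raw:
        kw["name"] = str(raw["scenario"])

    def take(block: str, mapping: dict[str, str]):
        blk = raw.get(block) or {}
        unknown = set(blk) - set(mapping)
        if unknown:
            raise ConfigurationError(f"unknown keys in {block} block: {sorted(unknown)}")
        for src, dst in mapping.items():
            if src in blk:
                kw[dst] = blk[src]

    take("architecture", {
        "heritability": "heritability", "mean_rr": "mean_rr", "maf_min": "maf_min",
        "maf_max": "maf_max", "fraction_diff": "fraction_diff", "delta_prs": "delta_prs",
        "preset": "preset",
    })
    take("populations", {
        "size": "size", "sex_ratio": "sex_ratio", "prevalence_pop1": "prevalence_pop1",
    })
    take("evolution", {
        "admixture": "admixture", "crossover_mean": "crossover_mean",
        "generations": "generations", "blend_start": "blend_start",
    })
    take("run", {
        "replicates": "replicates", "seed": "seed", "out_dir": "out_dir",
        "mapping_samples": "mapping_samples", "mapping_reps": "mapping_reps",
        "delta_beta": "delta_beta", "drift_adjust": "drift_adjust",
    })
    if raw.get("therapy"):
        blk = dict(raw["therapy"])
        allowed = {"mode", "target_prs", "coverage", "policy", "locus_ids", "start_generation"}
        unknown = set(blk) - allowed
        if unknown:
            raise ConfigurationError(f"unknown keys in therapy block: {sorted(unknown)}")
        kw["therapy"] = TherapyPlan(
            mode=blk.get("mode", "single_shot"),
            target_delta_prs=float(blk.get("target_prs", -LN10)),
            coverage=float(blk.get("coverage", 1.0)),
            selection_policy=blk.get("policy", "uniform_random"),
            locus_ids=blk.get("locus_ids"),
            start_generation=int(blk.get("start_generation", 1)),
        )
    cfg = ScenarioConfig(**kw)
    cfg.validate()
    return cfg


# ------------------------------------------------------------------ #


def _subset_pmf(delta_prs: float, mean_rr: float, common_freq: float, rare_freq: float,
                pop_index: int, step: float):
    """PMF of the high-risk subset's PRS contribution (analytic construction
    mirroring :func:`add_high_risk_subset`)."""
    beta = np.log(mean_rr)
    per_locus = 2.0 * (common_freq - rare_freq) * beta
    n_full = int(delta_prs // per_locus)
    remainder = delta_prs - n_full * per_locus
    effs = [beta] * n_full
    if remainder > 1e-12 * max(delta_prs, 1.0):
        effs.append(remainder / (2.0 * (common_freq - rare_freq)))
    if not effs:
        return np.array([0.0]), np.array([1.0])
    p = common_freq if pop_index == 2 else rare_freq
    arch = Architecture(
        locus_id=np.arange(len(effs)),
        position=np.linspace(0.1, 0.9, len(effs)),
        rr=np.exp(effs),
        effect=np.asarray(effs),
        freq=np.full((len(effs), 1), p),
        heritability_target=0.5,
        mean_rr=mean_rr,
    )
    return arch.prs_pmf(pop_index=1, step=step)


def solve_high_risk_offset(
    base: Architecture,
    mapping: MappingTable,
    prevalence_target: float,
    common_freq: float = 0.5,
    rare_freq: float = 0.001,
    step: float = 0.002,
) -> float:
    """Mean-PRS offset delta such that a population carrying the high-risk
    subset has expected prevalence ``prevalence_target`` under ``mapping``.

    Solved on the exact linkage-equilibrium PRS distribution (base
    architecture convolved with the subset's contribution).
    """
    grid, pmf = base.prs_pmf(pop_index=1, step=step)

    def prevalence_at(delta: float) -> float:
        if delta <= 0.0:
            return expected_prevalence_from_pmf(mapping, grid, pmf)
        sg, sp = _subset_pmf(delta, base.mean_rr, common_freq, rare_freq, 2, step)
        full = np.convolve(pmf, sp)
        fgrid = grid[0] + sg[0] + step * np.arange(full.size)
        return expected_prevalence_from_pmf(mapping, fgrid, full)

    f0 = prevalence_at(0.0)
    if prevalence_target <= f0:
        raise CalibrationError(
            f"target prevalence {prevalence_target} not above baseline {f0:.4g}"
        )
    hi = np.log(prevalence_target / f0) + 1.0
    while prevalence_at(hi) < prevalence_target:
        hi *= 1.6
        if hi > 60.0:
            raise CalibrationError("could not bracket the required PRS offset")
    return float(brentq(lambda d: prevalence_at(d) - prevalence_target, 1e-9, hi, xtol=1e-4))


def _build_architecture_for(cfg: ScenarioConfig, ss: np.random.SeedSequence):
    """Architecture variant + mapping for a scenario; returns (arch, mapping)."""
    s_arch, s_var, s_map, s_samp = ss.spawn(4)
    h2 = cfg.heritability
    K1 = cfg.prevalence_pop1
    if cfg.preset is not None:
        pre = DISEASE_PRESETS[cfg.preset]
        h2 = pre.heritability
        K1 = pre.prevalence_low
    base = build_architecture(h2, cfg.mean_rr, (cfg.maf_min, cfg.maf_max), seed=s_arch)

    sample = base.sample_prs(cfg.mapping_samples, pop_index=1, rng=np.random.default_rng(s_samp))
    mapping = calibrate_mapping(
        sample, K1, delta_beta=cfg.delta_beta, reps=cfg.mapping_reps, seed=s_map, arch=base
    )

    if cfg.fraction_diff is not None:
        arch = split_differing(base, cfg.fraction_diff, seed=s_var)
    elif cfg.delta_prs is not None:
        arch = add_high_risk_subset(base, cfg.delta_prs, seed=s_var)
    elif cfg.preset is not None:
        pre = DISEASE_PRESETS[cfg.preset]
        delta = solve_high_risk_offset(base, mapping, pre.prevalence_high)
        arch = add_high_risk_subset(base, delta, seed=s_var)
    else:
        arch = add_high_risk_subset(base, 0.0, seed=s_var)  # two identical columns
    return arch, mapping, K1


def _run_replicate(cfg: ScenarioConfig, arch: Architecture, mapping: MappingTable, rep: int, ss):
    rng = np.random.default_rng(ss)
    pop1 = init_population(cfg.size, arch, 1, cfg.sex_ratio, seed=rng)
    pop2 = init_population(cfg.size, arch, 2, cfg.sex_ratio, seed=rng)

    mu = [arch.expected_mean_prs(1), arch.expected_mean_prs(2)]
    maintain_level = None
    if cfg.therapy is not None and cfg.therapy.mode == "maintenance":
        maintain_level = mu[0] + cfg.therapy.target_delta_prs

    theory = tuple(mu) if cfg.drift_adjust else None
    rows = [dict(r, replicate=rep) for r in generation_stats(pop1, pop2, mapping, 0, theory)]
    edit_rows = []

    for g in range(1, cfg.generations + 1):
        t0 = time.perf_counter()
        m_g = cfg.admixture if g >= cfg.blend_start else 0.0
        params = ReproductionParams(
            admixture=m_g,
            crossover_mean=cfg.crossover_mean,
            sizes=(cfg.size, cfg.size),
            sex_ratio=cfg.sex_ratio,
        )
        pop1, pop2 = next_generation((pop1, pop2), params, seed=rng)
        # analytic mean-PRS recurrence (mirrors the simulation in expectation)
        gap = mu[1] - mu[0]
        mu = [mu[0] + 0.5 * m_g * gap, mu[1] - 0.5 * m_g * gap]

        if cfg.therapy is not None and g >= cfg.therapy.start_generation:
            plan = cfg.therapy
            acts = plan.mode == "maintenance" or g == plan.start_generation
            if acts:
                summary = apply_therapy(pop1, plan, mapping, seed=rng, maintain_level=maintain_level)
                edit_rows.append(dict(summary, generation=g, replicate=rep))
                # re-anchor the analytic mean on the realized post-edit mean
                # (absorbs the per-individual stop-rule overshoot)
                mu[0] = float(pop1.prs_values().mean())

        theory = tuple(mu) if cfg.drift_adjust else None
        rows.extend(dict(r, replicate=rep) for r in generation_stats(pop1, pop2, mapping, g, theory))
        logger.info(
            "%s rep %d gen %d: m=%.2f mean_prs=(%.3f, %.3f) prevalence=%.5f [%.2fs]",
            cfg.name, rep, g, m_g, rows[-3]["mean_prs"], rows[-2]["mean_prs"],
            rows[-1].get("prevalence", float("nan")), time.perf_counter() - t0,
        )
    return rows, edit_rows


def run_scenario(cfg: ScenarioConfig) -> ScenarioResult:
    """Run a scenario with replicates; deterministic given the master seed.

    Writes per-generation statistics, edit counts (if a therapy plan is
    configured), the calibrated mapping and a run manifest to
    ``cfg.out_dir`` when set; always returns the in-memory tables.
    """
    cfg.validate()
    ss = np.random.SeedSequence(cfg.seed)
    ss_build, ss_reps = ss.spawn(2)
    arch, mapping, K1 = _build_architecture_for(cfg, ss_build)

    all_rows: list[dict] = []
    all_edits: list[dict] = []
    for rep, child in enumerate(ss_reps.spawn(cfg.replicates)):
        rows, edit_rows = _run_replicate(cfg, arch, mapping, rep, child)
        all_rows.extend(rows)
        all_edits.extend(edit_rows)

    lead = ["replicate", "generation", "pop", "N", "mean_prs", "var_prs", "prevalence"]
    stats = pd.DataFrame(all_rows)
    stats = stats[[c for c in lead if c in stats.columns] + [c for c in stats.columns if c not in lead]]
    agg = aggregate_replicates(stats)
    edits = pd.DataFrame(all_edits) if all_edits else None

    manifest = {
        "package": "polyadmix",
        "version": __version__,
        "config": {k: (asdict(v) if isinstance(v, TherapyPlan) else v) for k, v in asdict(cfg).items()},
        "master_seed": cfg.seed,
        "architecture": {
            "n_loci": arch.n_loci,
            "lineage": arch.lineage,
            "fingerprint": arch.fingerprint(),
            "expected_mean_prs": [arch.expected_mean_prs(1), arch.expected_mean_prs(2)],
            "expected_prs_variance": [arch.expected_prs_variance(1), arch.expected_prs_variance(2)],
        },
        "mapping": {"prevalence": mapping.prevalence, "n_reference": mapping.n_reference,
                    "reps": mapping.reps, "delta_beta": mapping.delta_beta},
    }

    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stats.to_csv(out / "stats.csv", index=False)
        agg.to_csv(out / "aggregate.csv", index=False)
        if edits is not None:
            edits.to_csv(out / "edits.csv", index=False)
        save_mapping(mapping, out / "mapping.csv")
        arch.to_csv(out / "architecture.csv")
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    return ScenarioResult(cfg, arch, mapping, stats, agg, edits, manifest)


# ------------------------------------------------------------------ #


def builtin_scenarios() -> dict[str, ScenarioConfig]:
    """Ready-made configurations for the package's canonical experiments."""
    out: dict[str, ScenarioConfig] = {}
    # equal-liability admixture with differing causal-SNP sets
    for frac in (1.0, 0.65, 0.33, 0.20):
        for lam, gens in ((36.0, 25), (1000.0, 10)):
            tag = f"equal_liability_diff{int(round(frac * 100))}" + ("_accel" if lam > 36 else "")
            out[tag] = ScenarioConfig(
                name=tag, fraction_diff=frac, prevalence_pop1=0.01,
                admixture=1.0, crossover_mean=lam, generations=gens,
            )
    # 10-fold relative-risk gap, varying admixture rate
    for m in (1.0, 0.5, 0.25, 0.1):
        tag = f"rr10_admix{int(round(m * 100))}"
        out[tag] = ScenarioConfig(
            name=tag, delta_prs=LN10, prevalence_pop1=0.001,
            admixture=m, generations=15,
        )
    # single-shot 10-fold therapy followed by blending
    out["therapy_rr10_blend"] = ScenarioConfig(
        name="therapy_rr10_blend", prevalence_pop1=0.01, admixture=1.0, generations=15,
        therapy=TherapyPlan(mode="single_shot", target_delta_prs=-LN10),
    )
    # disease presets with contrasting prevalence between groups
    for disease in DISEASE_PRESETS:
        tag = f"preset_{disease.lower()}"
        out[tag] = ScenarioConfig(name=tag, preset=disease, admixture=1.0, generations=5)
    # maintenance therapy at a 10-fold-improved PRS level
    for m in (1.0, 0.25):
        tag = f"maintenance_rr10_admix{int(round(m * 100))}"
        out[tag] = ScenarioConfig(
            name=tag, prevalence_pop1=0.01, admixture=m, generations=15,
            therapy=TherapyPlan(mode="maintenance", target_delta_prs=-LN10),
        )
    return out
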