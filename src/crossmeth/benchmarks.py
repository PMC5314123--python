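"""Reference checks and planted-truth benchmarks for the whole pipeline.

These routines generate their own inputs with the package's synthetic-data
module (or plain random draws where only a statistic is being calibrated),
run the pipeline stages, and measure agreement, error rates or recovery.
They are used both by the test suite and by ``scripts/acceptance.py``.

Multi-replicate benchmarks derive replicate seeds as ``base_seed * 1000 + i``
so that different base seeds index disjoint seed blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import StudyConfig, DatasetDesign, PlantedGene, funnel_demo_config
from .cross_species import build_funnel
from .gene_calls import classify_genes, map_probes_to_genes
from .probe_stats import (LogRatioMatrix, adjust_fdr, call_dataset,
                          differential_probe_test)
from .simulate import (evaluate_recovery, generate_study, simulate_trajectory)
from .validation import fisher_lsd, two_way_anova


# ------------------------------------------------------------------- BH ----

def bh_step_up_reference(p) -> np.ndarray:
    """Literal Benjamini-Hochberg step-up definition, O(m^2).

    q_i = min over j with p_j >= p_i of min(1, p_j * m / rank(p_j)), where
    rank uses the largest position among tied values.
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    q = np.empty(m)
    for i in range(m):
        best = 1.0
        for j in range(m):
            if p[j] >= p[i]:
                rank = int((p <= p[j]).sum())
                best = min(best, p[j] * m / rank)
        q[i] = best
    return q


def bh_agreement(n_draws: int = 10_000, max_len: int = 8,
                 seed: int = 0) -> float:
    """Fraction of random p-vectors on which adjust_fdr equals the reference.

    A quarter of the draws are rounded to one decimal to exercise ties.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_draws):
        k = int(rng.integers(1, max_len + 1))
        p = rng.uniform(0, 1, k)
        if rng.uniform() < 0.25:
            p = np.round(p, 1)
        agree += np.allclose(adjust_fdr(p), bh_step_up_reference(p), atol=1e-12)
    return agree / n_draws


# ------------------------------------------------------ test calibration ----

def type1_error_rate(n_probes: int = 1000, n_per_group: int = 4,
                     sd: float = 0.5, alpha: float = 0.05,
                     seed: int = 0) -> float:
    """Empirical per-probe type-I error of the Welch test under the null."""
    rng = np.random.default_rng(seed)
    samples = [f"c{i}" for i in range(n_per_group)] + \
              [f"s{i}" for i in range(n_per_group)]
    values = pd.DataFrame(rng.normal(0, sd, (n_probes, 2 * n_per_group)),
                          index=[f"p{i}" for i in range(n_probes)],
                          columns=samples)
    groups = pd.Series(["control"] * n_per_group + ["stress"] * n_per_group,
                       index=samples)
    res = differential_probe_test(LogRatioMatrix(values, groups))
    return float((res["p_value"] < alpha).mean())


# ------------------------------------------------------ planted recovery ----

def _recovery_config(seed: int, n_genes: int = 200, n_dm: int = 20,
                     effect: float = 1.0, sd: float = 0.5) -> StudyConfig:
    design = DatasetDesign(dataset_id="rat_pfc", species="rat",
                           tissue="prefrontal_cortex", n_control=4, n_stress=4)
    states = ["hyper"] * (2 * n_dm // 5) + ["hypo"] * (2 * n_dm // 5)
    states += ["mixed"] * (n_dm - len(states))
    planted = [PlantedGene(gene_label=f"DM{i:03d}",
                           state_by_dataset={"rat_pfc": s})
               for i, s in enumerate(states)]
    return StudyConfig(datasets=[design], n_genes=n_genes,
                       planted_genes=planted, effect_logratio=effect,
                       baseline_logratio_sd=sd, seed=seed)


def _gene_calls(study, ds_id: str, fdr: float = 0.2):
    data = study.datasets[ds_id]
    probe_calls = call_dataset(data.bound, data.input, data.groups,
                               annotation=study.annotation[ds_id].probes,
                               fdr_threshold=fdr)
    assigned, _ = map_probes_to_genes(probe_calls,
                                      study.annotation[ds_id].genes)
    return classify_genes(assigned, dataset_id=ds_id)


@dataclass
class RecoveryBenchmark:
    sensitivity: float
    empirical_fdr: float
    direction_accuracy: float
    n_seeds: int


def recovery_benchmark(n_seeds: int = 20, base_seed: int = 0,
                       **config_kwargs) -> RecoveryBenchmark:
    """Mean gene-level recovery over seeded 200-gene single-cohort studies."""
    sens, fdr, acc = [], [], []
    for i in range(n_seeds):
        study = generate_study(_recovery_config(base_seed * 1000 + i,
                                                **config_kwargs))
        calls = _gene_calls(study, "rat_pfc")
        rec = evaluate_recovery(calls, study.truth, "rat_pfc")
        sens.append(rec.sensitivity)
        fdr.append(rec.empirical_fdr)
        acc.append(rec.direction_accuracy)
    return RecoveryBenchmark(float(np.mean(sens)), float(np.mean(fdr)),
                             float(np.mean(acc)), n_seeds)


def noiseless_direction_accuracy(seed: int = 0) -> float:
    """Fraction of genes whose class equals the planted state when noise
    vanishes; every gene is planted (10 hyper, 10 hypo, 10 mixed)."""
    design = DatasetDesign(dataset_id="rat_pfc", species="rat",
                           tissue="prefrontal_cortex", n_control=4, n_stress=4)
    states = ["hyper"] * 10 + ["hypo"] * 10 + ["mixed"] * 10
    planted = [PlantedGene(gene_label=f"P{i:02d}", state_by_dataset={"rat_pfc": s})
               for i, s in enumerate(states)]
    cfg = StudyConfig(datasets=[design], n_genes=30, planted_genes=planted,
                      baseline_logratio_sd=1e-9, seed=seed)
    study = generate_study(cfg)
    calls = _gene_calls(study, "rat_pfc")
    classes = dict(zip(calls.gene_id.str.upper(), calls.direction_class))
    truth = study.truth.states["rat_pfc"]
    hits = sum(classes.get(g.upper(), "none") == s for g, s in truth.items())
    return hits / len(truth)


# ----------------------------------------------------------------- funnel ----

@dataclass
class FunnelBenchmark:
    success_rate: float
    modal_counts: tuple[int, int, int]
    survivor: str
    n_seeds: int


def funnel_benchmark(n_seeds: int = 20, base_seed: int = 0) -> FunnelBenchmark:
    """Rate at which the demo study reproduces the staged 8 -> 2 -> 1 funnel
    with the planted survivor, over seeded replicates."""
    successes, counts = 0, []
    for i in range(n_seeds):
        cfg = funnel_demo_config(seed=base_seed * 1000 + i)
        study = generate_study(cfg)
        tables = {ds: _gene_calls(study, ds) for ds in study.datasets}
        funnel = build_funnel(tables, cfg.core_ids, cfg.extension_ids,
                              ortholog_map=study.orthologs)
        counts.append(funnel.stage_counts)
        if (funnel.stage_counts == (8, 2, 1)
                and funnel.extension_consistent == {"ANK3"}):
            successes += 1
    modal = max(set(counts), key=counts.count)
    return FunnelBenchmark(successes / n_seeds, modal, "ANK3", n_seeds)


# ------------------------------------------------------------ validation ----

def anova_ss_conservation(n_designs: int = 1000, seed: int = 0) -> float:
    """Max relative error of SS_A+SS_B+SS_AB+SSE vs total SS over random
    balanced two-factor designs."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_designs):
        la, lb = int(rng.integers(2, 4)), int(rng.integers(2, 4))
        n_cell = int(rng.integers(2, 5))
        rows = [(f"a{a}", f"b{b}", rng.normal(a * 0.5 + b * 0.3, 1.0))
                for a in range(la) for b in range(lb) for _ in range(n_cell)]
        df = pd.DataFrame(rows, columns=["group", "age", "value"])
        res = two_way_anova(df)
        total = sum(t.ss for t in res.terms.values()) + res.residual_ss
        y = df.value.to_numpy()
        expected = float(((y - y.mean()) ** 2).sum())
        worst = max(worst, abs(total - expected) / expected)
    return worst


def lsd_age_specificity(n_reps: int = 100, base_seed: int = 0,
                        n_control: int = 7, n_stress: int = 9,
                        effect: float = 1.0, sd: float = 0.3) -> float:
    """Fraction of trajectory simulations in which Fisher's LSD flags the
    control-stress difference at the planted age (the last) and no other."""
    hits = 0
    for i in range(n_reps):
        df = simulate_trajectory(stress_effects=(0.0, 0.0, -effect),
                                 n_control=n_control, n_stress=n_stress,
                                 sd=sd, seed=base_seed * 1000 + i)
        res = two_way_anova(df)
        lsd = fisher_lsd(res)
        flagged = set(lsd.loc[lsd.significant, "age"])
        hits += flagged == {"PND62"}
    return hits / n_reps
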