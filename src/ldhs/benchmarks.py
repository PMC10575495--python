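"""Canned benchmark protocols used by the validation suite and reproduction script.

Each function runs one self-contained experiment at its stated study
conditions and returns plain numbers. Problem sizes are chosen so the whole
battery runs on a single CPU in minutes; docs/methods.md discusses what they
do and do not demonstrate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bench import evaluate_power, exhaustive_all_objectives
from .epistasis_sim import (
    make_marginal_model,
    make_no_marginal_model,
    make_null_model,
    parity_table,
    simulate_annotations,
    simulate_dataset,
)
from .harmony_search import SearchConfig, run_ldhs
from .objectives import OBJECTIVES, association_tests


def oracle_equivalence(
    n_datasets: int = 30,
    m: int = 20,
    k: int = 2,
    n_case: int = 400,
    n_control: int = 400,
    budget: int = 230,
    seed: int = 0,
) -> float:
    """Fraction of (dataset, objective) pairs where the search returns the
    exhaustive optimum, given a budget at least C(m, k).

    Datasets carry a strong multiplicative 2-SNP signal (baseline 0.01,
    effect 2.0, MAF 0.3).
    """
    matches = 0
    total = 0
    for i in range(n_datasets):
        rng = np.random.default_rng(seed + 10_000 + i)
        model = make_marginal_model(k, (0.3,) * k, baseline=0.01, effect=2.0)
        ds, _ = simulate_dataset(model, n_case, n_control, m, rng)
        res = run_ldhs(ds, None, SearchConfig(k=k, max_evals=budget, seed=seed + 20_000 + i))
        exh, _ = exhaustive_all_objectives(ds, k)
        for obj in OBJECTIVES:
            total += 1
            best = res.best_per_objective[obj]
            same_set = best.snp_set == exh[obj].best_set
            same_value = abs(best.value(obj) - exh[obj].best_value) < 1e-12
            matches += same_set or same_value
    return matches / total


@dataclass
class InitAdvantage:
    """Locus-driven vs random-initialization comparison at equal budget."""

    power_ldhs: float
    power_baseline: float
    #: mean unique evaluations to detection, undetected runs censored at the
    #: budget they spent (comparable between arms with unequal power)
    evals_to_detection_ldhs: float | None
    evals_to_detection_baseline: float | None


def initialization_advantage(
    n_datasets: int = 20,
    m: int = 100,
    k: int = 2,
    n_case: int = 800,
    n_control: int = 800,
    maf: float = 0.4,
    prevalence: float = 0.2,
    budget: int = 2500,
    seed: int = 0,
) -> InitAdvantage:
    """Detection power of LDHS (locus_fraction 0.5, co-located annotations)
    vs the random-initialization baseline (locus_fraction 0) at equal budget,
    on XOR-seeded no-marginal-effect datasets.

    Runs stop early once the planted pair enters a harmony memory;
    ``evals_to_detection`` averages the unique-evaluation count at that
    moment, with undetected runs censored at the budget they spent.
    """
    res_ldhs, res_base, truths = [], [], []
    for i in range(n_datasets):
        rng = np.random.default_rng(seed + 30_000 + i)
        model = make_no_marginal_model(
            k, (maf,) * k, prevalence=prevalence, rng=rng,
            seed_table=parity_table(k, h=2.0 * prevalence),
        )
        ds, truth = simulate_dataset(model, n_case, n_control, m, rng)
        ann = simulate_annotations(m, truth, "co_located", rng)
        truths.append(truth)
        common = dict(k=k, max_evals=budget, stop_on_target=truth.functional)
        res_ldhs.append(
            run_ldhs(ds, ann, SearchConfig(seed=seed + 40_000 + i, **common))
        )
        res_base.append(
            run_ldhs(ds, None, SearchConfig(seed=seed + 40_000 + i, locus_fraction=0.0, **common))
        )
    p_l = evaluate_power(res_ldhs, truths)
    p_b = evaluate_power(res_base, truths)
    return InitAdvantage(
        power_ldhs=p_l.power,
        power_baseline=p_b.power,
        evals_to_detection_ldhs=p_l.mean_evals_to_target_censored,
        evals_to_detection_baseline=p_b.mean_evals_to_target_censored,
    )


def null_type_i_rate(
    n_replicates: int = 200,
    n_case: int = 200,
    n_control: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """G-test rejection rate on the functional pair of a constant-penetrance model."""
    rejections = 0
    for i in range(n_replicates):
        rng = np.random.default_rng(seed + 50_000 + i)
        model = make_null_model(2, (0.3, 0.3), penetrance=0.3)
        ds, truth = simulate_dataset(model, n_case, n_control, m=2, rng=rng)
        res = association_tests(ds, truth.functional, n_candidates=1)
        rejections += res.g_pvalue < alpha
    return rejections / n_replicates
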