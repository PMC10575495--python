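import numpy as np
import pytest

from ldhs.epistasis_sim import (
    PenetranceModel,
    hwe_genotype_freqs,
    make_marginal_model,
    make_no_marginal_model,
    make_null_model,
    parity_table,
    simulate_annotations,
    simulate_dataset,
)
from ldhs.errors import SimulationError
from ldhs.genotype_data import read_genotypes, write_genotypes
from ldhs.objectives import association_tests


# ---------------------------------------------------------------- HWE


@pytest.mark.parametrize(
    "maf,expected",
    [
        (0.5, (0.25, 0.5, 0.25)),
        (0.0, (1.0, 0.0, 0.0)),
        (0.3, (0.49, 0.42, 0.09)),
    ],
)
def test_hwe_genotype_freqs(maf, expected):
    freqs = hwe_genotype_freqs(maf)
    assert freqs == pytest.approx(expected, abs=1e-12)
    assert sum(freqs) == pytest.approx(1.0)


def test_hwe_maf_out_of_range():
    with pytest.raises(ValueError):
        hwe_genotype_freqs(0.7)
    with pytest.raises(ValueError):
        hwe_genotype_freqs(-0.1)


def test_hwe_sampler_calibration(rng):
    """Empirical genotype frequencies within 3 binomial SE at n = 1e5."""
    n = 100_000
    p = hwe_genotype_freqs(0.3)
    draws = rng.choice(3, size=n, p=p)
    emp = np.bincount(draws, minlength=3) / n
    for s in range(3):
        se = np.sqrt(p[s] * (1 - p[s]) / n)
        assert abs(emp[s] - p[s]) < 3 * se


# ---------------------------------------------------------------- models


def test_parity_table_equal_marginals_at_half_maf():
    model = PenetranceModel(2, (0.5, 0.5), parity_table(2, 0.6), marginal_effect_flag=False)
    assert model.prevalence == pytest.approx(0.3)
    assert model.max_marginal_deviation() < 1e-15


def test_xor_seed_accepted_unchanged_at_half_maf():
    seed = parity_table(2, 0.6)
    model = make_no_marginal_model(2, (0.5, 0.5), prevalence=0.3, seed_table=seed)
    assert np.allclose(model.table, seed)


def test_no_marginal_model_postconditions():
    rng = np.random.default_rng(0)
    model = make_no_marginal_model(
        2, (0.4, 0.4), prevalence=0.2, rng=rng, seed_table=parity_table(2, 0.4)
    )
    assert model.max_marginal_deviation() < 1e-6
    assert model.prevalence == pytest.approx(0.2, abs=1e-5)
    assert not model.marginal_effect_flag
    assert (model.table >= 0).all() and (model.table <= 1).all()


def test_no_marginal_model_random_start():
    rng = np.random.default_rng(1)
    model = make_no_marginal_model(3, (0.3, 0.4, 0.25), prevalence=0.15, rng=rng)
    assert model.max_marginal_deviation() < 1e-6
    assert model.prevalence == pytest.approx(0.15, abs=1e-5)


def test_marginal_model_values():
    model = make_marginal_model(2, (0.3, 0.3), baseline=0.1, effect=0.5)
    assert model.table[2, 2] == pytest.approx(0.1 * 1.5**4)  # 0.50625
    assert model.table[0, 0] == pytest.approx(0.1)
    # marginal penetrances strictly increase with genotype value at every locus
    for j in range(2):
        marg = model.marginal_penetrance(j)
        assert marg[0] < marg[1] < marg[2]


def test_marginal_model_null_effect():
    model = make_marginal_model(2, (0.3, 0.3), baseline=0.1, effect=0.0)
    assert np.allclose(model.table, 0.1)
    assert model.prevalence == pytest.approx(0.1)


def test_marginal_model_overflow_rejected():
    with pytest.raises(ValueError, match="overflow"):
        make_marginal_model(2, (0.3, 0.3), baseline=0.5, effect=1.0)


# ---------------------------------------------------------------- dataset simulation


def test_simulated_dataset_quotas_and_shapes(rng):
    model = make_marginal_model(2, (0.3, 0.3), baseline=0.05, effect=1.0)
    ds, truth = simulate_dataset(model, n_case=120, n_control=80, m=25, rng=rng)
    assert ds.n_case == 120 and ds.n_control == 80
    assert ds.m == 25
    assert len(truth.functional) == 2
    assert all(0 <= j < 25 for j in truth.functional)


def test_simulate_argument_errors(rng):
    model = make_marginal_model(2, (0.3, 0.3), baseline=0.05, effect=1.0)
    with pytest.raises(ValueError):
        simulate_dataset(model, 10, 10, m=1, rng=rng)
    with pytest.raises(ValueError):
        simulate_dataset(model, 10, 10, m=5, rng=rng, functional_indices=[0, 9])


def test_unfillable_quota_raises(rng):
    # penetrance ~1 everywhere: controls cannot be sampled
    model = PenetranceModel(2, (0.3, 0.3), np.ones((3, 3)), marginal_effect_flag=False)
    with pytest.raises(SimulationError):
        simulate_dataset(model, 1, 50, m=4, rng=rng, max_rejection_factor=10)


def test_null_model_type_i_error_rate():
    """G-test on the functional set of a null model rejects at ~ alpha."""
    rejections = 0
    n_rep = 100
    for i in range(n_rep):
        rng = np.random.default_rng(9000 + i)
        model = make_null_model(2, (0.3, 0.3), penetrance=0.3)
        # 200/200 keeps expected cell counts large enough for the chi-square
        # approximation to hold on the 9x2 joint table
        ds, truth = simulate_dataset(model, 200, 200, m=2, rng=rng)
        res = association_tests(ds, truth.functional, n_candidates=1)
        rejections += res.g_pvalue < 0.05
    assert rejections / n_rep == pytest.approx(0.05, abs=0.06)


def test_background_snps_carry_no_signal():
    """Case/control allele-frequency difference of background SNPs centers at 0."""
    from scipy import stats

    diffs = []
    for i in range(120):
        rng = np.random.default_rng(400 + i)
        model = make_null_model(2, (0.3, 0.3), penetrance=0.3)
        ds, truth = simulate_dataset(model, 100, 100, m=4, rng=rng)
        background = [j for j in range(4) if j not in truth.functional]
        j = background[0]
        case_af = ds.genotypes[ds.labels == 1, j].mean() / 2
        ctrl_af = ds.genotypes[ds.labels == 0, j].mean() / 2
        diffs.append(case_af - ctrl_af)
    t_stat, pvalue = stats.ttest_1samp(diffs, 0.0)
    assert pvalue > 0.01


def test_no_marginal_data_hides_single_locus_signal():
    """Single-SNP tests are null on zero-marginal data while the joint test has power."""
    single_rejections = 0
    joint_rejections = 0
    n_rep = 40
    for i in range(n_rep):
        rng = np.random.default_rng(600 + i)
        model = make_no_marginal_model(
            2, (0.4, 0.4), prevalence=0.2, rng=rng, seed_table=parity_table(2, 0.4)
        )
        ds, truth = simulate_dataset(model, 400, 400, m=2, rng=rng)
        for j in truth.functional:
            if association_tests(ds, [j], n_candidates=1).g_pvalue < 0.05:
                single_rejections += 1
        if association_tests(ds, truth.functional, n_candidates=1).g_pvalue < 0.05:
            joint_rejections += 1
    assert single_rejections / (2 * n_rep) < 0.15  # consistent with nominal alpha
    assert joint_rejections / n_rep > 0.95  # joint signal has high power


# ---------------------------------------------------------------- annotations & round-trip


def test_annotation_scenarios(rng):
    model = make_marginal_model(2, (0.3, 0.3), baseline=0.05, effect=1.0)
    ds, truth = simulate_dataset(model, 50, 50, m=40, rng=rng)

    co = simulate_annotations(40, truth, "co_located", rng)
    lookup = co.lookup()
    regions = {lookup[f"SNP{j}"][0] for j in truth.functional}
    assert len(regions) == 1

    sc = simulate_annotations(40, truth, "scattered", rng)
    lookup = sc.lookup()
    regions = [lookup[f"SNP{j}"][0] for j in truth.functional]
    assert len(set(regions)) == len(truth.functional)

    assert len(simulate_annotations(40, truth, "no_info", rng)) == 0
    with pytest.raises(ValueError):
        simulate_annotations(40, truth, "bogus", rng)


def test_simulated_dataset_round_trips_through_writer(tmp_path, rng):
    model = make_marginal_model(2, (0.3, 0.3), baseline=0.05, effect=1.0)
    ds, _ = simulate_dataset(model, 30, 30, m=10, rng=rng)
    path = tmp_path / "sim.tsv"
    write_genotypes(ds, path)
    assert read_genotypes(path) == ds
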