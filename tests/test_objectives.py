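import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import dataset_from_cells, random_dataset, table_from_rows
from ldhs.genotype_data import GenotypeDataset
from ldhs.objectives import (
    ContingencyTable,
    EvalCounter,
    association_tests,
    build_contingency,
    js_score,
    k2_score,
    lr_score,
    ndje_score,
    score_all,
)

LN2 = math.log(2.0)


# ---------------------------------------------------------------- tally


def test_empty_dataset_all_counts_zero():
    ds = GenotypeDataset(["A", "B"], np.zeros((0, 2), dtype=np.int8), np.zeros(0, dtype=np.int8))
    t = build_contingency(ds, [0, 1])
    assert t.counts.sum() == 0 and t.locus_marginals.sum() == 0


def test_k1_direct_tally():
    # genotypes [0,0,1], labels [case,case,control]
    ds = GenotypeDataset(
        ["A"], np.array([[0], [0], [1]], dtype=np.int8), np.array([1, 1, 0], dtype=np.int8)
    )
    t = build_contingency(ds, [0])
    assert t.counts[0].tolist() == [2, 0]  # genotype 0: 2 cases
    assert t.counts[1].tolist() == [0, 1]  # genotype 1: 1 control
    assert t.counts[2].tolist() == [0, 0]


def test_k2_matches_nested_loop_tally(rng):
    ds = random_dataset(rng, n=25, m=4)
    t = build_contingency(ds, [2, 0])  # unsorted input, canonical = (0, 2)
    expect = np.zeros((9, 2), dtype=int)
    for i in range(ds.n_samples):
        cell = ds.genotypes[i, 0] * 3 + ds.genotypes[i, 2]
        expect[cell, 1 - ds.labels[i]] += 1
    assert np.array_equal(t.counts, expect)


def test_build_contingency_argument_errors(rng):
    ds = random_dataset(rng, n=10, m=4)
    with pytest.raises(ValueError):
        build_contingency(ds, [1, 1])
    with pytest.raises(ValueError):
        build_contingency(ds, [])
    with pytest.raises(IndexError):
        build_contingency(ds, [0, 99])


@settings(deadline=None, max_examples=30, derandomize=True)
@given(seed=st.integers(0, 2**16), k=st.integers(1, 3))
def test_marginal_conservation_invariants(seed, k):
    """Cell counts and per-locus marginals both tally every sample exactly once."""
    rng = np.random.default_rng(seed)
    ds = random_dataset(rng, n=int(rng.integers(0, 60)), m=6)
    snp_set = rng.choice(6, size=k, replace=False)
    t = build_contingency(ds, snp_set)
    assert t.n == ds.n_samples
    assert t.n_case == ds.n_case and t.n_control == ds.n_control
    assert np.array_equal(t.n_i, t.counts.sum(axis=1))
    for j in range(k):
        assert t.locus_marginals[j, :, 0].sum() == ds.n_case
        assert t.locus_marginals[j, :, 1].sum() == ds.n_control


# ---------------------------------------------------------------- K2


def test_k2_all_zero_table_is_zero():
    assert k2_score(table_from_rows([])) == 0.0


def test_k2_single_row_factorial_value():
    # one row with 2 cases, 0 controls: marginal likelihood = 1!/(3!)*2!*0! = 1/3,
    # so the score (its negative log) is -ln(1/3)
    assert k2_score(table_from_rows([(2, 0)])) == pytest.approx(-math.log(1 / 3), abs=1e-12)


def _k2_exact(rows):
    """Big-integer K2 via exact factorials (independent oracle)."""
    val = Fraction(1)
    for nca, nco in rows:
        n_i = nca + nco
        if n_i == 0:
            continue
        val *= Fraction(
            math.factorial(1) * math.factorial(nca) * math.factorial(nco),
            math.factorial(n_i + 1),
        )
    return -float(math.log(val))


def test_k2_matches_bigint_factorials_on_random_tables(rng):
    for _ in range(200):
        n_rows = int(rng.integers(1, 4))
        rows = []
        budget = 30
        for _ in range(n_rows):
            a = int(rng.integers(0, budget + 1))
            b = int(rng.integers(0, budget - a + 1))
            rows.append((a, b))
            budget -= a + b
        t = table_from_rows(rows)
        assert k2_score(t) == pytest.approx(_k2_exact(rows), abs=1e-9)


def test_k2_separating_beats_balanced():
    sep = table_from_rows([(10, 0), (0, 10)])
    bal = table_from_rows([(5, 5), (5, 5)])
    assert k2_score(sep) < k2_score(bal)
    assert k2_score(sep) == pytest.approx(_k2_exact([(10, 0), (0, 10)]), abs=1e-9)


# ---------------------------------------------------------------- LR


def test_lr_zero_when_observed_equals_expected():
    assert lr_score(table_from_rows([(10, 10), (10, 10)])) == pytest.approx(0.0, abs=1e-12)


def test_lr_perfectly_separating_2x2():
    assert lr_score(table_from_rows([(10, 0), (0, 10)])) == pytest.approx(40 * LN2, abs=1e-9)


def test_lr_empty_table():
    assert lr_score(table_from_rows([])) == 0.0


def _lr_brute(rows):
    n = sum(a + b for a, b in rows)
    ncase = sum(a for a, _ in rows)
    nctrl = n - ncase
    total = 0.0
    for a, b in rows:
        n_i = a + b
        for o, col in ((a, ncase), (b, nctrl)):
            if o > 0:
                total += o * math.log(o / (n_i * col / n))
    return 2.0 * total


def test_lr_matches_independent_brute_force(rng):
    for _ in range(100):
        rows = [(int(rng.integers(0, 20)), int(rng.integers(0, 20))) for _ in range(3)]
        if sum(a for a, _ in rows) == 0 or sum(b for _, b in rows) == 0:
            continue
        assert lr_score(table_from_rows(rows)) == pytest.approx(_lr_brute(rows), abs=1e-10)


# ---------------------------------------------------------------- JS


def test_js_zero_on_even_rows():
    assert js_score(table_from_rows([(5, 5), (3, 3)])) == pytest.approx(0.0, abs=1e-12)


def test_js_single_pure_row():
    assert js_score(table_from_rows([(4, 0)])) == pytest.approx(0.5 * LN2, abs=1e-12)


def test_js_symmetric_under_column_swap(rng):
    for _ in range(50):
        rows = [(int(rng.integers(0, 15)), int(rng.integers(0, 15))) for _ in range(3)]
        swapped = [(b, a) for a, b in rows]
        assert js_score(table_from_rows(rows)) == pytest.approx(
            js_score(table_from_rows(swapped)), abs=1e-12
        )


def test_js_and_lr_nonnegative(rng):
    for _ in range(100):
        rows = [(int(rng.integers(0, 25)), int(rng.integers(0, 25))) for _ in range(3)]
        t = table_from_rows(rows)
        assert js_score(t) >= -1e-12
        assert lr_score(t) >= -1e-12
        assert math.isfinite(k2_score(t))


# ---------------------------------------------------------------- NDJE


def test_ndje_identical_joint_distributions_is_sentinel():
    assert ndje_score(table_from_rows([(5, 5), (7, 7)])) == math.inf


def test_ndje_degenerate_control_entropy_is_sentinel():
    # case=(10,0,10), control=(0,20,0): JE = -1*ln1 = 0
    ds = dataset_from_cells([10, 0, 10], [0, 20, 0])
    assert ndje_score(build_contingency(ds, [0])) == math.inf


def test_ndje_hand_worked_value():
    # case=(10,10,0), control=(10,0,10): d=200, D=20, JE=ln2 -> (200/20)/ln2
    ds = dataset_from_cells([10, 10, 0], [10, 0, 10])
    assert ndje_score(build_contingency(ds, [0])) == pytest.approx(
        (200 / 20) / LN2, abs=1e-9
    )


# ---------------------------------------------------------------- score_all


def test_score_all_deterministic_and_compositional(rng):
    ds = random_dataset(rng, n=40, m=6)
    counter = EvalCounter()
    sv1 = score_all(ds, [1, 4], counter)
    sv2 = score_all(ds, [1, 4], counter)
    assert sv1 == sv2
    assert counter.count == 2
    t = build_contingency(ds, [1, 4])
    assert sv1.k2 == k2_score(t)
    assert sv1.lr == lr_score(t)
    assert sv1.js == js_score(t)
    assert sv1.ndje == ndje_score(t)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(seed=st.integers(0, 2**16))
def test_scores_invariant_under_snp_set_permutation(seed):
    rng = np.random.default_rng(seed)
    ds = random_dataset(rng, n=30, m=6)
    k = int(rng.integers(2, 4))
    snp_set = [int(x) for x in rng.choice(6, size=k, replace=False)]
    perm = [snp_set[i] for i in rng.permutation(k)]
    assert score_all(ds, snp_set) == score_all(ds, perm)


# ---------------------------------------------------------------- verification


def test_association_tests_separating_table():
    ds = dataset_from_cells([10, 0, 0], [0, 10, 0])
    res = association_tests(ds, [0])
    assert res.g_statistic == pytest.approx(40 * LN2, abs=1e-9)
    assert res.chi2_statistic == pytest.approx(20.0, abs=1e-9)
    assert res.degrees_of_freedom == 1
    assert res.significant


def test_association_tests_null_table():
    ds = dataset_from_cells([10, 10, 0], [10, 10, 0])
    res = association_tests(ds, [0])
    assert res.g_statistic == pytest.approx(0.0, abs=1e-12)
    assert res.chi2_statistic == pytest.approx(0.0, abs=1e-12)
    assert res.g_pvalue == pytest.approx(1.0)
    assert not res.significant


def test_bonferroni_correction():
    ds = dataset_from_cells([5, 0, 0], [0, 5, 0])
    res = association_tests(ds, [0], n_candidates=4950)
    assert res.corrected_alpha == pytest.approx(0.05 / 4950, rel=1e-12)
    assert res.corrected_alpha == pytest.approx(1.0101e-5, rel=1e-3)


def test_single_realized_row_flagged_degenerate():
    ds = dataset_from_cells([7, 0, 0], [3, 0, 0])
    res = association_tests(ds, [0])
    assert res.degenerate
    assert res.degrees_of_freedom == 0
    assert res.g_pvalue == 1.0


def test_monotone_association_on_enumerated_2x2():
    """For fixed margins, shifting mass toward separation never lowers LR
    nor raises ln-K2 (checked exhaustively on small symmetric-margin tables)."""
    for n in range(2, 13, 2):
        half = n // 2
        values_lr = []
        values_k2 = []
        # a = cases in row 1; a = 0 is fully separating, a = half//2 closest to balanced
        for a in range(half // 2 + 1):
            rows = [(a, half - a), (half - a, a)]
            values_lr.append(lr_score(table_from_rows(rows)))
            values_k2.append(k2_score(table_from_rows(rows)))
        for i in range(len(values_lr) - 1):
            assert values_lr[i] >= values_lr[i + 1] - 1e-12
            assert values_k2[i] <= values_k2[i + 1] + 1e-12
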