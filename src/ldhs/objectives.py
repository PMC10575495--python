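"""Contingency tables and the four association objectives, plus verification tests.

A candidate interaction of order ``k`` is an (unordered) set of ``k`` SNPs. Its
joint genotype takes one of ``3^k`` values; tallying samples into
(genotype-combination, phenotype) cells gives an ``I x 2`` contingency table
(``I`` = number of realized combinations) on which four complementary
objectives are evaluated:

* **K2** — Bayesian Dirichlet score of the table (lower = stronger
  association); computed in natural-log space via log-gamma so that large
  sample counts do not overflow.
* **LR** — the likelihood-ratio (G) statistic ``2 sum o ln(o/e)`` against
  independence (higher = stronger).
* **JS** — a per-combination case/control divergence,
  ``0.5 sum_i sum_j (n_ij/n_i) ln(2 n_ij/n_i)`` (higher = stronger). Each
  realized row contributes ``ln 2 - H(n_i1/n_i) >= 0``.
* **NDJE** — normalized distance with joint entropy, the ratio of summed
  per-locus squared marginal differences to the joint class-distribution
  distance, normalized by the control-sample joint entropy. Designed so that
  interactions with *no marginal effect* (flat single-locus signal, divergent
  joint signal) take small values; minimized by default.

Degenerate NDJE denominators (identical joint class distributions, or a
control distribution concentrated on one cell) yield ``+inf``, a sentinel
that every ranking in this package treats as the worst possible value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import chi2 as chi2_dist

from .genotype_data import GenotypeDataset

#: Optimization direction of each objective ("min" = smaller is stronger).
DEFAULT_DIRECTIONS: dict[str, str] = {"k2": "min", "lr": "max", "js": "max", "ndje": "min"}

OBJECTIVES = ("k2", "lr", "js", "ndje")


@dataclass
class ContingencyTable:
    """Joint genotype-combination x phenotype counts for a k-SNP set.

    Attributes
    ----------
    k
        Interaction order.
    counts
        ``(3^k, 2)`` array; column 0 = cases, column 1 = controls. Cell ``i``
        encodes the genotype combination with mixed-radix index
        ``sum_j g_j * 3^(k-1-j)`` over the canonically sorted SNP order.
    locus_marginals
        ``(k, 3, 2)`` array of per-locus genotype-value counts by class
        (``[..., 0]`` cases, ``[..., 1]`` controls).
    """

    k: int
    counts: np.ndarray
    locus_marginals: np.ndarray
    snp_set: tuple[int, ...] = field(default=())

    @property
    def n_case(self) -> int:
        return int(self.counts[:, 0].sum())

    @property
    def n_control(self) -> int:
        return int(self.counts[:, 1].sum())

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def n_i(self) -> np.ndarray:
        """Row marginals (samples per realized genotype combination)."""
        return self.counts.sum(axis=1)

    @property
    def realized(self) -> np.ndarray:
        """Boolean mask of genotype combinations observed at least once."""
        return self.n_i > 0

    @property
    def n_realized(self) -> int:
        return int(self.realized.sum())


def canonical_set(snp_set) -> tuple[int, ...]:
    """Canonical (sorted, duplicate-checked) form of a SNP index set."""
    canon = tuple(sorted(int(i) for i in snp_set))
    if not canon:
        raise ValueError("snp_set must not be empty")
    if len(set(canon)) != len(canon):
        raise ValueError(f"snp_set contains repeated indices: {snp_set}")
    return canon


def build_contingency(dataset: GenotypeDataset, snp_set) -> ContingencyTable:
    """Tally a dataset into the contingency table of a k-SNP combination.

    Cell identity uses the canonical sorted SNP order, so any permutation of
    ``snp_set`` yields the same table.
    """
    canon = canonical_set(snp_set)
    k = len(canon)
    if canon[0] < 0 or canon[-1] >= dataset.m:
        raise IndexError(f"snp indices out of range 0..{dataset.m - 1}: {canon}")
    n_cells = 3**k
    geno = dataset.genotypes[:, canon].astype(np.int64)
    # mixed-radix cell index, most-significant digit = first (lowest) SNP
    cell = np.zeros(dataset.n_samples, dtype=np.int64)
    for j in range(k):
        cell = cell * 3 + geno[:, j]
    # column 0 = case (label 1), column 1 = control (label 0)
    col = 1 - dataset.labels.astype(np.int64)
    counts = np.bincount(cell * 2 + col, minlength=n_cells * 2).reshape(n_cells, 2)

    locus = np.zeros((k, 3, 2), dtype=np.int64)
    for j in range(k):
        locus[j] = np.bincount(geno[:, j] * 2 + col, minlength=6).reshape(3, 2)
    return ContingencyTable(k=k, counts=counts, locus_marginals=locus, snp_set=canon)


def k2_score(table: ContingencyTable) -> float:
    """K2 score: negative log Bayesian-Dirichlet marginal likelihood (minimize).

    The marginal likelihood of the table under a uniform Dirichlet prior is
    ``prod_i (J-1)!/(n_i + J - 1)! prod_j n_ij!`` with J = 2 phenotype
    states; concentrated (associated) tables make it large. The score is its
    negative natural log, ``sum_i [ ln((n_i + J - 1)!) - sum_j ln(n_ij!) ]``
    (the ``ln (J-1)!`` term vanishes for J = 2), so *lower = stronger
    association*; unrealized combinations contribute 0.
    """
    mask = table.realized
    if not mask.any():
        return 0.0
    n_i = table.n_i[mask].astype(np.float64)
    n_ij = table.counts[mask].astype(np.float64)
    return float((gammaln(n_i + 2) - gammaln(n_ij + 1).sum(axis=1)).sum())


def lr_score(table: ContingencyTable) -> float:
    """Likelihood-ratio (G) statistic against independence (maximize).

    Expected counts come from the table's own margins,
    ``e_ij = n_i * n_.j / n``; terms with ``n_ij = 0`` contribute 0.
    """
    n = table.n
    if n == 0:
        return 0.0
    mask = table.realized
    o = table.counts[mask].astype(np.float64)
    n_i = table.n_i[mask].astype(np.float64)
    col = np.array([table.n_case, table.n_control], dtype=np.float64)
    e = np.outer(n_i, col) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(o > 0, o * np.log(np.where(o > 0, o / e, 1.0)), 0.0)
    return float(2.0 * terms.sum())


def js_score(table: ContingencyTable) -> float:
    """Row-wise case/control divergence (maximize); >= 0, 0 iff every row is 50/50."""
    mask = table.realized
    if not mask.any():
        return 0.0
    n_i = table.n_i[mask].astype(np.float64)
    r = table.counts[mask].astype(np.float64) / n_i[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(r > 0, r * np.log(2.0 * np.where(r > 0, r, 1.0)), 0.0)
    return float(0.5 * terms.sum())


def ndje_score(table: ContingencyTable) -> float:
    """Normalized distance with joint entropy (minimize by default).

    ``NDJE = ND / JE(control)`` where ``ND = (sum_j d_j) / D``,
    ``d_j = sum_s (n_s^{j,control} - n_s^{j,case})^2`` over the three genotype
    values of locus j, ``D = sum_i |n_i^{control} - n_i^{case}|`` over joint
    cells, and ``JE`` is the natural-log entropy of the control joint
    distribution. Returns ``+inf`` when ``D = 0`` or ``JE = 0`` (degenerate
    tables carry no usable signal and must rank worst).
    """
    diff_locus = (
        table.locus_marginals[:, :, 1].astype(np.float64)
        - table.locus_marginals[:, :, 0].astype(np.float64)
    )
    d_sum = float((diff_locus**2).sum())
    cell_diff = table.counts[:, 1].astype(np.float64) - table.counts[:, 0].astype(np.float64)
    big_d = float(np.abs(cell_diff).sum())
    if big_d == 0.0:
        return math.inf
    n_control = table.n_control
    if n_control == 0:
        return math.inf
    p = table.counts[:, 1].astype(np.float64) / n_control
    p = p[p > 0]
    je = float(-(p * np.log(p)).sum())
    if je <= 0.0:
        return math.inf
    return (d_sum / big_d) / je


@dataclass
class ScoreVector:
    """The four objective values of one SNP set."""

    k2: float
    lr: float
    js: float
    ndje: float

    def __getitem__(self, objective: str) -> float:
        return getattr(self, objective)


@dataclass
class EvalCounter:
    """Counts unique objective-function evaluations (one per scored SNP set)."""

    count: int = 0

    def increment(self) -> None:
        self.count += 1


def score_all(
    dataset: GenotypeDataset, snp_set, counter: EvalCounter | None = None
) -> ScoreVector:
    """Build one contingency table and evaluate all four objectives on it.

    Exactly one table is built per call; ``counter`` (if given) is
    incremented by one, which is the unit of the evaluation-count metric.
    """
    table = build_contingency(dataset, snp_set)
    if counter is not None:
        counter.increment()
    return ScoreVector(
        k2=k2_score(table),
        lr=lr_score(table),
        js=js_score(table),
        ndje=ndje_score(table),
    )


@dataclass
class TestResult:
    """G-test and Pearson chi-square verification of one SNP set."""

    g_statistic: float
    g_pvalue: float
    chi2_statistic: float
    chi2_pvalue: float
    degrees_of_freedom: int
    corrected_alpha: float
    degenerate: bool = False

    @property
    def significant(self) -> bool:
        """True when both tests pass the Bonferroni-corrected threshold."""
        return (
            not self.degenerate
            and self.g_pvalue < self.corrected_alpha
            and self.chi2_pvalue < self.corrected_alpha
        )


def association_tests(
    dataset: GenotypeDataset, snp_set, n_candidates: int = 1, alpha: float = 0.05
) -> TestResult:
    """G-test and Pearson chi-square of a k-SNP set against phenotype.

    Degrees of freedom are ``(I - 1)(J - 1)`` over realized rows only;
    ``corrected_alpha = alpha / n_candidates`` (Bonferroni over the verified
    candidate pool). A single-row table has df 0 and is flagged degenerate
    (p-values forced to 1).
    """
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    table = build_contingency(dataset, snp_set)
    g = lr_score(table)
    mask = table.realized
    df = (int(mask.sum()) - 1) * 1
    corrected = alpha / n_candidates
    if df <= 0 or table.n == 0:
        return TestResult(
            g_statistic=g,
            g_pvalue=1.0,
            chi2_statistic=0.0,
            chi2_pvalue=1.0,
            degrees_of_freedom=max(df, 0),
            corrected_alpha=corrected,
            degenerate=True,
        )
    o = table.counts[mask].astype(np.float64)
    n_i = table.n_i[mask].astype(np.float64)
    col = np.array([table.n_case, table.n_control], dtype=np.float64)
    e = np.outer(n_i, col) / table.n
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2_stat = float(np.where(e > 0, (o - e) ** 2 / np.where(e > 0, e, 1.0), 0.0).sum())
    return TestResult(
        g_statistic=g,
        g_pvalue=float(chi2_dist.sf(g, df)),
        chi2_statistic=chi2_stat,
        chi2_pvalue=float(chi2_dist.sf(chi2_stat, df)),
        degrees_of_freedom=df,
        corrected_alpha=corrected,
    )
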