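"""Penetrance-model simulator for case-control epistasis data.

Emulates the GAMETES-style protocol: a k-locus penetrance table (disease
probability per joint genotype) with functional-SNP genotypes drawn under
Hardy-Weinberg equilibrium (HWE), case/control quotas filled by rejection
sampling, and independent HWE background SNPs. Two model families are
provided:

* **marginal models** — multiplicative risk, ``f(g) = baseline * (1+effect)^sum(g)``;
  every functional locus shows single-SNP association.
* **no-marginal models** — penetrance tables whose HWE-weighted per-locus
  marginal penetrance equals the prevalence at every locus and genotype
  value, so no single SNP carries any association signal while the joint
  genotype distribution still separates cases from controls. Tables are
  constructed by cyclic additive projection onto the marginal constraints
  starting from a random (or user-supplied, e.g. XOR/parity) seed table.

Synthetic annotations place the planted functional SNPs either in one shared
gene (``co_located``), in distinct genes (``scattered``), or nowhere
(``no_info``), to exercise locus-driven initialization in both regimes.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SimulationError
from .genotype_data import AnnotationTable, GenotypeDataset

__all__ = [
    "PenetranceModel",
    "SimTruth",
    "hwe_genotype_freqs",
    "parity_table",
    "make_no_marginal_model",
    "make_marginal_model",
    "make_null_model",
    "simulate_dataset",
    "simulate_annotations",
    "write_manifest",
]


def hwe_genotype_freqs(maf: float) -> tuple[float, float, float]:
    """Hardy-Weinberg genotype frequencies ((1-q)^2, 2q(1-q), q^2) for q = maf."""
    if not 0.0 <= maf <= 0.5:
        raise ValueError(f"maf must be in [0, 0.5], got {maf}")
    q = maf
    return ((1.0 - q) ** 2, 2.0 * q * (1.0 - q), q * q)


@dataclass
class PenetranceModel:
    """A k-locus penetrance table with its MAFs and implied prevalence.

    ``table[g1, ..., gk]`` is P(disease | joint genotype); ``prevalence`` is
    the HWE-weighted mean penetrance, recomputed on construction.
    """

    k: int
    mafs: tuple[float, ...]
    table: np.ndarray
    marginal_effect_flag: bool = True
    prevalence: float = field(init=False)

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=np.float64)
        if self.table.shape != (3,) * self.k:
            raise ValueError(f"table shape {self.table.shape} != {(3,) * self.k}")
        if len(self.mafs) != self.k:
            raise ValueError("need one MAF per functional locus")
        if (self.table < -1e-12).any() or (self.table > 1 + 1e-12).any():
            raise ValueError("penetrances must lie in [0, 1]")
        self.table = np.clip(self.table, 0.0, 1.0)
        self.prevalence = float(
            (self._joint_hwe_weights() * self.table).sum()
        )

    def _locus_weights(self) -> list[np.ndarray]:
        return [np.array(hwe_genotype_freqs(q)) for q in self.mafs]

    def _joint_hwe_weights(self) -> np.ndarray:
        w = self._locus_weights()
        joint = w[0]
        for wj in w[1:]:
            joint = np.multiply.outer(joint, wj)
        return joint

    def marginal_penetrance(self, locus: int) -> np.ndarray:
        """HWE-weighted P(disease | g_locus = s) for s in {0, 1, 2}."""
        joint = self._joint_hwe_weights()
        axes = tuple(a for a in range(self.k) if a != locus)
        num = np.moveaxis(joint * self.table, locus, 0).sum(axis=tuple(range(1, self.k)))
        den = np.moveaxis(joint, locus, 0).sum(axis=tuple(range(1, self.k)))
        del axes
        return num / den

    def max_marginal_deviation(self) -> float:
        """max over loci and genotype values of |marginal penetrance - prevalence|."""
        return max(
            float(np.abs(self.marginal_penetrance(j) - self.prevalence).max())
            for j in range(self.k)
        )


def parity_table(k: int = 2, h: float = 1.0) -> np.ndarray:
    """XOR/parity penetrance seed: f(g) = h when sum(g) is odd, else 0.

    At MAF 0.5 this table has exactly equal per-locus marginals for any k.
    """
    idx = np.indices((3,) * k).sum(axis=0)
    return np.where(idx % 2 == 1, h, 0.0)


def make_marginal_model(
    k: int, mafs, baseline: float, effect: float
) -> PenetranceModel:
    """Multiplicative-risk model, ``f(g) = baseline * (1+effect)^sum(g)``."""
    mafs = tuple(float(q) for q in mafs)
    top = baseline * (1.0 + effect) ** (2 * k)
    if top > 1.0 + 1e-12:
        raise ValueError(
            f"penetrance overflows 1 (baseline*(1+effect)^(2k) = {top:.4g})"
        )
    idx = np.indices((3,) * k).sum(axis=0)
    table = baseline * (1.0 + effect) ** idx
    return PenetranceModel(k=k, mafs=mafs, table=table, marginal_effect_flag=True)


def make_null_model(k: int, mafs, penetrance: float) -> PenetranceModel:
    """Constant-penetrance model: disease independent of genotype."""
    return PenetranceModel(
        k=k,
        mafs=tuple(float(q) for q in mafs),
        table=np.full((3,) * k, float(penetrance)),
        marginal_effect_flag=False,
    )


def make_no_marginal_model(
    k: int,
    mafs,
    prevalence: float,
    tol: float = 1e-6,
    rng: np.random.Generator | None = None,
    seed_table: np.ndarray | None = None,
    max_cycles: int = 20_000,
    max_restarts: int = 50,
) -> PenetranceModel:
    """Construct a penetrance table with no single-locus marginal effect.

    Starting from ``seed_table`` (or a random table), cycles of additive
    projection force every HWE-weighted per-locus marginal penetrance onto
    the target ``prevalence`` (subtracting the slice's deviation, then
    clipping to [0, 1]). The constant table f = prevalence always satisfies
    the constraints, so the feasible set is non-empty; a seed far from
    constant converges to a nearby feasible table that retains its
    interaction signal. A seed that already satisfies the constraints (e.g.
    the XOR table at MAF 0.5 with matching prevalence) is accepted unchanged.

    Raises :class:`~ldhs.errors.SimulationError` when no acceptable table is
    found within ``max_cycles`` cycles over ``max_restarts`` random restarts.
    """
    if k < 2:
        raise ValueError("no-marginal models need k >= 2")
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0, 1)")
    mafs = tuple(float(q) for q in mafs)
    if rng is None:
        rng = np.random.default_rng()
    weights = [np.array(hwe_genotype_freqs(q)) for q in mafs]

    def joint_weights() -> np.ndarray:
        joint = weights[0]
        for wj in weights[1:]:
            joint = np.multiply.outer(joint, wj)
        return joint

    jw = joint_weights()

    def project(table: np.ndarray) -> np.ndarray | None:
        f = table.astype(np.float64).copy()
        for _ in range(max_cycles):
            max_dev = 0.0
            for j in range(k):
                # conditional weights within each slice g_j = s sum to 1
                jw_j = np.moveaxis(jw, j, 0)
                f_j = np.moveaxis(f, j, 0)
                slice_w = jw_j / jw_j.sum(axis=tuple(range(1, k)), keepdims=True)
                marg = (slice_w * f_j).sum(axis=tuple(range(1, k)))
                dev = marg - prevalence
                max_dev = max(max_dev, float(np.abs(dev).max()))
                f_j -= dev.reshape((3,) + (1,) * (k - 1))
                np.clip(f, 0.0, 1.0, out=f)
            if max_dev < tol:
                model = PenetranceModel(
                    k=k, mafs=mafs, table=f, marginal_effect_flag=False
                )
                if model.max_marginal_deviation() < tol:
                    return f
        return None

    best_dev = np.inf
    seeds = [seed_table] if seed_table is not None else []
    for restart in range(max_restarts):
        if restart < len(seeds):
            start = np.asarray(seeds[restart], dtype=np.float64)
            if start.shape != (3,) * k:
                raise ValueError("seed_table has wrong shape")
        else:
            start = rng.uniform(0.0, min(1.0, 2.0 * prevalence), size=(3,) * k)
        f = project(start)
        if f is not None:
            return PenetranceModel(k=k, mafs=mafs, table=f, marginal_effect_flag=False)
        probe = PenetranceModel(k=k, mafs=mafs, table=np.clip(start, 0, 1))
        best_dev = min(best_dev, probe.max_marginal_deviation())
    raise SimulationError(
        f"no zero-marginal table found (k={k}, mafs={mafs}, prevalence={prevalence}, "
        f"tol={tol}); best residual marginal deviation {best_dev:.3g}"
    )


@dataclass
class SimTruth:
    """Ground truth of one simulated dataset: the planted functional SNP set."""

    functional: tuple[int, ...]
    model: PenetranceModel
    seed: int | None = None

    def __post_init__(self) -> None:
        self.functional = tuple(sorted(int(i) for i in self.functional))
        if len(self.functional) != self.model.k:
            raise ValueError("functional set size must equal the model order k")


def simulate_dataset(
    model: PenetranceModel,
    n_case: int,
    n_control: int,
    m: int,
    rng: np.random.Generator,
    background_maf_range: tuple[float, float] = (0.05, 0.5),
    functional_indices=None,
    max_rejection_factor: int = 1_000_000,
    seed: int | None = None,
) -> tuple[GenotypeDataset, SimTruth]:
    """Simulate a case-control dataset with one planted interaction.

    Functional genotypes are drawn under HWE per locus; disease status is
    Bernoulli in the penetrance of the joint genotype; rejection sampling
    fills the case and control quotas exactly. The remaining ``m - k`` SNPs
    are i.i.d. HWE background with MAFs uniform in ``background_maf_range``,
    independent of status. Sample order is a random permutation of cases and
    controls.
    """
    k = model.k
    if m < k:
        raise ValueError(f"m={m} < k={k}")
    if n_case < 0 or n_control < 0:
        raise ValueError("sample quotas must be >= 0")
    if functional_indices is None:
        functional = tuple(sorted(int(i) for i in rng.choice(m, size=k, replace=False)))
    else:
        functional = tuple(sorted(int(i) for i in functional_indices))
        if len(functional) != k or functional[0] < 0 or functional[-1] >= m:
            raise ValueError("functional_indices must be k distinct indices in range")

    locus_probs = [np.array(hwe_genotype_freqs(q)) for q in model.mafs]
    need_case, need_control = n_case, n_control
    case_rows: list[np.ndarray] = []
    control_rows: list[np.ndarray] = []
    total = n_case + n_control
    cap = max_rejection_factor * max(total, 1)
    drawn = 0
    batch = max(4 * total, 256)
    while need_case > 0 or need_control > 0:
        if drawn >= cap:
            raise SimulationError(
                f"case/control quotas unfillable after {drawn} draws "
                f"(prevalence {model.prevalence:.3g})"
            )
        size = min(batch, cap - drawn)
        drawn += size
        g = np.stack(
            [rng.choice(3, size=size, p=p) for p in locus_probs], axis=1
        ).astype(np.int8)
        f = model.table[tuple(g[:, j] for j in range(k))]
        disease = rng.random(size) < f
        if need_case > 0:
            rows = g[disease][:need_case]
            case_rows.append(rows)
            need_case -= len(rows)
        if need_control > 0:
            rows = g[~disease][:need_control]
            control_rows.append(rows)
            need_control -= len(rows)

    func_geno = np.concatenate(
        case_rows + control_rows if case_rows or control_rows else [np.zeros((0, k), np.int8)]
    )
    labels = np.concatenate([np.ones(n_case, np.int8), np.zeros(n_control, np.int8)])

    geno = np.empty((total, m), dtype=np.int8)
    background = [j for j in range(m) if j not in set(functional)]
    for j in background:
        maf = rng.uniform(*background_maf_range)
        geno[:, j] = rng.choice(3, size=total, p=hwe_genotype_freqs(maf))
    for pos, j in enumerate(functional):
        geno[:, j] = func_geno[:, pos]

    perm = rng.permutation(total)
    geno = geno[perm]
    labels = labels[perm]
    snp_ids = [f"SNP{j}" for j in range(m)]
    dataset = GenotypeDataset(snp_ids=snp_ids, genotypes=geno, labels=labels)
    return dataset, SimTruth(functional=functional, model=model, seed=seed)


def simulate_annotations(
    m: int,
    truth: SimTruth,
    scenario: str,
    rng: np.random.Generator,
    gene_size: int = 4,
    n_decoy_genes: int = 7,
    promoter_fraction: float = 0.25,
) -> AnnotationTable:
    """Synthetic annotations placing the planted SNPs per scenario.

    ``co_located``: all functional SNPs share one gene (padded with decoy
    members up to ``gene_size``); ``scattered``: each functional SNP sits in
    its own gene; ``no_info``: an empty table. Decoy genes of ``gene_size``
    non-functional SNPs are added in all informative scenarios; unannotated
    SNPs default to intergenic downstream.
    """
    if scenario not in ("co_located", "scattered", "no_info"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if scenario == "no_info":
        return AnnotationTable()
    functional = list(truth.functional)
    others = [j for j in range(m) if j not in set(functional)]
    rng.shuffle(others)
    rows: list[tuple] = []
    pool = iter(others)

    def category() -> str:
        return "promoter" if rng.random() < promoter_fraction else "coding"

    genes: list[list[int]] = []
    if scenario == "co_located":
        members = list(functional)
        while len(members) < gene_size:
            members.append(next(pool))
        genes.append(members)
    else:  # scattered
        for f in functional:
            members = [f]
            while len(members) < gene_size:
                members.append(next(pool))
            genes.append(members)
    for _ in range(n_decoy_genes):
        members = list(itertools.islice(pool, gene_size))
        if members:
            genes.append(members)

    for gi, members in enumerate(genes):
        for snp in members:
            rows.append((f"SNP{snp}", "1", (snp + 1) * 1000, f"GENE{gi}", category()))
    df = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "region_id", "category"])
    return AnnotationTable(records=df)


def write_manifest(path, truth: SimTruth, genotype_path: str, annotation_path: str | None, scenario: str) -> None:
    """Record simulation ground truth (model, planted set, file paths) as JSON."""
    payload = {
        "functional": list(truth.functional),
        "k": truth.model.k,
        "mafs": list(truth.model.mafs),
        "prevalence": truth.model.prevalence,
        "marginal_effect": truth.model.marginal_effect_flag,
        "penetrance_table": truth.model.table.tolist(),
        "seed": truth.seed,
        "genotypes": genotype_path,
        "annotations": annotation_path,
        "scenario": scenario,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
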