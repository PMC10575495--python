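"""Multi-population harmony search with locus-driven memory initialization (LDHS core).

Four harmony memories — one per objective (K2, LR, JS, NDJE) — each hold
``hms`` candidate SNP sets. Memories are initialized partly at random and
partly from locus-driven draws (SNPs sharing a gene/region, weighted toward
functional categories), which is the mechanism that rescues search on disease
models without marginal effects: the objective landscape is flat around the
true combination, so the search cannot be guided toward it, but biologically
co-located SNPs have an elevated prior of landing in the same initial harmony.

Each iteration improvises one candidate per memory (memory consideration at
rate ``hmcr``, pitch adjustment of +-1 on the SNP index at rate ``par``,
uniform random otherwise), scores it once (a shared cache makes every unique
set cost exactly one evaluation across all four memories), and replaces the
memory's worst member when strictly better. A stage-2 verification applies
the G-test and Pearson chi-square with Bonferroni correction to the union of
final memory members and the all-time best set per objective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .genotype_data import AnnotationTable, GenotypeDataset
from .locus_grouping import SnpGrouping, allocate_harmonies, group_snps, sample_locus_harmony
from .objectives import (
    DEFAULT_DIRECTIONS,
    OBJECTIVES,
    EvalCounter,
    ScoreVector,
    TestResult,
    association_tests,
    canonical_set,
    score_all,
)


@dataclass
class SearchConfig:
    """Tunable parameters of the locus-driven harmony search.

    Defaults follow the standard multi-population setting for this problem
    (HMS 10 per memory, HMCR 0.98, PAR 0.35) and the grid-searched category
    weight w = 2.
    """

    k: int = 2
    hms: int = 10
    hmcr: float = 0.98
    par: float = 0.35
    w: float = 2.0
    locus_fraction: float = 0.5
    max_evals: int = 5000
    alpha: float = 0.05
    seed: int | None = None
    directions: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_DIRECTIONS))
    uniform_group_choice: bool = False
    group_aware_pitch: bool = False
    stop_on_target: tuple[int, ...] | None = None
    stagnation_limit: int = 20
    max_iters: int | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.hms < 1:
            raise ValueError("hms must be >= 1")
        if not 0.0 <= self.hmcr <= 1.0:
            raise ValueError("hmcr must be in [0, 1]")
        if not 0.0 <= self.par <= 1.0:
            raise ValueError("par must be in [0, 1]")
        if not 0.0 <= self.locus_fraction <= 1.0:
            raise ValueError("locus_fraction must be in [0, 1]")
        if self.w < 1:
            raise ValueError("w must be >= 1")
        if self.max_evals < 1:
            raise ValueError("max_evals must be >= 1")
        unknown = set(self.directions) - set(OBJECTIVES)
        if unknown:
            raise ValueError(f"unknown objectives in directions: {unknown}")
        if self.stop_on_target is not None:
            self.stop_on_target = canonical_set(self.stop_on_target)


@dataclass
class Harmony:
    """One candidate solution: a canonical k-set of SNP indices plus its scores."""

    snp_set: tuple[int, ...]
    scores: ScoreVector

    def value(self, objective: str) -> float:
        return self.scores[objective]


def _sort_key(value: float, direction: str) -> float:
    """Ranking key (smaller = better); non-finite values always rank worst."""
    if not math.isfinite(value):
        return math.inf
    return value if direction == "min" else -value


@dataclass
class HarmonyMemory:
    """A ranked pool of harmonies for one objective."""

    objective_id: str
    direction: str
    harmonies: list[Harmony] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._members = {h.snp_set for h in self.harmonies}
        self._sort()

    def _sort(self) -> None:
        self.harmonies.sort(key=lambda h: _sort_key(h.value(self.objective_id), self.direction))

    def __contains__(self, snp_set: tuple[int, ...]) -> bool:
        return snp_set in self._members

    def __len__(self) -> int:
        return len(self.harmonies)

    @property
    def best(self) -> Harmony:
        return self.harmonies[0]

    @property
    def worst(self) -> Harmony:
        return self.harmonies[-1]

    def add(self, harmony: Harmony) -> None:
        if harmony.snp_set in self._members:
            raise ValueError(f"duplicate snp_set in memory: {harmony.snp_set}")
        self.harmonies.append(harmony)
        self._members.add(harmony.snp_set)
        self._sort()


def update_memory(memory: HarmonyMemory, candidate: Harmony) -> bool:
    """Replace the memory's worst member when the candidate is strictly better.

    Ties keep the incumbent; a candidate whose set is already in the memory
    is never inserted. Returns True iff a replacement happened.
    """
    if candidate.snp_set in memory:
        return False
    cand_key = _sort_key(candidate.value(memory.objective_id), memory.direction)
    worst = memory.worst
    worst_key = _sort_key(worst.value(memory.objective_id), memory.direction)
    if cand_key < worst_key:
        memory._members.discard(worst.snp_set)
        memory.harmonies[-1] = candidate
        memory._members.add(candidate.snp_set)
        memory._sort()
        return True
    return False


def improvise(
    memory: HarmonyMemory,
    config: SearchConfig,
    m: int,
    rng: np.random.Generator,
    grouping: SnpGrouping | None = None,
) -> tuple[int, ...]:
    """Improvise one candidate k-set from a memory.

    Per position: with probability ``hmcr`` copy that position's value from a
    uniformly chosen memory harmony, then with probability ``par``
    pitch-adjust it by +-1 on the SNP index (wrapping at the bounds; with
    ``group_aware_pitch`` the step moves within the value's locus group
    instead); otherwise draw uniformly. Duplicate indices are repaired by
    uniform redraw, so the result always has ``k`` distinct indices.
    """
    k = config.k
    values: list[int] = []
    pool = memory.harmonies
    for pos in range(k):
        if rng.random() < config.hmcr:
            v = pool[int(rng.integers(len(pool)))].snp_set[pos]
            if rng.random() < config.par:
                v = _pitch_adjust(v, m, rng, config, grouping)
        else:
            v = int(rng.integers(m))
        values.append(int(v))
    seen = set()
    out = []
    for v in values:
        while v in seen:
            v = int(rng.integers(m))
        seen.add(v)
        out.append(v)
    return tuple(sorted(out))


def _pitch_adjust(
    v: int,
    m: int,
    rng: np.random.Generator,
    config: SearchConfig,
    grouping: SnpGrouping | None,
) -> int:
    if config.group_aware_pitch and grouping is not None:
        for members in grouping.locus_groups.values():
            if v in members and len(members) > 1:
                others = [x for x in members if x != v]
                return int(others[int(rng.integers(len(others)))])
    step = 1 if rng.random() < 0.5 else -1
    return (v + step) % m


def random_distinct_set(m: int, k: int, rng: np.random.Generator) -> tuple[int, ...]:
    """A uniform random canonical k-subset of 0..m-1."""
    return tuple(sorted(int(x) for x in rng.choice(m, size=k, replace=False)))


class _ScoreCache:
    """Shared score cache; its size is the unique-evaluation count."""

    def __init__(self, dataset: GenotypeDataset):
        self.dataset = dataset
        self.cache: dict[tuple[int, ...], ScoreVector] = {}
        self.counter = EvalCounter()

    def __contains__(self, snp_set: tuple[int, ...]) -> bool:
        return snp_set in self.cache

    def score(self, snp_set: tuple[int, ...]) -> ScoreVector:
        sv = self.cache.get(snp_set)
        if sv is None:
            sv = score_all(self.dataset, snp_set, counter=self.counter)
            self.cache[snp_set] = sv
        return sv

    @property
    def eval_count(self) -> int:
        return self.counter.count


def init_memories(
    dataset: GenotypeDataset,
    grouping: SnpGrouping,
    config: SearchConfig,
    rng: np.random.Generator,
    cache: _ScoreCache | None = None,
) -> list[HarmonyMemory]:
    """Initialize the four harmony memories.

    Each memory receives ``round(locus_fraction * hms)`` locus-driven harmonies
    (allocated between the two categories by :func:`allocate_harmonies`) and
    uniform random harmonies for the rest, all distinct within the memory.
    Scores are shared across memories through the evaluation cache. When
    ``C(m, k) < hms`` the memory is filled with every distinct set instead
    (degraded mode).
    """
    m = dataset.m
    k = config.k
    if m < k:
        raise ValueError(f"dataset has m={m} SNPs < k={k}")
    if cache is None:
        cache = _ScoreCache(dataset)
    total_sets = math.comb(m, k)
    memories = []
    for obj in OBJECTIVES:
        direction = config.directions.get(obj, DEFAULT_DIRECTIONS[obj])
        memory = HarmonyMemory(objective_id=obj, direction=direction)
        if total_sets < config.hms:
            import itertools

            for combo in itertools.combinations(range(m), k):
                memory.add(Harmony(combo, cache.score(combo)))
            memories.append(memory)
            continue
        n_locus = round(config.locus_fraction * config.hms)
        draws: list[tuple[int, ...]] = []
        if n_locus > 0:
            alloc = allocate_harmonies(grouping, n_locus)
            plan = [(1, alloc.category1), (2, alloc.category2)]
        else:
            plan = []
        seen: set[tuple[int, ...]] = set()
        max_tries = 200 * config.hms + 100
        for category, count in plan:
            for _ in range(count):
                for _try in range(max_tries):
                    s = sample_locus_harmony(
                        grouping, category, k, rng,
                        uniform_group_choice=config.uniform_group_choice,
                    )
                    if s not in seen:
                        break
                else:  # pragma: no cover - saturated neighborhood
                    s = _fresh_random_set(m, k, seen, rng)
                seen.add(s)
                draws.append(s)
        while len(draws) < config.hms:
            s = _fresh_random_set(m, k, seen, rng)
            seen.add(s)
            draws.append(s)
        for s in draws:
            memory.add(Harmony(s, cache.score(s)))
        memories.append(memory)
    return memories


def _fresh_random_set(
    m: int, k: int, seen: set[tuple[int, ...]], rng: np.random.Generator
) -> tuple[int, ...]:
    while True:
        s = random_distinct_set(m, k, rng)
        if s not in seen:
            return s


@dataclass
class CandidateRecord:
    """A verified SNP set with its scores and test results."""

    snp_set: tuple[int, ...]
    snp_ids: tuple[str, ...]
    scores: ScoreVector
    test: TestResult


@dataclass
class SearchResult:
    """Outcome of one LDHS run."""

    candidates: list[CandidateRecord]
    verified: list[CandidateRecord]
    eval_count: int
    trace: list[dict[str, float]]
    best_per_objective: dict[str, Harmony]
    stop_reason: str
    evals_to_target: int | None = None
    target_found: bool = False


def run_ldhs(
    dataset: GenotypeDataset,
    annotations: AnnotationTable | None,
    config: SearchConfig,
) -> SearchResult:
    """Run the locus-driven multi-population harmony search end to end.

    Stage 1 iterates improvise/score/update over the four memories until the
    unique-evaluation budget (capped at ``C(m, k)``) is spent, the iteration
    safety cap is hit, or — when ``config.stop_on_target`` is set — the
    planted set enters a memory. When improvisation stagnates (repeatedly
    proposing already-scored sets) a uniform random set is drawn instead, so
    the budget is always spent on distinct candidates.

    Stage 2 verifies the union of all final memory members plus the all-time
    best set per objective with the G-test and Pearson chi-square, Bonferroni
    corrected over the union size; significant sets are returned sorted by
    G-test p-value.
    """
    rng = np.random.default_rng(config.seed)
    grouping = group_snps(annotations, dataset.snp_ids, w=config.w)
    cache = _ScoreCache(dataset)
    memories = init_memories(dataset, grouping, config, rng, cache=cache)

    target = config.stop_on_target
    best: dict[str, Harmony] = {}

    def note_best(h: Harmony) -> None:
        for mem in memories:
            b = best.get(mem.objective_id)
            if b is None or _sort_key(h.value(mem.objective_id), mem.direction) < _sort_key(
                b.value(mem.objective_id), mem.direction
            ):
                best[mem.objective_id] = h

    for mem in memories:
        for h in mem.harmonies:
            note_best(h)

    total_sets = math.comb(dataset.m, config.k)
    budget = min(config.max_evals, total_sets)
    max_iters = config.max_iters if config.max_iters is not None else max(10_000, 60 * budget)

    evals_to_target: int | None = None
    target_found = target is not None and any(target in mem for mem in memories)
    if target_found:
        evals_to_target = cache.eval_count
    stop_reason = "budget"
    trace: list[dict[str, float]] = []
    stagnation = 0
    iters = 0
    while not (target is not None and target_found):
        if cache.eval_count >= budget:
            stop_reason = "budget" if budget == config.max_evals else "exhausted_space"
            break
        if iters >= max_iters:
            stop_reason = "max_iters"
            break
        iters += 1
        for mem in memories:
            if cache.eval_count >= budget:
                break
            if stagnation >= config.stagnation_limit:
                cand = random_distinct_set(dataset.m, config.k, rng)
                stagnation = 0
            else:
                cand = improvise(mem, config, dataset.m, rng, grouping=grouping)
            if cand in cache:
                stagnation += 1
                sv = cache.score(cand)
            else:
                stagnation = 0
                sv = cache.score(cand)
            h = Harmony(cand, sv)
            note_best(h)
            update_memory(mem, h)
            if target is not None and not target_found and target in mem:
                target_found = True
                evals_to_target = cache.eval_count
                break
        trace.append(
            {mem.objective_id: mem.best.value(mem.objective_id) for mem in memories}
        )
    if target is not None and target_found:
        stop_reason = "target"

    # stage 2: verification of final memories plus all-time bests
    union: dict[tuple[int, ...], ScoreVector] = {}
    for mem in memories:
        for h in mem.harmonies:
            union[h.snp_set] = h.scores
    for h in best.values():
        union[h.snp_set] = h.scores
    n_candidates = max(len(union), 1)
    verified: list[CandidateRecord] = []
    for snp_set, sv in union.items():
        test = association_tests(dataset, snp_set, n_candidates=n_candidates, alpha=config.alpha)
        verified.append(
            CandidateRecord(
                snp_set=snp_set,
                snp_ids=tuple(dataset.snp_ids[i] for i in snp_set),
                scores=sv,
                test=test,
            )
        )
    verified.sort(key=lambda r: r.test.g_pvalue)
    candidates = [r for r in verified if r.test.significant]
    return SearchResult(
        candidates=candidates,
        verified=verified,
        eval_count=cache.eval_count,
        trace=trace,
        best_per_objective=best,
        stop_reason=stop_reason,
        evals_to_target=evals_to_target,
        target_found=target_found,
    )
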