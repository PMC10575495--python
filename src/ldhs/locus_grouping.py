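"""SNP grouping by genomic locus/functional category and weighted harmony allocation.

Physically close genomic content tends to be co-inherited (genetic linkage),
and a disease-causing SNP combination must be co-inherited to act jointly.
SNPs sharing a gene/region are therefore promising co-members of a candidate
interaction, and SNPs in functional sequence (coding, promoter,
upstream/downstream) carry a higher prior than intronic/intergenic ones.

This module turns an annotation table into:

* locus groups — SNPs sharing a ``region_id``;
* two functional categories — category 1 (coding/promoter/upstream/downstream)
  and category 2 (everything else, including unannotated SNPs);

and allocates a quota of locus-driven harmonies between the two categories in
proportion to their sizes, with category 2 down-weighted by a divisor ``w``
(default 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AllocationError
from .genotype_data import AnnotationTable

#: Functional categories assigned to category 1 (higher prior).
CATEGORY1_CATEGORIES = frozenset({"coding", "promoter", "upstream", "downstream"})


@dataclass
class SnpGrouping:
    """Locus groups and the two functional categories over a dataset's SNPs."""

    locus_groups: dict[str, list[int]]
    category1: list[int]
    category2: list[int]
    w: float = 2.0
    m: int = 0

    def __post_init__(self) -> None:
        if self.w < 1:
            raise ValueError("w must be >= 1")
        if set(self.category1) & set(self.category2):
            raise ValueError("category1 and category2 must be disjoint")


@dataclass
class HarmonyAllocation:
    """Number of locus-driven harmonies to draw from each category."""

    category1: int
    category2: int

    @property
    def quota(self) -> int:
        return self.category1 + self.category2


def group_snps(
    annotations: AnnotationTable | None, snp_ids: list[str], w: float = 2.0
) -> SnpGrouping:
    """Group a dataset's SNPs by region co-membership and functional category.

    SNPs absent from ``annotations`` (or with a null region) form no locus
    group and default to category 2 (intergenic prior). Deterministic for
    fixed input.
    """
    lookup = annotations.lookup() if annotations is not None else {}
    locus_groups: dict[str, list[int]] = {}
    cat1: list[int] = []
    cat2: list[int] = []
    for idx, snp in enumerate(snp_ids):
        region, category = lookup.get(snp, (None, "intergenic"))
        if region is not None:
            locus_groups.setdefault(region, []).append(idx)
        (cat1 if category in CATEGORY1_CATEGORIES else cat2).append(idx)
    return SnpGrouping(
        locus_groups=locus_groups, category1=cat1, category2=cat2, w=w, m=len(snp_ids)
    )


def allocate_harmonies(grouping: SnpGrouping, quota: int) -> HarmonyAllocation:
    """Split a harmony quota between the two categories, largest-remainder rounded.

    Effective sizes are ``s1 = |category1|`` and ``s2 = |category2| / w``;
    the share of category c is ``quota * s_c / (s1 + s2)``. Rounding is by
    largest remainder (ties go to the larger effective size, then to
    category 1), so the counts always sum exactly to ``quota``.
    """
    if quota < 0:
        raise ValueError("quota must be >= 0")
    if quota == 0:
        return HarmonyAllocation(0, 0)
    s = [len(grouping.category1), len(grouping.category2) / grouping.w]
    total = s[0] + s[1]
    if total == 0:
        raise AllocationError("cannot allocate harmonies: no SNPs in either category")
    exact = [quota * si / total for si in s]
    floors = [int(np.floor(x)) for x in exact]
    remainder = quota - sum(floors)
    # order categories by (remainder, effective size, prefer category 1)
    order = sorted(range(2), key=lambda c: (exact[c] - floors[c], s[c], -c), reverse=True)
    for c in order[:remainder]:
        floors[c] += 1
    return HarmonyAllocation(category1=floors[0], category2=floors[1])


def sample_locus_harmony(
    grouping: SnpGrouping,
    category: int,
    k: int,
    rng: np.random.Generator,
    uniform_group_choice: bool = False,
) -> tuple[int, ...]:
    """Draw one locus-driven candidate SNP set of size ``k``.

    Category 1 picks a locus group (probability proportional to group size by
    default) and samples up to ``k`` distinct members from it; category 2
    samples from the category-2 pool. Whenever the chosen neighborhood is
    smaller than ``k``, the remainder is filled uniformly at random from all
    SNPs, so the result always holds ``k`` distinct indices.
    """
    m = grouping.m
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > m:
        raise ValueError(f"k={k} exceeds the number of SNPs m={m}")
    chosen: list[int] = []
    if category == 1:
        groups = [g for g in grouping.locus_groups.values() if g]
        if groups:
            sizes = np.array([len(g) for g in groups], dtype=float)
            p = None if uniform_group_choice else sizes / sizes.sum()
            gi = int(rng.choice(len(groups), p=p))
            members = groups[gi]
            take = min(k, len(members))
            chosen = [int(x) for x in rng.choice(members, size=take, replace=False)]
        elif grouping.category1:
            pool = grouping.category1
            take = min(k, len(pool))
            chosen = [int(x) for x in rng.choice(pool, size=take, replace=False)]
    elif category == 2:
        pool = grouping.category2
        if pool:
            take = min(k, len(pool))
            chosen = [int(x) for x in rng.choice(pool, size=take, replace=False)]
    else:
        raise ValueError("category must be 1 or 2")
    # fill any shortfall uniformly from the whole SNP universe
    if len(chosen) < k:
        used = set(chosen)
        rest = np.array([i for i in range(m) if i not in used])
        extra = rng.choice(rest, size=k - len(chosen), replace=False)
        chosen.extend(int(x) for x in extra)
    return tuple(sorted(chosen))
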