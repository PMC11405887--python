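"""Counterbalanced gel-loading design.

Polyacrylamide gels are not spatially uniform, and separate gel runs differ
systematically; if an experimental group is missing from a gel, or clustered
in adjacent lanes, those technical gradients are confounded with the group
effect.  The generator here enforces the two counterbalancing rules:

1. every experimental group is represented on every gel (whenever group sizes
   permit), with per-gel quotas as even as possible;
2. samples from the same group are not loaded in adjacent lanes whenever a
   zero-adjacency arrangement exists.

The molecular-weight ladder occupies lane 1 of each gel, loaded lanes are
centered in the remaining lanes, and the whole layout is re-randomized
independently for each technical replicate (each replicate is a fresh gel
run) unless ``same_layout_across_replicates`` is set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InfeasibleDesignError
from .io import Sample

__all__ = [
    "LADDER",
    "EMPTY",
    "DesignSpec",
    "LaneAssignment",
    "GelMap",
    "GelPlan",
    "plan_gels",
    "order_lanes",
    "generate_gel_map",
    "count_adjacency_violations",
]

LADDER = "LADDER"
EMPTY = "EMPTY"


@dataclass(frozen=True)
class DesignSpec:
    """Parameters of one gel-loading design."""

    samples: tuple[Sample, ...]
    lanes_per_gel: int
    n_replicates: int = 3
    ladder_in_first_lane: bool = True
    same_layout_across_replicates: bool = False
    seed: int = 0

    def __init__(self, samples, lanes_per_gel, n_replicates=3,
                 ladder_in_first_lane=True, same_layout_across_replicates=False,
                 seed=0):
        object.__setattr__(self, "samples", tuple(samples))
        object.__setattr__(self, "lanes_per_gel", int(lanes_per_gel))
        object.__setattr__(self, "n_replicates", int(n_replicates))
        object.__setattr__(self, "ladder_in_first_lane", bool(ladder_in_first_lane))
        object.__setattr__(self, "same_layout_across_replicates",
                           bool(same_layout_across_replicates))
        object.__setattr__(self, "seed", int(seed))
        if self.lanes_per_gel < 3:
            raise InfeasibleDesignError("lanes_per_gel must be >= 3")
        if self.usable_lanes < 2:
            raise InfeasibleDesignError(
                "at least 2 usable (non-ladder) lanes are required"
            )
        if self.n_replicates < 1:
            raise InfeasibleDesignError("n_replicates must be >= 1")

    @property
    def usable_lanes(self) -> int:
        return self.lanes_per_gel - (1 if self.ladder_in_first_lane else 0)

    @property
    def group_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for s in self.samples:
            sizes[s.group] = sizes.get(s.group, 0) + 1
        return sizes


@dataclass(frozen=True)
class LaneAssignment:
    """Content of one lane on one gel of one replicate run."""

    replicate: int
    gel_index: int
    lane: int
    content: Sample | str  # a Sample, or the LADDER / EMPTY markers


@dataclass
class GelPlan:
    """How many gels a replicate needs and which groups go on which gel."""

    n_gels: int
    quota: dict[tuple[int, str], int]  # (gel_index 1-based, group) -> count
    warnings: list[str] = field(default_factory=list)

    def gel_quota(self, gel_index: int) -> dict[str, int]:
        return {
            g: n for (i, g), n in self.quota.items() if i == gel_index and n > 0
        }


@dataclass
class GelMap:
    """A complete loading plan: every lane of every gel of every replicate."""

    spec: DesignSpec
    assignments: list[LaneAssignment]
    n_gels_per_replicate: int
    warnings: list[str] = field(default_factory=list)

    def sample_assignments(self) -> list[LaneAssignment]:
        """Loaded (sample-carrying) lanes ordered by replicate, gel, lane."""
        out = [a for a in self.assignments if isinstance(a.content, Sample)]
        out.sort(key=lambda a: (a.replicate, a.gel_index, a.lane))
        return out

    def gel_lanes(self, replicate: int, gel_index: int) -> list[LaneAssignment]:
        out = [
            a
            for a in self.assignments
            if a.replicate == replicate and a.gel_index == gel_index
        ]
        out.sort(key=lambda a: a.lane)
        return out


def plan_gels(
    n_samples: int,
    group_sizes: Mapping[str, int],
    usable_lanes: int,
) -> GelPlan:
    """Decide the number of gels and the per-gel group quotas.

    The number of gels is the minimum that fits all samples
    (``ceil(n_samples / usable_lanes)``).  Each group is split across gels as
    evenly as possible (per-gel quotas differing by at most 1), and the
    remainders are oriented so that per-gel lane totals are as even as
    possible.  A group smaller than the gel count cannot appear on every gel;
    that is reported as a warning, not an error.
    """
    if any(c <= 0 for c in group_sizes.values()):
        raise InfeasibleDesignError("group sizes must be positive")
    if sum(group_sizes.values()) != n_samples:
        raise InfeasibleDesignError("group sizes must sum to n_samples")
    n_groups = len(group_sizes)
    if usable_lanes < n_groups:
        raise InfeasibleDesignError(
            f"{usable_lanes} usable lanes cannot hold one sample from each of "
            f"{n_groups} groups"
        )
    n_gels = math.ceil(n_samples / usable_lanes)

    warnings = []
    quota: dict[tuple[int, str], int] = {}
    totals = [0] * n_gels  # loaded-lane count per gel
    # Largest groups first so their remainders are placed while totals are
    # still flexible.
    for group in sorted(group_sizes, key=lambda g: (-group_sizes[g], g)):
        size = group_sizes[group]
        base, extra = divmod(size, n_gels)
        if size < n_gels:
            warnings.append(
                f"group {group!r} has {size} sample(s) but {n_gels} gels are "
                "needed; it cannot appear on every gel"
            )
        for gel in range(n_gels):
            quota[(gel + 1, group)] = base
            totals[gel] += base
        # put the `extra` surplus samples on the currently lightest gels
        order = sorted(range(n_gels), key=lambda g: (totals[g], g))
        for gel in order[:extra]:
            quota[(gel + 1, group)] += 1
            totals[gel] += 1
    if max(totals) > usable_lanes:
        # only possible when heavy rounding collides with near-full gels:
        # rebalance by moving surplus units to lighter gels
        _rebalance_overflow(quota, totals, usable_lanes, n_gels)
    return GelPlan(n_gels=n_gels, quota=quota, warnings=warnings)


def _rebalance_overflow(quota, totals, usable_lanes, n_gels):
    """Move single-sample units from overfull to underfull gels, keeping each
    group's per-gel quotas within a spread of 1."""
    for _ in range(10 * n_gels):
        hi = max(range(n_gels), key=lambda g: totals[g])
        if totals[hi] <= usable_lanes:
            return
        lo = min(range(n_gels), key=lambda g: totals[g])
        moved = False
        for (gel, group), n in sorted(quota.items()):
            if gel != hi + 1 or n == 0:
                continue
            if quota[(hi + 1, group)] > quota[(lo + 1, group)]:
                quota[(hi + 1, group)] -= 1
                quota[(lo + 1, group)] += 1
                totals[hi] -= 1
                totals[lo] += 1
                moved = True
                break
        if not moved:
            raise InfeasibleDesignError(
                "cannot fit group quotas within the available lanes"
            )


def order_lanes(
    gel_quota: Mapping[str, int], seed: int | np.random.Generator = 0
) -> tuple[list[str], int]:
    """Arrange one gel's group labels to minimize adjacent same-group pairs.

    Greedy most-remaining-first (the classic string-reorganisation argument:
    zero adjacency is achievable iff the largest count <= ceil(total/2)),
    with seeded tie-breaking and a swap-repair pass for residual adjacencies.
    Returns the sequence and its adjacent-equal-pair count.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = {g: int(n) for g, n in gel_quota.items() if n > 0}
    if any(n <= 0 for n in gel_quota.values()):
        raise InfeasibleDesignError("lane quotas must be positive")
    seq: list[str] = []
    while sum(counts.values()) > 0:
        candidates = [g for g, n in counts.items() if n > 0]
        non_adjacent = [g for g in candidates if not seq or g != seq[-1]]
        pool = non_adjacent or candidates
        top = max(counts[g] for g in pool)
        best = [g for g in pool if counts[g] == top]
        pick = best[rng.integers(len(best))]
        seq.append(pick)
        counts[pick] -= 1

    # repair pass: try swaps that strictly reduce the violation count
    def violations(s):
        return sum(a == b for a, b in zip(s, s[1:]))

    v = violations(seq)
    improved = True
    while v > 0 and improved:
        improved = False
        for i in range(len(seq) - 1):
            if seq[i] != seq[i + 1]:
                continue
            for j in range(len(seq)):
                if seq[j] == seq[i]:
                    continue
                seq[i], seq[j] = seq[j], seq[i]
                nv = violations(seq)
                if nv < v:
                    v = nv
                    improved = True
                    break
                seq[i], seq[j] = seq[j], seq[i]
            if improved:
                break
    return seq, v


def generate_gel_map(spec: DesignSpec) -> GelMap:
    """Generate the full counterbalanced loading plan for a design.

    Within each replicate run, subjects of each group are randomly
    partitioned across gels to fill the :func:`plan_gels` quotas, the lane
    order on each gel comes from :func:`order_lanes`, and the loaded block is
    centered among the usable lanes (odd slack goes to the high-numbered
    end).  Deterministic for a fixed spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    plan = plan_gels(len(spec.samples), spec.group_sizes, spec.usable_lanes)
    by_group: dict[str, list[Sample]] = {}
    for s in spec.samples:
        by_group.setdefault(s.group, []).append(s)

    assignments: list[LaneAssignment] = []
    layout_cache: list[list[tuple[int, int, Sample | str]]] | None = None

    for rep in range(1, spec.n_replicates + 1):
        if spec.same_layout_across_replicates and layout_cache is not None:
            for gel_index, lane, content in layout_cache[0]:
                assignments.append(LaneAssignment(rep, gel_index, lane, content))
            continue

        layout: list[tuple[int, int, Sample | str]] = []
        # randomly partition each group's subjects across gels per quota
        pools = {g: list(rng.permutation(len(ss))) for g, ss in by_group.items()}
        per_gel_samples: dict[int, dict[str, list[Sample]]] = {}
        for gel in range(1, plan.n_gels + 1):
            per_gel_samples[gel] = {}
            for group, n in plan.gel_quota(gel).items():
                idx = [pools[group].pop() for _ in range(n)]
                per_gel_samples[gel][group] = [by_group[group][i] for i in idx]

        for gel in range(1, plan.n_gels + 1):
            quota = plan.gel_quota(gel)
            seq, _ = order_lanes(quota, rng)
            # walk the group sequence, drawing subjects in shuffled order
            queues = {g: list(ss) for g, ss in per_gel_samples[gel].items()}
            loaded = [queues[g].pop(0) for g in seq]

            first_data_lane = 2 if spec.ladder_in_first_lane else 1
            offset = (spec.usable_lanes - len(loaded)) // 2
            if spec.ladder_in_first_lane:
                layout.append((gel, 1, LADDER))
            occupied = {}
            for i, sample in enumerate(loaded):
                occupied[first_data_lane + offset + i] = sample
            for lane in range(first_data_lane, spec.lanes_per_gel + 1):
                layout.append((gel, lane, occupied.get(lane, EMPTY)))

        for gel_index, lane, content in layout:
            assignments.append(LaneAssignment(rep, gel_index, lane, content))
        if spec.same_layout_across_replicates:
            layout_cache = [layout]

    return GelMap(
        spec=spec,
        assignments=assignments,
        n_gels_per_replicate=plan.n_gels,
        warnings=list(plan.warnings),
    )


def count_adjacency_violations(gelmap: GelMap) -> tuple[dict[tuple[int, int], int], int]:
    """Count adjacent same-group pairs per gel and in total.

    Adjacency is over consecutive *loaded* lanes: empty lanes are skipped,
    not treated as separators, because the gel gradients the rule guards
    against are smooth in space.
    """
    per_gel: dict[tuple[int, int], int] = {}
    total = 0
    reps = {a.replicate for a in gelmap.assignments}
    gels = {a.gel_index for a in gelmap.assignments}
    for rep in sorted(reps):
        for gel in sorted(gels):
            lanes = [
                a.content
                for a in gelmap.gel_lanes(rep, gel)
                if isinstance(a.content, Sample)
            ]
            v = sum(a.group == b.group for a, b in zip(lanes, lanes[1:]))
            per_gel[(rep, gel)] = v
            total += v
    return per_gel, total
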