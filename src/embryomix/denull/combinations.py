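"""Exhaustive and sampled two-group assignment ensembles.

For equally sized groups the label swap (group1 <-> group2) yields the same
two-sample test, so deduplicated enumeration anchors the first sample in
group1 and counts each partition once: 16 arrays in two groups of 8 give
6,435 assignments; 8 sibling pairs constrained to contribute one member per
group give 128.
"""

from __future__ import annotations

from itertools import combinations
from math import comb
from typing import Mapping, Sequence

import numpy as np

from .base import GroupAssignment

__all__ = ["enumerate_assignments", "count_assignments", "sample_assignments"]


def count_assignments(
    n_samples: int, group_size: int, dedupe_label_swap: bool = True
) -> int:
    """Closed-form count of two-group assignments (group sizes g and n-g)."""
    if not 0 <= group_size <= n_samples:
        raise ValueError("group_size must lie in [0, n_samples]")
    total = comb(n_samples, group_size)
    if dedupe_label_swap and 2 * group_size == n_samples:
        total //= 2
    return total


def _paired_assignments(
    samples: Sequence[str],
    pair_map: Mapping[str, str],
    dedupe_label_swap: bool,
) -> list[GroupAssignment]:
    pairs: dict[str, list[str]] = {}
    for s in samples:
        if s not in pair_map:
            raise ValueError(f"sample {s!r} missing from pair map")
        pairs.setdefault(pair_map[s], []).append(s)
    bad = [p for p, members in pairs.items() if len(members) != 2]
    if bad:
        raise ValueError(f"pairs without exactly two samples: {bad}")
    pair_list = list(pairs.values())
    out: list[GroupAssignment] = []
    n = len(pair_list)
    # each pair sends one member to group1; anchoring the first pair's first
    # member in group1 removes the label swap
    first_choices = (0,) if dedupe_label_swap else (0, 1)
    for first in first_choices:
        for bits in range(2 ** (n - 1)):
            g1 = [pair_list[0][first]]
            g2 = [pair_list[0][1 - first]]
            for i in range(1, n):
                side = (bits >> (i - 1)) & 1
                g1.append(pair_list[i][side])
                g2.append(pair_list[i][1 - side])
            out.append(GroupAssignment(tuple(g1), tuple(g2), respects_pairing=True))
    return out


def enumerate_assignments(
    samples: Sequence[str],
    group_size: int,
    dedupe_label_swap: bool = True,
    pair_map: Mapping[str, str] | None = None,
) -> list[GroupAssignment]:
    """All duplicate-free two-group assignments of ``samples``.

    With ``pair_map`` the enumeration is restricted to pairing-respecting
    assignments (one member of every sibling pair per group) and
    ``group_size`` must equal the number of pairs.
    """
    samples = list(samples)
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids")
    if pair_map is not None:
        if 2 * group_size != len(samples):
            raise ValueError("pairing-respecting groups must be equally sized")
        return _paired_assignments(samples, pair_map, dedupe_label_swap)
    if not 0 < group_size < len(samples):
        raise ValueError("group_size must lie in (0, n_samples)")
    dedupe = dedupe_label_swap and 2 * group_size == len(samples)
    out: list[GroupAssignment] = []
    if dedupe:
        # anchor samples[0] in group1 so each partition appears exactly once
        rest = samples[1:]
        for combo in combinations(rest, group_size - 1):
            g1 = (samples[0],) + combo
            g2 = tuple(s for s in samples if s not in set(g1))
            out.append(GroupAssignment(g1, g2))
    else:
        for combo in combinations(samples, group_size):
            chosen = set(combo)
            g2 = tuple(s for s in samples if s not in chosen)
            out.append(GroupAssignment(tuple(combo), g2))
    return out


def _unrank_combination(rank: int, n: int, k: int) -> tuple[int, ...]:
    """The rank-th (lexicographic, 0-based) k-combination of range(n)."""
    combo = []
    x = 0
    for remaining in range(k, 0, -1):
        while comb(n - x - 1, remaining - 1) <= rank:
            rank -= comb(n - x - 1, remaining - 1)
            x += 1
        combo.append(x)
        x += 1
    return tuple(combo)


def sample_assignments(
    samples: Sequence[str],
    group_size: int,
    k: int,
    seed: int = 20160913,
    dedupe_label_swap: bool = True,
) -> list[GroupAssignment]:
    """k distinct assignments drawn uniformly without replacement.

    Uniformity holds exactly: k distinct lexicographic combination ranks are
    drawn without replacement and unranked into group memberships.
    """
    samples = list(samples)
    n = len(samples)
    total = count_assignments(n, group_size, dedupe_label_swap)
    if k > total:
        raise ValueError(f"requested {k} assignments but only {total} exist")
    rng = np.random.default_rng(seed)
    dedupe = dedupe_label_swap and 2 * group_size == n
    out: list[GroupAssignment] = []
    if dedupe:
        # partitions <-> combinations of size group_size-1 from samples[1:]
        ranks = rng.choice(comb(n - 1, group_size - 1), size=k, replace=False)
        for r in sorted(int(r) for r in ranks):
            idx = _unrank_combination(r, n - 1, group_size - 1)
            g1 = (samples[0],) + tuple(samples[1 + i] for i in idx)
            g2 = tuple(s for s in samples if s not in set(g1))
            out.append(GroupAssignment(g1, g2))
    else:
        ranks = rng.choice(total, size=k, replace=False)
        for r in sorted(int(r) for r in ranks):
            idx = _unrank_combination(r, n, group_size)
            g1 = tuple(samples[i] for i in idx)
            g2 = tuple(s for s in samples if s not in set(g1))
            out.append(GroupAssignment(g1, g2))
    return out
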