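"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written naively (character loops, str.count over
slices, exhaustive pair counting / permutation enumeration) and shares no
arithmetic with the package code it checks.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np


def count_gc_positions(seq: str) -> int:
    """Position-by-position scan for the 'GC' dinucleotide."""
    return sum(1 for i in range(len(seq) - 1) if seq[i] == "G" and seq[i + 1] == "C")


def gc_density_oracle(seq: str) -> float:
    return count_gc_positions(seq) / len(seq)


def gc_content_oracle(seq: str) -> float:
    return sum(1 for ch in seq if ch in "GC") / len(seq)


def gc_excl_oracle(seq: str) -> float:
    return max(
        (sum(1 for ch in seq if ch in "GC") - 2 * count_gc_positions(seq)) / len(seq),
        0.0,
    )


def splice_oracle(seq: str) -> tuple[bool, bool]:
    return (not seq.startswith("GT"), not seq.endswith("AG"))


def cpg_islands_oracle(
    seq: str,
    min_gc: float = 0.55,
    min_obs_exp: float = 0.65,
    min_length: int = 500,
    window: int = 200,
    merge_gap: int = 100,
) -> list[tuple[int, int]]:
    """Naive re-derivation of the sliding-window island procedure.

    Checks every candidate interval with direct substring counting
    (str.count on slices), with no rolling sums: qualify every window,
    union runs of qualifying starts, merge near regions, trim one base
    from both ends until the whole region meets the three criteria, keep
    regions >= min_length.
    """

    def ok(s: int, e: int) -> bool:
        sub = seq[s:e]
        n = len(sub)
        c, g = sub.count("C"), sub.count("G")
        if (c + g) / n < min_gc:
            return False
        if c == 0 or g == 0:
            return False
        obs = sub.count("CG")
        exp = c * g / n
        return obs / exp >= min_obs_exp

    L = len(seq)
    if L < window:
        return []
    qualifying = [s for s in range(L - window + 1) if ok(s, s + window)]
    if not qualifying:
        return []
    regions = []
    start = prev = qualifying[0]
    for s in qualifying[1:]:
        if s != prev + 1:
            regions.append((start, prev + window))
            start = s
        prev = s
    regions.append((start, prev + window))

    merged = [list(regions[0])]
    for s, e in regions[1:]:
        if s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    out = []
    for s, e in merged:
        while e - s >= min_length and not ok(s, e):
            s, e = s + 1, e - 1
        if e - s >= min_length:
            out.append((s, e))
    return out


def auc_pair_counting(scores, labels) -> float:
    """AUC as the Mann-Whitney statistic by exhaustive pair counting.

    Every (positive, negative) pair contributes 1 if the positive
    outscores the negative, 1/2 on a tie.
    """
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def exact_rank_p_oracle(a, b) -> float:
    """Two-sided rank-test p by enumerating all label permutations.

    Uses the deviation-of-U-from-its-null-mean definition of 'at least
    as extreme'.  Exponential in n; only for tiny samples.
    """
    pooled = list(a) + list(b)
    n_a, n_b = len(a), len(b)
    mid = n_a * n_b / 2.0

    def u_of(xs, ys):
        total = 0.0
        for x in xs:
            for y in ys:
                if x > y:
                    total += 1.0
                elif x == y:
                    total += 0.5
        return total

    obs_dev = abs(u_of(a, b) - mid)
    hits = 0
    count = 0
    for perm in permutations(range(len(pooled))):
        xs = [pooled[i] for i in perm[:n_a]]
        ys = [pooled[i] for i in perm[n_a:]]
        count += 1
        if abs(u_of(xs, ys) - mid) >= obs_dev - 1e-12:
            hits += 1
    return hits / count


def conv_param_count(n_filters: int, window: int, fc_units: int) -> int:
    """Closed-form parameter count of the conv->pool->dense->softmax net."""
    conv = window * 4 * n_filters + n_filters
    fc = n_filters * fc_units + fc_units
    out = fc_units * 2 + 2
    return conv + fc + out


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=probs))
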