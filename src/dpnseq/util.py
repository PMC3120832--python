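"""Small shared helpers: sequence ops, intervals, deterministic RNG streams."""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DPNII_SITE = "GATC"


def revcomp(seq: str) -> str:
    """Reverse complement, preserving soft-mask case."""
    return seq.translate(_COMP)[::-1]


def gatc_positions(seq: str) -> list[int]:
    """0-based start positions of every GATC occurrence (case-insensitive)."""
    s = seq.upper()
    out = []
    i = s.find(DPNII_SITE)
    while i != -1:
        out.append(i)
        i = s.find(DPNII_SITE, i + 1)
    return out


def digest(seq: str) -> list[tuple[int, int]]:
    """DpnII digestion intervals (0-based half-open) of a cDNA sequence.

    Cuts 5' of every GATC, so every fragment except the first begins with
    the GATC site.
    """
    cuts = gatc_positions(seq)
    bounds = [0] + cuts + [len(seq)]
    return [(bounds[i], bounds[i + 1]) for i in range(len(bounds) - 1) if bounds[i + 1] > bounds[i]]


def overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Length of the intersection of two half-open intervals (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def interval_distance(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Gap between two half-open intervals; 0 if they touch or overlap."""
    if a[0] < b[1] and b[0] < a[1]:
        return 0
    return max(a[0] - b[1], b[0] - a[1], 0)


def merge_intervals(ivs: list[tuple[int, int]], gap: int = 0) -> list[tuple[int, int]]:
    """Union of half-open intervals, merging any pair closer than ``gap``."""
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1] + gap:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]


def child_rng(seed: int, *keys: int) -> np.random.Generator:
    """Independent, reproducible RNG stream derived from a base seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *[int(k) for k in keys]]))


def homopolymer_run(seq: str, pos: int) -> int:
    """Length of the maximal run of identical bases containing ``pos``."""
    b = seq[pos].upper()
    i = pos
    while i > 0 and seq[i - 1].upper() == b:
        i -= 1
    j = pos
    n = len(seq)
    while j + 1 < n and seq[j + 1].upper() == b:
        j += 1
    return j - i + 1
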