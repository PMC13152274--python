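"""Independent brute-force oracles for the detection algorithms.

These deliberately avoid the production code paths: runs are found by
sample-by-sample scans, prominences by literal walks, and the iterated
threshold procedure loops over every threshold and every integer size.
"""

from __future__ import annotations

import numpy as np


def runs_bruteforce(mask) -> list[tuple[int, int]]:
    """Half-open (start, end) runs of True found by linear scan."""
    out = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            out.append((start, i))
            start = None
    if start is not None:
        out.append((start, len(mask)))
    return out


def significance_mask_bruteforce(z, k_grid, fp_ratio=0.05, strict=False) -> np.ndarray:
    """Literal iteration over every k and every integer size s.

    Inclusive counting sweeps every integer size from 1 to the longest
    segment; the strict variant assesses each positive segment at its own
    size, mirroring its documented semantics.
    """
    z = np.asarray(z, float)
    mask = np.zeros(len(z), dtype=bool)
    for k in k_grid:
        pos = runs_bruteforce(z > k)
        neg = runs_bruteforce(z < -k)
        if not pos:
            continue
        max_s = max(e - s for s, e in pos + neg)
        sizes = sorted({e - s for s, e in pos}) if strict else range(1, max_s + 1)
        for s in sizes:
            if strict:
                n_pos = sum(1 for a, b in pos if b - a > s)
                n_neg = sum(1 for a, b in neg if b - a > s)
            else:
                n_pos = sum(1 for a, b in pos if b - a >= s)
                n_neg = sum(1 for a, b in neg if b - a >= s)
            if n_pos > 0 and n_neg / n_pos < fp_ratio:
                for a, b in pos:
                    size = b - a
                    if (size > s) if strict else (size >= s):
                        mask[a:b] = True
    return mask


def local_maxima_bruteforce(y) -> list[int]:
    return [i for i in range(1, len(y) - 1) if y[i - 1] < y[i] > y[i + 1]]


def prominence_bruteforce(y, i) -> float:
    """Literal prominence: on each side walk to the nearest higher sample
    (or the edge); prominence is peak height above the higher of the two
    interval minima."""
    left_min = y[i]
    j = i - 1
    while j >= 0 and y[j] <= y[i]:
        left_min = min(left_min, y[j])
        j -= 1
    right_min = y[i]
    j = i + 1
    while j < len(y) and y[j] <= y[i]:
        right_min = min(right_min, y[j])
        j += 1
    return y[i] - max(left_min, right_min)


def peaks_bruteforce(y, min_height, min_prominence, distance) -> list[int]:
    """Height filter, then keep-taller distance rule, then prominence,
    mirroring the documented criterion order."""
    cand = [i for i in local_maxima_bruteforce(y) if y[i] >= min_height]
    # distance: process candidates from tallest to shortest, discarding
    # any not-yet-kept candidate within `distance` samples of a kept one
    order = sorted(range(len(cand)), key=lambda j: y[cand[j]], reverse=True)
    keep = [True] * len(cand)
    for j in order:
        if not keep[j]:
            continue
        for l in range(len(cand)):
            if l != j and keep[l] and abs(cand[l] - cand[j]) < distance:
                if y[cand[l]] <= y[cand[j]]:
                    keep[l] = False
    kept = [c for c, k in zip(cand, keep) if k]
    return [i for i in kept if prominence_bruteforce(y, i) >= min_prominence]
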