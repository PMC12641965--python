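"""Brute-force pair-enumeration oracle for GLCM entropy.

Written independently of the package implementation: plain Python loops over
every pixel and direction, dictionary-counted co-occurrences.  Deliberately
slow and obvious.
"""

import math

DIRECTIONS = ((0, 1), (1, 0), (1, 1), (1, -1))


def glcm_entropy_oracle(img, mask, levels=256, dist=1, directions=DIRECTIONS, symmetric=True):
    H = len(img)
    W = len(img[0])
    vals = [img[r][c] for r in range(H) for c in range(W) if mask[r][c]]
    if len(vals) < 2:
        return float("nan")
    lo, hi = min(vals), max(vals)

    def level(v):
        if hi == lo:
            return 0
        q = int((v - lo) / (hi - lo) * levels)
        return min(max(q, 0), levels - 1)

    counts = {}
    for r in range(H):
        for c in range(W):
            if not mask[r][c]:
                continue
            for dr, dc in directions:
                rr, cc = r + dr * dist, c + dc * dist
                if 0 <= rr < H and 0 <= cc < W and mask[rr][cc]:
                    a, b = level(img[r][c]), level(img[rr][cc])
                    counts[(a, b)] = counts.get((a, b), 0) + 1
                    if symmetric:
                        counts[(b, a)] = counts.get((b, a), 0) + 1
    total = sum(counts.values())
    if total == 0:
        return float("nan")
    ent = 0.0
    for n in counts.values():
        p = n / total
        ent -= p * math.log2(p)
    return ent
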