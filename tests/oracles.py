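"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected result by exhaustive enumeration or a
naive algorithm written without reference to the package implementation, so
agreement is meaningful.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

NEG = float("-inf")


# ---------------------------------------------------------------------------
# alignment scoring oracles (gap of length L costs gap_open + L * gap_extend)


def global_score_oracle(a: str, b: str, match, mismatch, gap_open, gap_extend):
    """Affine-gap global alignment score by memoized recursion (Gotoh states),
    written independently of the production aligner."""

    @lru_cache(maxsize=None)
    def rec(i, j, state):
        # score of aligning a[i:] with b[j:], given the previous column state
        if i == len(a) and j == len(b):
            return 0.0
        best = NEG
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + rec(i + 1, j + 1, "M"))
        if i < len(a):  # gap in b
            cost = gap_extend if state == "A" else gap_open + gap_extend
            best = max(best, cost + rec(i + 1, j, "A"))
        if j < len(b):  # gap in a
            cost = gap_extend if state == "B" else gap_open + gap_extend
            best = max(best, cost + rec(i, j + 1, "B"))
        return best

    return rec(0, 0, "M")


def local_score_oracle(a: str, b: str, match, mismatch, gap_open, gap_extend):
    """Plain Smith-Waterman with affine gaps, naive O(nm) with explicit
    loops."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(
                H[i][j - 1] + gap_open + gap_extend, E[i][j - 1] + gap_extend
            )
            F[i][j] = max(
                H[i - 1][j] + gap_open + gap_extend, F[i - 1][j] + gap_extend
            )
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


# ---------------------------------------------------------------------------
# monotone-chain oracle for synteny block detection


def _valid_chains(pos_b, max_rank_gap, increasing):
    """All strictly monotone index chains with consecutive rank gaps of at
    most max_rank_gap skipped anchors, by exhaustive subset enumeration."""
    n = len(pos_b)
    step = max_rank_gap + 1
    chains = []
    for r in range(1, n + 1):
        for combo in itertools.combinations(range(n), r):
            ok = True
            for x, y in zip(combo, combo[1:]):
                if y - x > step:
                    ok = False
                    break
                if increasing and not pos_b[y] > pos_b[x]:
                    ok = False
                    break
                if not increasing and not pos_b[y] < pos_b[x]:
                    ok = False
                    break
            if ok:
                chains.append(combo)
    return chains


def best_chain_oracle(pos_b, max_rank_gap, increasing):
    """Maximum-length chain; ties resolved to the lexicographically smallest
    index tuple."""
    chains = _valid_chains(pos_b, max_rank_gap, increasing)
    if not chains:
        return ()
    best_len = max(len(c) for c in chains)
    return min(c for c in chains if len(c) == best_len)


def detect_blocks_oracle(pos_b, min_block, max_rank_gap):
    """Greedy block extraction exactly as specified, with the chain finder
    replaced by exhaustive enumeration. Returns a list of
    (orientation, member index tuple) in original-rank indices."""
    remaining = list(range(len(pos_b)))
    out = []
    while len(remaining) >= min_block:
        sub = [pos_b[i] for i in remaining]
        fwd = best_chain_oracle(sub, max_rank_gap, True)
        rev = best_chain_oracle(sub, max_rank_gap, False)
        chain, orient = (fwd, "forward") if len(fwd) >= len(rev) else (rev, "reverse")
        if len(chain) < min_block:
            break
        out.append((orient, tuple(remaining[i] for i in chain)))
        taken = {remaining[i] for i in chain}
        remaining = [i for i in remaining if i not in taken]
    return out


# ---------------------------------------------------------------------------
# naive Neighbor-Joining


def nj_oracle(labels, d):
    """Naive O(n^3) NJ without caching: returns (set of bipartitions keyed by
    the side excluding the lexicographically first label, total tree length).
    Tie-breaking matches the documented rule: smallest (label_i, label_j)
    lexicographic pair.
    """
    import numpy as np

    labels = list(labels)
    d = [list(map(float, row)) for row in d]
    # each live node: (representative label for ties, member leaf frozenset)
    nodes = [(lab, frozenset([lab])) for lab in labels]
    splits = []
    lengths = []
    while len(nodes) > 3:
        m = len(nodes)
        r = [sum(d[i]) for i in range(m)]
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                q = (m - 2) * d[i][j] - r[i] - r[j]
                key = (
                    q,
                    min(nodes[i][0], nodes[j][0]),
                    max(nodes[i][0], nodes[j][0]),
                )
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * d[i][j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i][j] - li
        lengths += [max(li, 0.0), max(lj, 0.0)]
        merged = nodes[i][1] | nodes[j][1]
        splits.append(merged)
        rep = min(nodes[i][0], nodes[j][0])
        new_row = [
            0.5 * (d[i][x] + d[j][x] - d[i][j]) for x in range(m)
        ]
        keep = [x for x in range(m) if x not in (i, j)]
        d = [[d[x][y] for y in keep] + [new_row[x]] for x in keep]
        d.append([new_row[x] for x in keep] + [0.0])
        nodes = [nodes[x] for x in keep] + [(rep, merged)]
    # final star
    da, db, dc = d[0][1], d[0][2], d[1][2]
    lengths += [
        max((da + db - dc) / 2, 0.0),
        max((da + dc - db) / 2, 0.0),
        max((db + dc - da) / 2, 0.0),
    ]
    all_leaves = frozenset(labels)
    ref = sorted(labels)[0]
    out = set()
    for s in splits:
        side = s if ref not in s else all_leaves - s
        if 2 <= len(side) <= len(labels) - 2:
            out.add(frozenset(side))
    return out, sum(lengths)
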