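"""Independent brute-force oracles used to validate the implementations.

Each oracle recomputes a quantity by direct, exhaustive evaluation with
no code shared with the package's algorithmic path.
"""

from __future__ import annotations

import math


# --- DUST masking -----------------------------------------------------------

def dust_intervals_bruteforce(seq, window=64, level=20, linker=1):
    """Mask intervals by recomputing every window's score from scratch."""
    s = seq.upper()
    n = len(s)
    if n < 3:
        return []
    w = min(window, n)
    masked = [False] * n
    for start in range(n - w + 1):
        counts = {}
        n_valid = 0
        for t in range(start, start + w - 2):
            tri = s[t : t + 3]
            if set(tri) <= set("ACGT"):
                counts[tri] = counts.get(tri, 0) + 1
                n_valid += 1
        if n_valid < 2:
            continue
        score = sum(c * (c - 1) // 2 for c in counts.values())
        if 10 * score > level * (n_valid - 1):
            for p in range(start, start + w):
                masked[p] = True
    intervals = []
    i = 0
    while i < n:
        if masked[i]:
            j = i
            while j < n and masked[j]:
                j += 1
            intervals.append((i, j))
            i = j
        else:
            i += 1
    # merge across linker gaps
    merged = []
    for iv in intervals:
        if merged and iv[0] - merged[-1][1] <= linker:
            merged[-1] = (merged[-1][0], iv[1])
        else:
            merged.append(iv)
    return merged


# --- gapless alignment ------------------------------------------------------

_RC = str.maketrans("ACGTN", "TGCAN")


def best_gapless_score(a, b):
    """Best local gapless alignment score (+1/-1) over all diagonals and
    both strands of b, by exhaustive Kadane scan.  Returns 0 if nothing
    positive exists."""
    best = 0
    au = a.upper()
    for b_or in (b.upper(), b.upper().translate(_RC)[::-1]):
        for diag in range(-(len(b_or) - 1), len(au)):
            i = max(0, diag)
            j = i - diag
            cur = 0
            while i < len(au) and j < len(b_or):
                step = 1 if (au[i] == b_or[j] and au[i] != "N") else -1
                cur = max(0, cur + step)
                best = max(best, cur)
                i += 1
                j += 1
    return best


# --- histogram threshold ----------------------------------------------------

def threshold_bruteforce(counts):
    """(contaminated, threshold_bin, fallback) by direct predicate
    evaluation of every candidate bin."""
    if counts[100] <= counts[99]:
        return (False, None, False)
    qualifying = [
        b
        for b in range(2, 100)
        if counts[b - 1] >= counts[b] and counts[b - 2] >= counts[b - 1]
    ]
    if qualifying:
        return (True, max(qualifying), False)
    lowest = min(b for b in range(101) if counts[b] > 0)
    return (True, lowest - 1, True)


def bin_bruteforce(pident):
    """Round-half-up integer binning, recomputed arithmetically."""
    return max(0, min(100, int(math.floor(pident + 0.5))))


# --- best-hits reduction ----------------------------------------------------

def best_hits_bruteforce(hits):
    """Group-by-max over unordered contig pairs with the documented
    tie-break, via explicit sorting of each group."""
    groups = {}
    for h in hits:
        key = frozenset(
            ((h.q_project, h.q_contig), (h.s_project, h.s_contig))
        )
        groups.setdefault(key, []).append(h)
    out = []
    for group in groups.values():
        group.sort(
            key=lambda h: (
                -h.score, -h.pident, -h.aln_len,
                h.q_project, h.q_contig, h.s_project, h.s_contig, h.strand,
            )
        )
        out.append(group[0])
    out.sort(key=lambda h: (h.q_project, h.q_contig, h.s_project, h.s_contig))
    return out


# --- TMD prediction ---------------------------------------------------------

def tmds_bruteforce(seq, scale, window=19, threshold=1.6, min_gap=5,
                    min_len=7):
    """Per-position window means computed independently, then runs."""
    s = seq.upper()
    n = len(s)
    if n < window:
        return []
    half = window // 2
    above = []
    for centre in range(half, n - half):
        total = sum(
            scale.get(s[p], 0.0) for p in range(centre - half, centre + half + 1)
        )
        above.append((centre, total / window >= threshold - 1e-9))
    runs = []
    start = None
    for centre, ok in above:
        if ok and start is None:
            start = centre
        elif not ok and start is not None:
            runs.append((start, centre - 1))
            start = None
    if start is not None:
        runs.append((start, above[-1][0]))
    merged = []
    for s0, e0 in runs:
        if merged and s0 - merged[-1][1] - 1 < min_gap:
            merged[-1] = (merged[-1][0], e0)
        else:
            merged.append((s0, e0))
    return [(s0 + 1, e0 + 1) for s0, e0 in merged if e0 - s0 + 1 >= min_len]


# --- tree screening ---------------------------------------------------------

def _parse_nested(newick):
    """Tiny recursive newick reader -> (nested structure, supports).

    A node is either a leaf label or (children list, support or None).
    """
    text = newick.strip().rstrip(";")
    pos = 0

    def parse():
        nonlocal pos
        if text[pos] == "(":
            pos += 1
            children = [parse()]
            while text[pos] == ",":
                pos += 1
                children.append(parse())
            assert text[pos] == ")"
            pos += 1
            label = ""
            while pos < len(text) and text[pos] not in ",()":
                label += text[pos]
                pos += 1
            label = label.split(":")[0]
            support = float(label) if label else None
            return (children, support)
        label = ""
        while pos < len(text) and text[pos] not in ",()":
            label += text[pos]
            pos += 1
        return label.split(":")[0]

    return parse()


def screen_bruteforce(newick, query, group_map, expected,
                      exceptions=frozenset({"prokaryote"}), threshold=70.0):
    """Evaluate the screening rule over the nested clades containing the
    query, smallest first, from an independent newick parse."""
    root = _parse_nested(newick)
    clades = []

    def leaves(node):
        if isinstance(node, str):
            return [node]
        out = []
        for child in node[0]:
            out.extend(leaves(child))
        return out

    def walk(node):
        if isinstance(node, str):
            return
        clades.append((set(leaves(node)), node[1]))
        for child in node[0]:
            walk(child)

    walk(root)
    containing = sorted(
        (c for c in clades if query in c[0]), key=lambda c: len(c[0])
    )
    for members, support in containing:
        if support is None or support <= threshold:
            continue
        others = members - {query}
        if not others:
            continue
        groups = {group_map[x] for x in others}
        if expected in groups:
            return "clean"
        if len(groups) == 1:
            (g,) = groups
            return "exception" if g in exceptions else "flagged"
    return "clean"
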