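"""All-vs-all gapless local alignment between sequencing projects.

Cross-contaminant contigs are near-verbatim copies, so gapless
seed-and-extend alignment is sufficient to recover them, and it keeps an
exact brute-force oracle (a best-segment scan over every diagonal)
feasible for testing.  Gapped hits computed externally can be ingested
through :func:`sitkit.io.read_hits_table` instead.

Seeds are exact k-mer matches that are fully uppercase in both
sequences (soft-masked positions never seed, but extensions may run
through them); both strands of the subject are searched.  Extension is
bidirectional with an x-drop stop, scoring +1/-1 so that the score
equals matches minus mismatches and is directly consistent with percent
identity.  The default minimum score of 64 mirrors the e>=64 score
cutoff used with LAST in the original procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import ContigRecord, DataError, Hit

__all__ = ["AlignParams", "align_pair", "best_hits", "all_vs_all"]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass(frozen=True)
class AlignParams:
    seed_k: int = 12
    match: int = 1
    mismatch: int = -1
    xdrop: int = 10
    min_score: int = 64

    def __post_init__(self) -> None:
        if self.seed_k < 4:
            raise ValueError("seed_k must be >= 4")
        if self.min_score < 1:
            raise ValueError("min_score must be >= 1")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _seed_positions(seq: str, k: int) -> dict[str, list[int]]:
    """Map each fully-uppercase, unambiguous k-mer to its start positions."""
    index: dict[str, list[int]] = {}
    n = len(seq)
    # positions that may participate in a seed: uppercase ACGT only
    ok = [c in "ACGT" for c in seq]
    run = 0
    for i in range(n):
        run = run + 1 if ok[i] else 0
        if run >= k:
            start = i - k + 1
            index.setdefault(seq[start : start + k], []).append(start)
    return index


def _extend(
    a: str, b: str, i: int, j: int, k: int, params: AlignParams
) -> tuple[int, int, int, int]:
    """Bidirectional x-drop extension of a length-k seed at a[i], b[j].

    Sequences are compared case-insensitively.  Returns (a_start, length,
    score, matches) with a_start 0-based on ``a``; the subject interval
    starts at j - (i - a_start).
    """
    au, bu = a.upper(), b.upper()
    match, mismatch, xdrop = params.match, params.mismatch, params.xdrop
    # seed itself is an exact uppercase match
    score = k * match
    matches = k
    # right extension from a[i+k], b[j+k]
    best = score
    best_right = i + k - 1
    best_matches = matches
    cur = score
    cur_matches = matches
    p, q = i + k, j + k
    while p < len(a) and q < len(b):
        if au[p] == bu[q] and au[p] != "N":
            cur += match
            cur_matches += 1
        else:
            cur += mismatch
        if cur > best:
            best, best_right, best_matches = cur, p, cur_matches
        if best - cur > xdrop:
            break
        p += 1
        q += 1
    # left extension from a[i-1], b[j-1]
    score0 = best
    best_left = i
    cur = score0
    cur_matches = best_matches
    best = score0
    p, q = i - 1, j - 1
    while p >= 0 and q >= 0:
        if au[p] == bu[q] and au[p] != "N":
            cur += params.match
            cur_matches += 1
        else:
            cur += params.mismatch
        if cur > best:
            best, best_left, best_matches = cur, p, cur_matches
        if best - cur > xdrop:
            break
        p -= 1
        q -= 1
    length = best_right - best_left + 1
    return best_left, length, best, best_matches


def _align_one_strand(
    a: ContigRecord,
    b_seq: str,
    strand: str,
    b: ContigRecord,
    index_a: Mapping[str, list[int]],
    params: AlignParams,
) -> list[Hit]:
    """Align one orientation of b against a using a's seed index."""
    k = params.seed_k
    n_b = len(b_seq)
    # collect seeds grouped by diagonal d = i - j
    seeds: dict[int, list[tuple[int, int]]] = {}
    ok = [c in "ACGT" for c in b_seq]
    run = 0
    for j in range(n_b):
        run = run + 1 if ok[j] else 0
        if run >= k:
            start = j - k + 1
            for i in index_a.get(b_seq[start : start + k], ()):
                seeds.setdefault(i - start, []).append((i, start))
    hits: list[Hit] = []
    for diag, seed_list in seeds.items():
        seed_list.sort()
        best_hit: tuple[int, int, int, int] | None = None
        covered_end = -1
        for i, j in seed_list:
            if i < covered_end:
                continue
            a_start, length, score, matches = _extend(
                a.sequence, b_seq, i, j, k, params
            )
            covered_end = a_start + length
            if best_hit is None or score > best_hit[2]:
                best_hit = (a_start, length, score, matches)
        if best_hit is None:
            continue
        a_start, length, score, matches = best_hit
        if score < params.min_score:
            continue
        j_start = a_start - diag
        pident = 100.0 * matches / length
        q_start, q_end = a_start + 1, a_start + length
        if strand == "+":
            s_start, s_end = j_start + 1, j_start + length
        else:
            # map coordinates on the reverse complement back to forward b
            s_end = b.length - j_start
            s_start = b.length - (j_start + length) + 1
        hits.append(
            Hit(
                a.project, a.contig_id, b.project, b.contig_id,
                pident=pident, aln_len=length, score=score,
                q_start=q_start, q_end=q_end,
                s_start=s_start, s_end=s_end, strand=strand,
            )
        )
    return hits


def align_pair(
    a: ContigRecord, b: ContigRecord, params: AlignParams = AlignParams()
) -> list[Hit]:
    """Gapless local alignments between two contigs of different projects.

    At most one alignment (the best-scoring) is reported per seed
    diagonal and strand; alignments scoring below ``params.min_score``
    are dropped.  An empty list means no qualifying alignment.
    """
    if a.project == b.project:
        raise DataError(
            f"align_pair requires contigs from different projects, got "
            f"{a.project!r} twice"
        )
    index_a = _seed_positions(a.sequence, params.seed_k)
    hits = _align_one_strand(a, b.sequence, "+", b, index_a, params)
    hits += _align_one_strand(a, revcomp(b.sequence), "-", b, index_a, params)
    return hits


def _hit_sort_key(h: Hit):
    return (
        -h.score, -h.pident, -h.aln_len,
        h.q_project, h.q_contig, h.s_project, h.s_contig, h.strand,
    )


def best_hits(hits: Iterable[Hit]) -> list[Hit]:
    """Keep the single top-scoring hit per unordered contig pair.

    Ties break on higher pident, longer alignment, then lexicographic
    identifiers, so the result is deterministic regardless of input
    order.  Output is canonically sorted.
    """
    by_pair: dict[frozenset, Hit] = {}
    for h in hits:
        key = h.contig_pair
        prev = by_pair.get(key)
        if prev is None or _hit_sort_key(h) < _hit_sort_key(prev):
            by_pair[key] = h
    return sorted(
        by_pair.values(),
        key=lambda h: (h.q_project, h.q_contig, h.s_project, h.s_contig),
    )


_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODE_LUT[ord(_c)] = _i  # uppercase only: soft-masked bases never seed


def _seed_kmers(seq: str, k: int) -> tuple[np.ndarray, np.ndarray]:
    """(kmer codes, start positions) of all seedable k-mers of ``seq``.

    A k-mer is seedable when all k bases are uppercase A/C/G/T.
    """
    codes = _CODE_LUT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = codes.size
    if n < k:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    valid = codes != 255
    ok = np.ones(n - k + 1, dtype=bool)
    vals = np.zeros(n - k + 1, dtype=np.int64)
    for t in range(k):
        window = codes[t : t + n - k + 1]
        ok &= valid[t : t + n - k + 1]
        vals = vals * 4 + window
    starts = np.nonzero(ok)[0]
    return vals[starts], starts


def all_vs_all(
    projects: Mapping[str, Sequence[ContigRecord]],
    params: AlignParams = AlignParams(),
) -> list[Hit]:
    """Top-scoring hit for every cross-project contig pair that aligns.

    Within-project comparisons are never performed.  All projects are
    k-mer-indexed into one sorted array; every contig is then scanned
    once per strand against the index, pairing only with projects of
    lexicographically smaller label so each unordered project pair is
    processed exactly once.  Output is deterministic and symmetric in
    the input order.
    """
    labels = sorted(projects)
    if len(labels) < 2:
        raise DataError("decontamination requires >=2 projects")
    k = params.seed_k
    # global seed index over all projects
    contigs: list[ContigRecord] = []
    contig_proj_rank: list[int] = []
    kmer_parts, pos_parts, cid_parts = [], [], []
    for rank, label in enumerate(labels):
        for contig in projects[label]:
            vals, starts = _seed_kmers(contig.sequence, k)
            kmer_parts.append(vals)
            pos_parts.append(starts)
            cid_parts.append(np.full(vals.size, len(contigs), dtype=np.int64))
            contigs.append(contig)
            contig_proj_rank.append(rank)
    kmers = np.concatenate(kmer_parts) if kmer_parts else np.empty(0, np.int64)
    order = np.argsort(kmers, kind="stable")
    kmers = kmers[order]
    positions = np.concatenate(pos_parts)[order] if kmer_parts else order
    contig_ids = np.concatenate(cid_parts)[order] if kmer_parts else order

    raw: list[Hit] = []
    for s_idx, s_contig in enumerate(contigs):
        s_rank = contig_proj_rank[s_idx]
        if s_rank == 0:
            continue  # nothing with a smaller label to pair with
        for strand in "+-":
            b_seq = (
                s_contig.sequence if strand == "+" else revcomp(s_contig.sequence)
            )
            vals, starts = _seed_kmers(b_seq, k)
            if vals.size == 0:
                continue
            lo = np.searchsorted(kmers, vals, side="left")
            in_range = lo < kmers.size
            matched = np.zeros(vals.size, dtype=bool)
            matched[in_range] = kmers[lo[in_range]] == vals[in_range]
            with_match = np.nonzero(matched)[0]
            # group matching seeds per (query contig, diagonal)
            groups: dict[tuple[int, int], list[tuple[int, int]]] = {}
            n_postings = kmers.size
            for m in with_match:
                j = int(starts[m])
                val = vals[m]
                t = int(lo[m])
                while t < n_postings and kmers[t] == val:
                    ci = int(contig_ids[t])
                    if contig_proj_rank[ci] < s_rank:
                        i = int(positions[t])
                        groups.setdefault((ci, i - j), []).append((i, j))
                    t += 1
            for (ci, diag), seed_list in sorted(groups.items()):
                a = contigs[ci]
                seed_list.sort()
                best: tuple[int, int, int, int] | None = None
                covered_end = -1
                for i, j in seed_list:
                    if i < covered_end:
                        continue
                    a_start, length, score, matches = _extend(
                        a.sequence, b_seq, i, j, k, params
                    )
                    covered_end = a_start + length
                    if best is None or score > best[2]:
                        best = (a_start, length, score, matches)
                if best is None or best[2] < params.min_score:
                    continue
                a_start, length, score, matches = best
                j_start = a_start - diag
                if strand == "+":
                    s_start, s_end = j_start + 1, j_start + length
                else:
                    s_end = s_contig.length - j_start
                    s_start = s_contig.length - (j_start + length) + 1
                raw.append(
                    Hit(
                        a.project, a.contig_id,
                        s_contig.project, s_contig.contig_id,
                        pident=100.0 * matches / length,
                        aln_len=length, score=score,
                        q_start=a_start + 1, q_end=a_start + length,
                        s_start=s_start, s_end=s_end, strand=strand,
                    )
                )
    return best_hits(raw)
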