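"""Soft-masking of simple repeats with a symmetric DUST score.

Low-complexity tracts (homopolymers, short-period repeats) produce
spurious near-100%-identity alignments between unrelated contigs, which
would corrupt the percent-identity histograms the decontamination
procedure relies on.  Masking is encoded in sequence case: lowercase
positions are excluded from alignment *seeding* but still allowed inside
extensions, so a genuine contaminant copy spanning a repeat is still
found while repeat-only matches never seed.

The score of a window is the symmetric DUST statistic over overlapping
triplets: S = sum_t c_t (c_t - 1) / 2, normalised per triplet position,
and a window is low-complexity when 10 * S / (L - 1) > level, where L is
the number of (unambiguous) triplets in the window.  Every position of
every qualifying window is masked.  This windowed definition is the
normative one for this toolkit and is tested against an exhaustive
per-window brute-force implementation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .io import ContigRecord

__all__ = ["MaskParams", "dust_mask", "low_complexity_intervals", "merge_intervals"]

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class MaskParams:
    """Masking parameters (defaults follow the classic DUST defaults)."""

    window: int = 64
    level: int = 20
    linker: int = 1

    def __post_init__(self) -> None:
        if self.window < 3:
            raise ValueError("window must be >= 3")
        if self.level < 1:
            raise ValueError("level must be >= 1")
        if self.linker < 0:
            raise ValueError("linker must be >= 0")


def merge_intervals(
    intervals: list[tuple[int, int]], linker: int = 0
) -> list[tuple[int, int]]:
    """Merge half-open intervals separated by <= linker positions."""
    if not intervals:
        return []
    intervals = sorted(intervals)
    merged = [intervals[0]]
    for start, end in intervals[1:]:
        last_start, last_end = merged[-1]
        if start - last_end <= linker:
            merged[-1] = (last_start, max(last_end, end))
        else:
            merged.append((start, end))
    return merged


def low_complexity_intervals(
    sequence: str, params: MaskParams = MaskParams()
) -> list[tuple[int, int]]:
    """0-based half-open intervals of low-complexity sequence.

    A sliding window of ``params.window`` positions (or the whole
    sequence when shorter) moves one position at a time; triplet counts
    and the DUST sum are updated incrementally.  Triplets containing an
    ambiguous base are ignored.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < 3:
        return []
    codes = [_BASE_CODE.get(c, -1) for c in seq]
    # triplet code at i covers positions i..i+2; -1 marks ambiguity
    triplets: list[int] = []
    for i in range(n - 2):
        a, b, c = codes[i], codes[i + 1], codes[i + 2]
        triplets.append(-1 if -1 in (a, b, c) else (a << 4) | (b << 2) | c)

    w = min(params.window, n)
    counts = [0] * 64
    s = 0  # sum of c*(c-1)/2 over triplet counts
    n_valid = 0
    flagged: list[tuple[int, int]] = []

    def add(t: int) -> None:
        nonlocal s, n_valid
        if t >= 0:
            s += counts[t]
            counts[t] += 1
            n_valid += 1

    def remove(t: int) -> None:
        nonlocal s, n_valid
        if t >= 0:
            counts[t] -= 1
            s -= counts[t]
            n_valid -= 1

    # window [i, i+w) holds triplets i .. i+w-3
    for j in range(w - 2):
        add(triplets[j])
    level = params.level
    last = n - w
    for i in range(last + 1):
        if n_valid >= 2 and 10 * s > level * (n_valid - 1):
            flagged.append((i, i + w))
        if i < last:
            remove(triplets[i])
            add(triplets[i + w - 2])

    return merge_intervals(flagged, params.linker)


def dust_mask(record: ContigRecord, params: MaskParams = MaskParams()) -> ContigRecord:
    """Return the contig with low-complexity positions lowercased.

    Existing lowercase (prior masking) is preserved and unioned with the
    newly detected intervals; the uppercased sequence is unchanged.
    Sequences shorter than 3 nt are returned unchanged with a warning.
    """
    if record.length < 3:
        warnings.warn(
            f"{record.seqid}: sequence shorter than 3 nt, not masked",
            stacklevel=2,
        )
        return record
    intervals = low_complexity_intervals(record.sequence, params)
    if not intervals:
        return record
    chars = list(record.sequence)
    for start, end in intervals:
        for i in range(start, end):
            chars[i] = chars[i].lower()
    return ContigRecord(record.project, record.contig_id, "".join(chars))
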