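"""Structural classification of silicon transporter (SIT/SIT-L) proteins.

Full SITs are 10-TMD proteins carrying two EGXQ-GRQ motif pairs (the
first pair straddling TMD2/3, the second TMD7/8); SIT-Ls are 5-TMD
proteins with a single pair at TMD2/3, resembling one half of the
pseudosymmetric SIT architecture.  Transmembrane domains are predicted
with a Kyte-Doolittle sliding-window hydropathy scan — a transparent,
parameterised stand-in for interactive web predictors — and motifs with
explicit patterns that include the documented natural variants (GRH,
GQS; A for G and K/M/H for Q in EGXQ).  A broadly conserved xQxxxQx
motif in TMD4 is reported as annotation.

Full SITs can be split into N- and C-terminal halves midway between
TMD5 and TMD6 for duplication-fusion analyses; each half of a canonical
SIT then classifies like an SIT-L (5 TMDs, one motif pair).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

__all__ = [
    "KYTE_DOOLITTLE",
    "TmdParams",
    "MotifHit",
    "MotifPair",
    "TransporterCall",
    "predict_tmds",
    "scan_motifs",
    "pair_motifs",
    "classify",
    "split_sit",
]

# Kyte & Doolittle hydropathy values; X (unknown) is treated as neutral.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "X": 0.0,
}

MIN_TMD_LEN = 7  # residues; shorter hydrophobic runs are noise

_EGXQ_RE = re.compile(r"(?=(E[GA].[QKMH]))")
_GRQ_RE = re.compile(r"(?=(GRQ|GRH|GQS))")
_XQ5_RE = re.compile(r"(?=(Q...Q))")


@dataclass(frozen=True)
class TmdParams:
    """Hydropathy-window TMD prediction parameters."""

    window: int = 19
    threshold: float = 1.6
    min_gap: int = 5

    def __post_init__(self) -> None:
        if self.window < 7 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 7")


@dataclass(frozen=True)
class MotifHit:
    motif_class: str  # EGXQ | GRQ | xQxxxQx
    start: int  # 1-based position of the first matched residue
    text: str

    @property
    def end(self) -> int:
        return self.start + len(self.text) - 1


@dataclass(frozen=True)
class MotifPair:
    egxq: MotifHit
    grq: MotifHit
    anchor_tmd: int  # 1-based index n of the first TMD of the (n, n+1) anchor


@dataclass
class TransporterCall:
    protein_id: str
    tmds: list[tuple[int, int]]
    motif_hits: list[MotifHit]
    pairs: list[MotifPair]
    label: str  # SIT | SIT-L | unclassified
    notes: list[str] = field(default_factory=list)

    @property
    def n_tmds(self) -> int:
        return len(self.tmds)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def predict_tmds(seq: str, params: TmdParams = TmdParams()) -> list[tuple[int, int]]:
    """Predict TMDs as runs of high window-mean hydropathy.

    The mean Kyte-Doolittle hydropathy of a centred window is computed
    for every position where the window fits; maximal runs of positions
    with mean >= threshold become TMD intervals (1-based inclusive)
    after merging runs separated by fewer than ``min_gap`` residues and
    dropping runs shorter than 7 residues.
    """
    seq = seq.upper()
    n = len(seq)
    w = params.window
    if n < w:
        warnings.warn(
            f"sequence of length {n} shorter than hydropathy window {w}; "
            "no TMDs predicted",
            stacklevel=2,
        )
        return []
    values = [KYTE_DOOLITTLE.get(c, 0.0) for c in seq]
    half = w // 2
    # rolling window sum; centre index runs over [half, n - half - 1]
    wsum = sum(values[:w])
    means = [wsum / w]
    for i in range(1, n - w + 1):
        wsum += values[i + w - 1] - values[i - 1]
        means.append(wsum / w)
    runs: list[tuple[int, int]] = []  # 0-based centre positions, inclusive
    start = None
    # epsilon absorbs rolling-sum float noise; genuine margins are either
    # exactly zero or >= 0.1/window on this one-decimal hydropathy scale
    cutoff = params.threshold - 1e-9
    for idx, m in enumerate(means):
        centre = idx + half
        if m >= cutoff:
            if start is None:
                start = centre
        elif start is not None:
            runs.append((start, centre - 1))
            start = None
    if start is not None:
        runs.append((start, half + len(means) - 1))
    merged: list[tuple[int, int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] - 1 < params.min_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return [
        (s + 1, e + 1) for s, e in merged if e - s + 1 >= MIN_TMD_LEN
    ]


def scan_motifs(seq: str) -> list[MotifHit]:
    """Find all EGXQ-class, GRQ-class and xQxxxQx motif occurrences.

    Matching is case-insensitive and overlaps are allowed.  EGXQ-class
    means E[GA]X[QKMH] (X any residue); GRQ-class means GRQ, GRH or
    GQS; xQxxxQx requires glutamines four residues apart.
    """
    seq = seq.upper()
    hits: list[MotifHit] = []
    for regex, cls in ((_EGXQ_RE, "EGXQ"), (_GRQ_RE, "GRQ"), (_XQ5_RE, "xQxxxQx")):
        for m in regex.finditer(seq):
            hits.append(MotifHit(cls, m.start() + 1, m.group(1)))
    hits.sort(key=lambda h: (h.start, h.motif_class))
    return hits


def pair_motifs(
    motifs: list[MotifHit],
    tmds: list[tuple[int, int]],
    margin: int = 15,
) -> list[MotifPair]:
    """Pair EGXQ with GRQ motifs anchored on consecutive TMDs.

    A pair anchors on TMDs (n, n+1) when an EGXQ motif starts within
    [start(TMD_n) - margin, end(TMD_n)] and a GRQ motif starts within
    [start(TMD_{n+1}) - margin, end(TMD_{n+1}) + margin], mirroring the
    observed geometry (EGXQ just before/within one TMD, GRQ at the face
    of the next).  Assignment is greedy left-to-right and each motif hit
    joins at most one pair.
    """
    egxq = [h for h in motifs if h.motif_class == "EGXQ"]
    grq = [h for h in motifs if h.motif_class == "GRQ"]
    used_e: set[int] = set()
    used_g: set[int] = set()
    pairs: list[MotifPair] = []
    for n in range(1, len(tmds)):
        s_n, e_n = tmds[n - 1]
        s_n1, e_n1 = tmds[n]
        e_hit = next(
            (
                (i, h)
                for i, h in enumerate(egxq)
                if i not in used_e and s_n - margin <= h.start <= e_n
            ),
            None,
        )
        if e_hit is None:
            continue
        g_hit = next(
            (
                (i, h)
                for i, h in enumerate(grq)
                if i not in used_g and s_n1 - margin <= h.start <= e_n1 + margin
            ),
            None,
        )
        if g_hit is None:
            continue
        used_e.add(e_hit[0])
        used_g.add(g_hit[0])
        pairs.append(MotifPair(e_hit[1], g_hit[1], anchor_tmd=n))
    return pairs


def classify(
    seq: str,
    protein_id: str = "",
    params: TmdParams = TmdParams(),
    margin: int = 15,
    strict: bool = False,
) -> TransporterCall:
    """Classify a protein as SIT, SIT-L or unclassified.

    Strict mode applies the literal definitions: SIT = exactly 10 TMDs
    with 2 EGXQ-GRQ pairs, SIT-L = exactly 5 TMDs with 1 pair.  The
    default tolerant mode keeps the motif-pair requirement exact but
    allows the TMD count to wander within 8-12 (SIT) or 4-6 (SIT-L),
    absorbing predictor disagreement at hydropathy boundaries; near
    misses are annotated in ``notes`` (assembly-truncated SITs with one
    pair but >6 TMDs are a documented real-world case).
    """
    seq = seq.upper()
    tmds = predict_tmds(seq, params)
    motifs = scan_motifs(seq)
    pairs = pair_motifs(motifs, tmds, margin)
    n_t, n_p = len(tmds), len(pairs)
    notes: list[str] = []
    if strict:
        if n_t == 10 and n_p == 2:
            label = "SIT"
        elif n_t == 5 and n_p == 1:
            label = "SIT-L"
        else:
            label = "unclassified"
    else:
        if n_p == 2 and 8 <= n_t <= 12:
            label = "SIT"
        elif n_p == 1 and 4 <= n_t <= 6:
            label = "SIT-L"
        else:
            label = "unclassified"
            if n_p == 2:
                notes.append(f"2 pairs, {n_t} TMDs: outside SIT TMD range")
            elif n_p == 1 and n_t > 6:
                notes.append(
                    f"1 pair, {n_t} TMDs: possible truncated SIT"
                )
            elif n_p == 1:
                notes.append(f"1 pair, {n_t} TMDs: outside SIT-L TMD range")
    for h in motifs:
        if h.motif_class == "xQxxxQx" and any(
            s <= h.start and h.end <= e for s, e in tmds
        ):
            notes.append(f"xQxxxQx motif within a TMD at {h.start}")
            break
    return TransporterCall(
        protein_id=protein_id,
        tmds=tmds,
        motif_hits=motifs,
        pairs=pairs,
        label=label,
        notes=notes,
    )


def split_sit(
    seq: str, tmds: list[tuple[int, int]]
) -> tuple[str, str, int]:
    """Split a full SIT into N- and C-terminal halves between TMD5 and 6.

    The split point is the midpoint between the end of TMD5 and the
    start of TMD6 (floor), approximating the conserved inter-domain
    point used to study SIT duplication-fusion.  Returns (n_half,
    c_half, split_position); the halves concatenate to the input.
    """
    if len(tmds) < 6:
        raise ValueError(
            f"split requires >= 6 TMDs, got {len(tmds)}"
        )
    end5 = tmds[4][1]
    start6 = tmds[5][0]
    split_position = (end5 + start6) // 2
    return seq[:split_position], seq[split_position:], split_position
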