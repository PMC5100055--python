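"""Cross-contamination detection and purging between sequencing projects.

The decision procedure, per unordered project pair:

1. qualify hits — an alignment counts only if it is >= 150 nt long or
   covers at least half of the shorter contig;
2. bin qualified hits into 1%-wide percent-identity bins (round half up);
3. detect the contamination threshold — a pair is contaminated only if
   the 100% bin outnumbers the 99% bin; the scan then descends from 99%
   until three consecutive bins are found whose lower two each hold at
   least as many hits as the bin above, marking the start of the
   genuine-homology plateau.  Hits in bins strictly above the threshold
   are cross-contaminants;
4. arbitrate flagged contig pairs by expression — a contig whose RPKM is
   >= 10x its partner's is retained (its partner discarded), and any
   contig with RPKM >= 10,000 is retained regardless, because highly
   conserved, highly expressed genes legitimately align at high identity;
5. purge — discarded contigs (and their predicted proteins) are split
   into separate retained/purged files; discard dominates when a contig
   is flagged against several projects.

Project pairs known to be the same species under different names can be
excluded from comparison via ``DecontamConfig.excluded_pairs``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import ContigRecord, DataError, ExpressionRecord, Hit, ProteinRecord

__all__ = [
    "DecontamConfig",
    "PairHistogram",
    "ThresholdResult",
    "ContigDecision",
    "qualify_hit",
    "pident_bin",
    "build_pair_histogram",
    "detect_threshold",
    "compute_rpkm",
    "arbitrate_pair",
    "run_decontam",
    "purge",
]


@dataclass(frozen=True)
class DecontamConfig:
    min_hit_len: int = 150
    min_frac_of_shorter: float = 0.5
    rpkm_ratio: float = 10.0
    rpkm_retain: float = 10000.0
    excluded_pairs: frozenset[frozenset[str]] = frozenset()
    arbitration: bool = True
    # normative choices where the procedure's description is silent
    bin_rounding: str = "half_up"
    threshold_inclusive: bool = False

    def __post_init__(self) -> None:
        if self.min_hit_len < 1:
            raise ValueError("min_hit_len must be >= 1")
        if not (0.0 < self.min_frac_of_shorter <= 1.0):
            raise ValueError("min_frac_of_shorter must be in (0, 1]")
        if self.rpkm_ratio <= 1.0:
            raise ValueError("rpkm_ratio must be > 1")
        if self.rpkm_retain <= 0.0:
            raise ValueError("rpkm_retain must be > 0")


@dataclass
class PairHistogram:
    """Integer percent-identity bin counts for one project pair."""

    pair: frozenset[str]
    counts: np.ndarray  # shape (101,), bins 0..100

    @property
    def n_hits(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class ThresholdResult:
    pair: frozenset[str]
    contaminated: bool
    threshold_bin: int | None = None
    fallback_used: bool = False


@dataclass
class ContigDecision:
    project: str
    contig_id: str
    status: str = "retained"  # retained | discarded
    reason: str = "not_flagged"
    evidence: list[tuple[frozenset[str], float]] = field(default_factory=list)


def qualify_hit(hit: Hit, len_q: int, len_s: int, cfg: DecontamConfig) -> bool:
    """True when the hit is long enough to be trusted.

    Inclusive OR of the two published arms: absolute length >= 150 nt,
    or alignment covering >= 50% of the shorter contig.  A gapless
    alignment longer than the shorter contig is corrupt input.
    """
    shorter = min(len_q, len_s)
    if hit.aln_len > shorter:
        raise DataError(
            f"hit {hit.q_project}|{hit.q_contig} vs "
            f"{hit.s_project}|{hit.s_contig}: alignment length "
            f"{hit.aln_len} exceeds shorter contig length {shorter}"
        )
    return (
        hit.aln_len >= cfg.min_hit_len
        or hit.aln_len >= cfg.min_frac_of_shorter * shorter
    )


def pident_bin(pident: float) -> int:
    """Integer bin of a percent identity: round half up, clamped to [0, 100]."""
    b = math.floor(pident + 0.5)
    return max(0, min(100, b))


def build_pair_histogram(hits: Iterable[Hit], pair: frozenset[str]) -> PairHistogram:
    counts = np.zeros(101, dtype=np.int64)
    for h in hits:
        if h.pair != pair:
            raise DataError(
                f"hit between {sorted(h.pair)} does not belong to pair "
                f"{sorted(pair)}"
            )
        counts[pident_bin(h.pident)] += 1
    return PairHistogram(pair=pair, counts=counts)


def detect_threshold(hist: PairHistogram) -> ThresholdResult:
    """Scan one pair's histogram for the contamination threshold.

    No contamination unless counts[100] > counts[99].  Otherwise descend
    b = 99, 98, ..., 2 and stop at the first b where
    counts[b-1] >= counts[b] and counts[b-2] >= counts[b-1] (the start
    of the true-hit plateau); hits in bins strictly above b are the
    pair's contaminants.  If no such triple exists the whole populated
    range below 100 is treated as contaminant (fallback), since the
    100%-peak trigger already fired and no genuine-homology plateau is
    present.
    """
    c = hist.counts
    if c[100] <= c[99]:
        return ThresholdResult(hist.pair, contaminated=False)
    for b in range(99, 1, -1):
        if c[b - 1] >= c[b] and c[b - 2] >= c[b - 1]:
            return ThresholdResult(hist.pair, True, threshold_bin=b)
    populated = np.nonzero(c)[0]
    lowest = int(populated[0])  # c[100] > 0, so nonempty
    warnings.warn(
        f"pair {sorted(hist.pair)}: no plateau found below the 100% peak; "
        "flagging all populated bins below 100 as contaminant",
        stacklevel=2,
    )
    return ThresholdResult(
        hist.pair, True, threshold_bin=lowest - 1, fallback_used=True
    )


def compute_rpkm(
    read_count: int, contig_length_nt: int, project_total_reads: int
) -> float:
    """Reads per kilobase of contig per million mapped reads."""
    if contig_length_nt < 1:
        raise DataError("contig length must be >= 1 for RPKM")
    if project_total_reads < 1:
        raise DataError("project total reads must be >= 1 for RPKM")
    return 1e9 * read_count / (contig_length_nt * project_total_reads)


def arbitrate_pair(
    a: tuple[str, str, float],
    b: tuple[str, str, float],
    cfg: DecontamConfig,
) -> tuple[tuple[str, str], tuple[str, str]]:
    """Expression arbitration for one flagged contig pair.

    ``a`` and ``b`` are (project, contig_id, rpkm).  Returns
    ((status_a, reason_a), (status_b, reason_b)).  Default is to discard
    both copies; the >=10x RPKM ratio retains the higher-expression copy
    and discards the other; independently, any copy with RPKM >= 10,000
    is retained (both rules are applied symmetrically to both members).
    """
    ra, rb = a[2], b[2]
    status_a, reason_a = "discarded", "default_both"
    status_b, reason_b = "discarded", "default_both"
    win_a = ra > 0 and ra >= cfg.rpkm_ratio * rb
    win_b = rb > 0 and rb >= cfg.rpkm_ratio * ra
    if win_a and not win_b:
        status_a, reason_a = "retained", "rpkm_ratio_winner"
        reason_b = "rpkm_ratio_loser"
    elif win_b and not win_a:
        status_b, reason_b = "retained", "rpkm_ratio_winner"
        reason_a = "rpkm_ratio_loser"
    if ra >= cfg.rpkm_retain:
        status_a, reason_a = "retained", "rpkm_high_expression"
    if rb >= cfg.rpkm_retain:
        status_b, reason_b = "retained", "rpkm_high_expression"
    return (status_a, reason_a), (status_b, reason_b)


@dataclass
class DecontamResult:
    decisions: dict[tuple[str, str], ContigDecision]
    thresholds: list[ThresholdResult]
    histograms: dict[frozenset[str], PairHistogram]
    pair_stats: list[dict]
    project_summary: list[dict]
    n_excluded_hits: int = 0

    def decision_rows(self) -> list[tuple]:
        rows = []
        for (project, contig_id), d in sorted(self.decisions.items()):
            ev = ";".join(
                f"{'+'.join(sorted(pair))}:{pident:.2f}"
                for pair, pident in d.evidence
            )
            rows.append((project, contig_id, d.status, d.reason, ev))
        return rows


def run_decontam(
    projects: Mapping[str, Sequence[ContigRecord]],
    hits: Sequence[Hit],
    counts: Sequence[ExpressionRecord] | None,
    cfg: DecontamConfig = DecontamConfig(),
) -> DecontamResult:
    """Run the whole decision procedure on best-hits.

    ``counts`` may be None only when ``cfg.arbitration`` is False, in
    which case every flagged contig pair is discarded outright.
    Pipeline order is fixed: excluded pairs -> hit qualification ->
    per-pair histogram -> threshold detection -> per-hit flagging ->
    RPKM arbitration -> aggregation with discard dominating across
    pairs.
    """
    if len(projects) < 2:
        raise DataError("decontamination requires >=2 projects")
    lengths: dict[tuple[str, str], int] = {}
    decisions: dict[tuple[str, str], ContigDecision] = {}
    for label, contigs in projects.items():
        for contig in contigs:
            key = (label, contig.contig_id)
            if key in lengths:
                raise DataError(f"duplicate contig {label}|{contig.contig_id}")
            lengths[key] = contig.length
            decisions[key] = ContigDecision(label, contig.contig_id)

    rpkms: dict[tuple[str, str], float] | None = None
    if counts is not None:
        rpkms = {}
        for rec in counts:
            key = (rec.project, rec.contig_id)
            if key not in lengths:
                continue  # counts may cover contigs outside these projects
            rpkms[key] = compute_rpkm(
                rec.read_count, lengths[key], rec.project_total_reads
            )
    elif cfg.arbitration:
        raise DataError(
            "expression counts are mandatory when RPKM arbitration is enabled"
        )

    # group hits by unordered project pair, dropping excluded pairs
    by_pair: dict[frozenset[str], list[Hit]] = {}
    n_excluded = 0
    for h in hits:
        if h.pair in cfg.excluded_pairs:
            n_excluded += 1
            continue
        by_pair.setdefault(h.pair, []).append(h)

    thresholds: list[ThresholdResult] = []
    histograms: dict[frozenset[str], PairHistogram] = {}
    pair_stats: list[dict] = []

    def rpkm_of(key: tuple[str, str]) -> float:
        assert rpkms is not None
        if key not in rpkms:
            raise DataError(
                f"no expression record for flagged contig {key[0]}|{key[1]}"
            )
        return rpkms[key]

    for pair in sorted(by_pair, key=lambda p: tuple(sorted(p))):
        qualified = []
        for h in by_pair[pair]:
            lq = lengths.get((h.q_project, h.q_contig))
            ls = lengths.get((h.s_project, h.s_contig))
            if lq is None or ls is None:
                raise DataError(
                    f"hit references unknown contig "
                    f"{h.q_project}|{h.q_contig} or {h.s_project}|{h.s_contig}"
                )
            if qualify_hit(h, lq, ls, cfg):
                qualified.append(h)
        hist = build_pair_histogram(qualified, pair)
        histograms[pair] = hist
        result = detect_threshold(hist)
        thresholds.append(result)
        n_flagged = 0
        if result.contaminated:
            assert result.threshold_bin is not None
            for h in qualified:
                if pident_bin(h.pident) <= result.threshold_bin:
                    continue
                n_flagged += 1
                key_q = (h.q_project, h.q_contig)
                key_s = (h.s_project, h.s_contig)
                if cfg.arbitration:
                    (st_q, rs_q), (st_s, rs_s) = arbitrate_pair(
                        (*key_q, rpkm_of(key_q)),
                        (*key_s, rpkm_of(key_s)),
                        cfg,
                    )
                else:
                    st_q = st_s = "discarded"
                    rs_q = rs_s = "default_both"
                _apply(decisions[key_q], st_q, rs_q, pair, h.pident)
                _apply(decisions[key_s], st_s, rs_s, pair, h.pident)
        pair_stats.append(
            {
                "pair": "+".join(sorted(pair)),
                "n_hits": hist.n_hits,
                "contaminated": result.contaminated,
                "threshold_bin": (
                    "" if result.threshold_bin is None else result.threshold_bin
                ),
                "fallback_used": result.fallback_used,
                "n_flagged_hits": n_flagged,
            }
        )

    project_summary = []
    for label in sorted(projects):
        decs = [d for (p, _), d in decisions.items() if p == label]
        project_summary.append(
            {
                "project": label,
                "n_contigs": len(decs),
                "n_flagged": sum(1 for d in decs if d.evidence),
                "n_discarded": sum(1 for d in decs if d.status == "discarded"),
                "n_retained_by_exception": sum(
                    1
                    for d in decs
                    if d.status == "retained"
                    and d.reason in ("rpkm_ratio_winner", "rpkm_high_expression")
                ),
            }
        )
    return DecontamResult(
        decisions=decisions,
        thresholds=thresholds,
        histograms=histograms,
        pair_stats=pair_stats,
        project_summary=project_summary,
        n_excluded_hits=n_excluded,
    )


_REASON_RANK = {
    # higher rank wins within the same status
    "rpkm_high_expression": 2,
    "rpkm_ratio_winner": 1,
    "rpkm_ratio_loser": 2,
    "default_both": 1,
    "not_flagged": 0,
}


def _apply(
    decision: ContigDecision,
    status: str,
    reason: str,
    pair: frozenset[str],
    pident: float,
) -> None:
    """Fold one per-hit outcome into a contig's running decision.

    Discard dominates across pairs; within a status the more specific
    reason is kept.
    """
    decision.evidence.append((pair, pident))
    if decision.status == "discarded":
        if status == "discarded" and _REASON_RANK[reason] > _REASON_RANK[decision.reason]:
            decision.reason = reason
        return
    if status == "discarded":
        decision.status = "discarded"
        decision.reason = reason
    elif _REASON_RANK[reason] > _REASON_RANK[decision.reason]:
        decision.reason = reason


@dataclass
class PurgeResult:
    retained_nt: list[ContigRecord]
    purged_nt: list[ContigRecord]
    retained_aa: list[ProteinRecord]
    purged_aa: list[ProteinRecord]
    report: dict


def purge(
    contigs: Sequence[ContigRecord],
    proteins: Sequence[ProteinRecord] | None,
    decisions: Mapping[tuple[str, str], ContigDecision],
) -> PurgeResult:
    """Partition contigs (and linked proteins) into retained and purged sets.

    Every input appears in exactly one output, order preserved.  A
    protein whose contig_id resolves to no contig decision is retained
    with a warning (fail-open) and counted in the report.
    """
    retained_nt, purged_nt = [], []
    for contig in contigs:
        d = decisions.get((contig.project, contig.contig_id))
        if d is None:
            raise DataError(
                f"no decision for contig {contig.project}|{contig.contig_id}"
            )
        (purged_nt if d.status == "discarded" else retained_nt).append(contig)
    retained_aa, purged_aa = [], []
    n_unlinked = 0
    for prot in proteins or []:
        d = decisions.get((prot.project, prot.contig_id))
        if d is None:
            n_unlinked += 1
            warnings.warn(
                f"protein {prot.project}|{prot.protein_id} links to unknown "
                f"contig {prot.contig_id!r}; retained",
                stacklevel=2,
            )
            retained_aa.append(prot)
        elif d.status == "discarded":
            purged_aa.append(prot)
        else:
            retained_aa.append(prot)
    report = {
        "contigs_in": len(contigs),
        "contigs_retained": len(retained_nt),
        "contigs_purged": len(purged_nt),
        "proteins_in": len(proteins or []),
        "proteins_retained": len(retained_aa),
        "proteins_purged": len(purged_aa),
        "proteins_unlinked": n_unlinked,
    }
    return PurgeResult(retained_nt, purged_nt, retained_aa, purged_aa, report)
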