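"""Synthetic multi-project assemblies with known cross-contamination.

The generator emulates the data structure the decontamination procedure
assumes: each sequencing project is a set of contigs; a fraction of
contigs belong to ortholog families shared across projects at moderate
divergence (genuine inter-species hits, identity ~85%); a fraction are
cross-contaminants — near-verbatim copies of another project's contigs
(identity ~99.5%) carried over at a small fraction of the donor's read
depth, as happens with index misassignment on multiplexed flow cells.
Mutations are substitution-only so realized identities are analytically
predictable and the gapless aligner is exact.  Ground truth is recorded
for scoring pipeline output.

Also provides canonical transporter protein fixtures built to the
SIT/SIT-L architectural definitions (10 or 5 TMDs, 2 or 1 EGXQ-GRQ
pairs) plus negative controls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .decontam import ContigDecision
from .io import (
    ContigRecord,
    DataError,
    ExpressionRecord,
    write_counts_table,
    write_fasta,
)

__all__ = [
    "SimParams",
    "TruthRow",
    "SimResult",
    "simulate_projects",
    "evaluate",
    "EvalResult",
    "make_canonical_fixtures",
    "expression_scenario",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimParams:
    n_projects: int = 4
    contigs_per_project: int = 200
    length_median: float = 1000.0
    length_sigma: float = 0.55  # log-normal spread of contig lengths
    length_min: int = 300
    length_max: int = 5000
    ortholog_fraction: float = 0.2
    ortholog_divergence: float = 0.15  # target pairwise divergence
    contamination_rate: float = 0.05
    contaminant_error: float = 0.005  # per-site substitution prob of the copy
    rpkm_log_mean: float = math.log(30.0)  # donor RPKM law (log-normal)
    rpkm_log_sigma: float = 1.5
    contaminant_count_scale: float = 0.02  # recipient reads / donor reads
    project_total_reads: int = 5_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "ortholog_fraction",
            "ortholog_divergence",
            "contamination_rate",
            "contaminant_error",
            "contaminant_count_scale",
        ):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {value}")


@dataclass(frozen=True)
class TruthRow:
    donor_project: str
    donor_contig: str
    recipient_project: str
    recipient_contig: str
    identity: float  # realized percent identity of the copy


@dataclass
class SimResult:
    projects: dict[str, list[ContigRecord]]
    counts: list[ExpressionRecord]
    totals: dict[str, int]
    truth: list[TruthRow]
    params: SimParams

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for label, contigs in sorted(self.projects.items()):
            write_fasta(contigs, out / f"{label}.fasta")
        write_counts_table(self.counts, self.totals, out / "counts.tsv")
        with open(out / "truth.tsv", "w") as fh:
            fh.write(f"# sitkit simulate seed={self.params.seed} ")
            fh.write(
                " ".join(f"{k}={v}" for k, v in asdict(self.params).items() if k != "seed")
            )
            fh.write("\n")
            fh.write(
                "donor_project\tdonor_contig\trecipient_project\t"
                "recipient_contig\tidentity\n"
            )
            for row in self.truth:
                fh.write(
                    f"{row.donor_project}\t{row.donor_contig}\t"
                    f"{row.recipient_project}\t{row.recipient_contig}\t"
                    f"{row.identity:.4f}\n"
                )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each site to a different base with probability ``rate``."""
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(arr.size) < rate
    idx = np.nonzero(hit)[0]
    if idx.size:
        shift = rng.integers(1, 4, size=idx.size)
        codes = np.char.upper(arr[idx]).view(np.uint8)
        base_idx = np.searchsorted(_BASES.view(np.uint8), codes)
        arr[idx] = _BASES[(base_idx + shift) % 4]
    return arr.tobytes().decode()


def _identity(a: str, b: str) -> float:
    same = sum(1 for x, y in zip(a, b) if x == y)
    return 100.0 * same / len(a)


def _draw_length(rng: np.random.Generator, p: SimParams) -> int:
    L = rng.lognormal(math.log(p.length_median), p.length_sigma)
    return int(min(max(L, p.length_min), p.length_max))


def simulate_projects(params: SimParams = SimParams()) -> SimResult:
    """Generate per-project contigs, read counts and a ground-truth table.

    Deterministic under a fixed ``params.seed``.  Ortholog families are
    present in every project, each member mutated from the family
    ancestor at a rate chosen so the *pairwise* divergence between any
    two members matches ``ortholog_divergence``.  Contaminant copies
    are appended to the recipient project with read counts scaled by
    ``contaminant_count_scale``.
    """
    rng = np.random.default_rng(params.seed)
    p = params
    labels = [f"P{i + 1}" for i in range(p.n_projects)]
    n_fam = round(p.ortholog_fraction * p.contigs_per_project)
    # per-copy rate r so that pairwise identity (1-r)^2 ~= 1 - divergence
    r_copy = 1.0 - math.sqrt(1.0 - p.ortholog_divergence)

    ancestors = [
        _random_seq(rng, _draw_length(rng, p)) for _ in range(n_fam)
    ]
    projects: dict[str, list[ContigRecord]] = {}
    for label in labels:
        contigs = []
        for fam_idx, anc in enumerate(ancestors):
            seq = _mutate(rng, anc, r_copy)
            contigs.append(ContigRecord(label, f"c{fam_idx + 1:04d}", seq))
        for k in range(n_fam, p.contigs_per_project):
            seq = _random_seq(rng, _draw_length(rng, p))
            contigs.append(ContigRecord(label, f"c{k + 1:04d}", seq))
        projects[label] = contigs

    # expression: donor RPKM drawn log-normally; counts derived from the
    # declared library size so realized RPKM matches the draw
    counts: dict[tuple[str, str], int] = {}
    totals = {label: p.project_total_reads for label in labels}
    for label in labels:
        for contig in projects[label]:
            rpkm = rng.lognormal(p.rpkm_log_mean, p.rpkm_log_sigma)
            counts[(label, contig.contig_id)] = int(
                round(rpkm * contig.length * totals[label] / 1e9)
            )

    # cross-contamination: copy a fraction of each project's contigs into
    # one other project, lightly mutated, at a fraction of the donor depth
    truth: list[TruthRow] = []
    n_cont = round(p.contamination_rate * p.contigs_per_project)
    if p.contamination_rate > 0 and n_cont < 1:
        warnings.warn("no contaminants injected", stacklevel=2)
    next_id = {label: p.contigs_per_project + 1 for label in labels}
    for label in labels:
        if n_cont < 1:
            break
        donor_idx = rng.choice(p.contigs_per_project, size=n_cont, replace=False)
        others = [x for x in labels if x != label]
        for di in sorted(int(x) for x in donor_idx):
            donor = projects[label][di]
            recipient = others[int(rng.integers(len(others)))]
            copy_seq = _mutate(rng, donor.sequence, p.contaminant_error)
            cid = f"c{next_id[recipient]:04d}"
            next_id[recipient] += 1
            projects[recipient].append(
                ContigRecord(recipient, cid, copy_seq)
            )
            donor_count = counts[(label, donor.contig_id)]
            counts[(recipient, cid)] = int(
                round(p.contaminant_count_scale * donor_count)
            )
            truth.append(
                TruthRow(
                    label, donor.contig_id, recipient, cid,
                    _identity(donor.sequence, copy_seq),
                )
            )

    count_records = [
        ExpressionRecord(proj, cid, n, totals[proj])
        for (proj, cid), n in sorted(counts.items())
    ]
    return SimResult(projects, count_records, totals, truth, params)


@dataclass(frozen=True)
class EvalResult:
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 1.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 1.0


def evaluate(
    decisions: Mapping[tuple[str, str], ContigDecision],
    truth: Sequence[TruthRow],
) -> EvalResult:
    """Score discarded-vs-truth.  Positives are the truth's recipients.

    Donor contigs retained by the RPKM exceptions are simply retained
    and therefore never counted; a *discarded* donor counts as a false
    positive like any other collateral discard.
    """
    decided_projects = {proj for proj, _ in decisions}
    for row in truth:
        if (
            row.recipient_project not in decided_projects
            or row.donor_project not in decided_projects
        ):
            raise DataError(
                f"truth row references project outside the decision table: "
                f"{row.donor_project} -> {row.recipient_project}"
            )
    positives = {(r.recipient_project, r.recipient_contig) for r in truth}
    discarded = {
        key for key, d in decisions.items() if d.status == "discarded"
    }
    tp = len(discarded & positives)
    fp = len(discarded - positives)
    fn = len(positives - discarded)
    return EvalResult(tp=tp, fp=fp, fn=fn)


# ---------------------------------------------------------------------------
# Expression-arbitration scenario: one planted verbatim copy with
# controlled donor/recipient RPKM
# ---------------------------------------------------------------------------

def expression_scenario(
    seed: int,
    donor_rpkm: float = 500.0,
    recipient_rpkm: float = 20.0,
    n_background: int = 20,
    total_reads: int = 5_000_000,
) -> tuple[dict[str, list[ContigRecord]], list[ExpressionRecord], dict[str, int],
           tuple[str, str], tuple[str, str]]:
    """Two projects with one planted verbatim contig copy at set RPKMs.

    Returns (projects, counts, totals, donor_key, recipient_key).
    """
    rng = np.random.default_rng(seed)
    length = 900
    planted = _random_seq(rng, length)
    projects = {
        "A": [ContigRecord("A", "c0001", planted)]
        + [
            ContigRecord("A", f"c{i + 2:04d}", _random_seq(rng, 600))
            for i in range(n_background)
        ],
        "B": [ContigRecord("B", "c0001", planted)]
        + [
            ContigRecord("B", f"c{i + 2:04d}", _random_seq(rng, 600))
            for i in range(n_background)
        ],
    }
    totals = {"A": total_reads, "B": total_reads}

    def count_for(rpkm: float, L: int) -> int:
        return int(round(rpkm * L * total_reads / 1e9))

    counts = []
    for label, rpkm in (("A", donor_rpkm), ("B", recipient_rpkm)):
        counts.append(
            ExpressionRecord(label, "c0001", count_for(rpkm, length), total_reads)
        )
        for contig in projects[label][1:]:
            counts.append(
                ExpressionRecord(
                    label, contig.contig_id, count_for(30.0, contig.length),
                    total_reads,
                )
            )
    return projects, counts, totals, ("A", "c0001"), ("B", "c0001")


# ---------------------------------------------------------------------------
# Canonical transporter fixtures
# ---------------------------------------------------------------------------

# building blocks chosen so that no motif pattern can arise by accident:
# loops avoid G, A and Q entirely; TMD stretches avoid A, G, E and Q
_LOOP = "DSSKDRESTDKSNDS"  # 15 residues, mean hydropathy ~ -2.9
_TMD = "LLIVLLFVLLIVLLFVLLIVL"  # 21 hydrophobic residues
_TMD4 = _TMD[:7] + "LQLLLQL" + _TMD[14:]  # carries the xQxxxQx motif
_LOOP_EGXQ = _LOOP[:11] + "EGSQ"  # EGXQ motif just before the next TMD
_LOOP_GRQ = _LOOP[:12] + "GRQ"  # GRQ motif just before the next TMD
_NTERM = "MDSSKDREST"
_CTERM = "DSSKDRESTN"


def make_canonical_fixtures() -> dict[str, str]:
    """Deterministic protein fixtures built to the architectural definitions.

    ``canonical_SIT``: 10 TMDs with EGXQ/GRQ pairs at TMD2/3 and TMD7/8
    and xQxxxQx in TMD4.  ``canonical_SITL``: the 5-TMD, one-pair
    half-architecture.  ``motifs_no_tmds`` and ``tmds_no_motifs`` are
    negative controls that must stay unclassified.
    """
    half = (
        _TMD + _LOOP_EGXQ + _TMD + _LOOP_GRQ + _TMD + _LOOP + _TMD4 + _LOOP + _TMD
    )
    sit = _NTERM + half + _LOOP + half + _CTERM
    sitl = _NTERM + half + _CTERM
    no_tmds = "M" + _LOOP + _LOOP + "EGSQ" + _LOOP + "GRQ" + _LOOP
    no_motifs = _NTERM + (_TMD + _LOOP) * 5 + _CTERM
    return {
        "canonical_SIT": sit,
        "canonical_SITL": sitl,
        "motifs_no_tmds": no_tmds,
        "tmds_no_motifs": no_motifs,
    }
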