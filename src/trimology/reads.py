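"""Classification of junction-spanning amplicon reads into repair outcomes.

A junction model describes the expected perfect product at one genome-donor
boundary: genome flank, trimology arm and a cassette-proximal stub (the arm
sits between genome and cassette in the order dictated by its side).  Each
read is anchored to the model by semi-global alignment; deletions are
apportioned to the genome side, the cassette side, or the degenerate tandem-
unit run spanning the junction.  Within the run only the resulting copy
number is observable, so unit losses are counted as whole units and any
partial-unit remainder counts as trimming.  Categories:

* ``scarless_NHEJ``    -- no trimming, no unit loss (the HiTi outcome)
* ``trimology_repair`` -- no trimming, >= 1 whole unit lost
* ``genome_trimmed`` / ``cassette_trimmed`` / ``both_trimmed``
* ``unaligned``        -- identity below threshold

Substitutions at the junction are tolerated (only gaps count as trimming)
and are visible in the identity figure.  Frame calls use the net indel
length only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import Align, SeqIO

from .donors import DEFAULT_CASSETTE_STUB, TrimologyArm, _unit_run
from .seqcore import CutSite, context_window, revcomp

log = logging.getLogger(__name__)

CATEGORIES = (
    "scarless_NHEJ",
    "trimology_repair",
    "genome_trimmed",
    "cassette_trimmed",
    "both_trimmed",
    "unaligned",
)


@dataclass(frozen=True)
class AlignmentParams:
    """Pairwise alignment scoring; gaps of length n cost open + (n-1)*extend.

    By default end gaps are penalised like internal gaps (plain global
    alignment): amplicon reads span the whole junction model, and free end
    gaps would let a large junction-spanning deletion masquerade as an
    unaligned tail.  Set ``free_end_gaps`` for reads that may be truncated.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -4.0
    gap_extend: float = -1.0
    min_identity: float = 0.8
    free_end_gaps: bool = False


@dataclass(frozen=True)
class JunctionModel:
    """Expected perfect product at one genome-donor junction."""

    genome_flank: str
    arm: TrimologyArm
    cassette_stub: str
    frame_anchor: int = 0

    def __post_init__(self) -> None:
        if not self.genome_flank or not self.cassette_stub:
            raise ValueError("genome_flank and cassette_stub must be non-empty")

    @property
    def side(self) -> str:
        return self.arm.side

    @property
    def expected_perfect(self) -> str:
        if self.side == "left":
            return self.genome_flank + self.arm.seq + self.cassette_stub
        return self.cassette_stub + self.arm.seq + self.genome_flank

    @property
    def junction_index(self) -> int:
        """Index of the genome/donor boundary within ``expected_perfect``."""
        if self.side == "left":
            return len(self.genome_flank)
        return len(self.cassette_stub) + len(self.arm.seq)

    def unit_run(self) -> tuple[int, int]:
        """Extent of the degenerate unit run spanning the junction."""
        if self.arm.repeats == 0:
            j = self.junction_index
            return j, j
        return _unit_run(self.expected_perfect, self.junction_index, self.arm.unit)


def junction_model_for_site(
    site: CutSite,
    arm: TrimologyArm,
    cassette_stub: str = DEFAULT_CASSETTE_STUB,
    flank_len: int = 30,
) -> JunctionModel:
    """Build the junction model for a designed arm at its cut site."""
    if arm.side == "left":
        flank = context_window(site, flank_len, 0, strict=True)[0]
    else:
        flank = context_window(site, 0, flank_len, strict=True)[1]
    return JunctionModel(genome_flank=flank, arm=arm, cassette_stub=cassette_stub)


@dataclass(frozen=True)
class ReadClassification:
    read_id: str
    category: str
    genome_trim: int = 0
    cassette_trim: int = 0
    units_lost: int = 0
    net_indel: int = 0
    in_frame: bool = True
    identity: float = 0.0
    orientation: str = "+"


def _make_aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    if params.free_end_gaps:
        try:  # Biopython >= 1.88 naming
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # pragma: no cover - older Biopython
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0
    return aligner


def _alignment_stats(alignment, target: str, query: str):
    """Matches, aligned columns, internal indel intervals (target coords)."""
    t_blocks, q_blocks = alignment.aligned
    matches = 0
    columns = 0
    deletions: list[tuple[int, int]] = []
    insertions = 0
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        columns += te - ts
        matches += sum(1 for a, b in zip(target[ts:te], query[qs:qe]) if a == b)
    for idx in range(1, len(t_blocks)):
        t_gap = t_blocks[idx][0] - t_blocks[idx - 1][1]
        q_gap = q_blocks[idx][0] - q_blocks[idx - 1][1]
        if t_gap > 0:
            deletions.append((t_blocks[idx - 1][1], t_blocks[idx][0]))
        if q_gap > 0:
            insertions += q_gap
    covered = (t_blocks[0][0], t_blocks[-1][1]) if len(t_blocks) else (0, 0)
    return matches, columns, deletions, insertions, covered


def classify_read(
    read: str,
    model: JunctionModel,
    aln_params: AlignmentParams | None = None,
    read_id: str = "read",
) -> ReadClassification:
    """Classify one junction-spanning read against the expected product.

    Orientation is resolved by the better-scoring of the read and its
    reverse complement.  Deletions are apportioned by overlap with the
    genome region, the degenerate unit run and the cassette region of the
    model; within the run, whole units count as unit losses and partial-unit
    remainders as trimming on the nearer side.
    """
    aln_params = aln_params or AlignmentParams()
    read = read.upper().replace("U", "T")
    target = model.expected_perfect
    aligner = _make_aligner(aln_params)
    best = None
    for orientation, query in (("+", read), ("-", revcomp(read))):
        alignments = aligner.align(target, query)
        score = alignments.score
        if best is None or score > best[0]:
            best = (score, orientation, alignments[0], query)
    _, orientation, alignment, query = best
    matches, columns, deletions, insertions, covered = _alignment_stats(
        alignment, target, query
    )
    identity = matches / columns if columns else 0.0
    if identity < aln_params.min_identity:
        return ReadClassification(
            read_id=read_id, category="unaligned", identity=identity,
            orientation=orientation,
        )
    run_start, run_end = model.unit_run()
    k = model.arm.unit_len
    if model.side == "left":
        genome_region = (0, run_start)
        cassette_region = (run_end, len(target))
    else:
        cassette_region = (0, run_start)
        genome_region = (run_end, len(target))

    def overlap(interval, region):
        return max(0, min(interval[1], region[1]) - max(interval[0], region[0]))

    def canonicalize(s: int, e: int) -> tuple[int, int]:
        """Shift a deletion within its product-equivalence range to the
        placement maximising overlap with the unit run.

        All placements of a deletion inside repeated sequence yield the same
        read, so the observed gap position is arbitrary; attributing as much
        as possible to the run implements copy-number (not placement)
        accounting.
        """
        d = e - s
        s_min, s_max = s, s
        while s_min > 0 and target[s_min - 1] == target[s_min + d - 1]:
            s_min -= 1
        while s_max + d < len(target) and target[s_max] == target[s_max + d]:
            s_max += 1
        cand = {min(max(s_min, run_start), s_max), max(min(s_max, run_end - d), s_min)}
        best_s = min(cand)
        best_ol = -1
        for c in sorted(cand):
            ol = overlap((c, c + d), (run_start, run_end))
            if ol > best_ol:
                best_ol, best_s = ol, c
        return best_s, best_s + d

    genome_trim = cassette_trim = units_lost = 0
    total_del = 0
    for s, e in deletions:
        total_del += e - s
        s, e = canonicalize(s, e)
        ol_run = overlap((s, e), (run_start, run_end))
        g = overlap((s, e), genome_region)
        c = overlap((s, e), cassette_region)
        units_lost += ol_run // k if k else 0
        rem = ol_run % k if k else 0
        if rem:
            if g > 0:
                g += rem
            elif c > 0:
                c += rem
            else:
                # wholly inside the run: charge the nearer boundary
                if (s - run_start) <= (run_end - e):
                    g += rem
                else:
                    c += rem
        genome_trim += g
        cassette_trim += c
    net_indel = insertions - total_del
    if genome_trim and cassette_trim:
        category = "both_trimmed"
    elif genome_trim:
        category = "genome_trimmed"
    elif cassette_trim:
        category = "cassette_trimmed"
    elif units_lost:
        category = "trimology_repair"
    else:
        # insertions without any trimming stay in this class; the net indel
        # and frame fields record them
        category = "scarless_NHEJ"
    return ReadClassification(
        read_id=read_id,
        category=category,
        genome_trim=genome_trim,
        cassette_trim=cassette_trim,
        units_lost=units_lost,
        net_indel=net_indel,
        in_frame=net_indel % 3 == 0,
        identity=identity,
        orientation=orientation,
    )


def classify_reads(
    reads: Iterable[tuple[str, str]],
    models: Sequence[JunctionModel],
    aln_params: AlignmentParams | None = None,
) -> list[ReadClassification]:
    """Classify reads, assigning each to the best-scoring junction model."""
    aln_params = aln_params or AlignmentParams()
    if not models:
        raise ValueError("at least one junction model is required")
    out = []
    for read_id, seq in reads:
        if len(models) == 1:
            out.append(classify_read(seq, models[0], aln_params, read_id))
            continue
        best = None
        for model in models:
            c = classify_read(seq, model, aln_params, read_id)
            if best is None or c.identity > best.identity:
                best = c
        out.append(best)
    return out


@dataclass(frozen=True)
class OutcomeTable:
    """Per-category summary of classified reads.

    Percentages are over assigned (aligned) reads; unaligned reads are
    reported separately.  ``fold_enrichment`` is the ratio of in-frame
    non-scarless reads (trimology repair plus other in-frame outcomes) to
    scarless-NHEJ reads.
    """

    counts: dict = field(compare=False)
    percentages: dict = field(compare=False)
    n_reads: int = 0
    n_unaligned: int = 0
    in_frame_pct: float = 0.0
    fold_enrichment: float | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_reads": self.n_reads,
                "n_unaligned": self.n_unaligned,
                "counts": self.counts,
                "percentages": self.percentages,
                "in_frame_pct": self.in_frame_pct,
                "fold_enrichment": self.fold_enrichment,
            },
            indent=2,
        )


def summarize(classifications: Sequence[ReadClassification]) -> OutcomeTable:
    """Summarise classifications into per-category percentages."""
    if not classifications:
        raise ValueError("no classifications to summarise")
    counts = {c: 0 for c in CATEGORIES}
    for c in classifications:
        counts[c.category] += 1
    n_unaligned = counts["unaligned"]
    aligned = [c for c in classifications if c.category != "unaligned"]
    n_aligned = len(aligned)
    percentages = {
        cat: (100.0 * counts[cat] / n_aligned if n_aligned else 0.0)
        for cat in CATEGORIES
        if cat != "unaligned"
    }
    in_frame = sum(1 for c in aligned if c.in_frame)
    scarless = counts["scarless_NHEJ"]
    inframe_mut = sum(
        1 for c in aligned if c.in_frame and c.category != "scarless_NHEJ"
    )
    return OutcomeTable(
        counts=counts,
        percentages=percentages,
        n_reads=len(classifications),
        n_unaligned=n_unaligned,
        in_frame_pct=100.0 * in_frame / n_aligned if n_aligned else 0.0,
        fold_enrichment=(inframe_mut / scarless) if scarless else None,
    )


def classifications_to_table(classifications: Sequence[ReadClassification]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "read_id": c.read_id,
                "category": c.category,
                "genome_trim": c.genome_trim,
                "cassette_trim": c.cassette_trim,
                "units_lost": c.units_lost,
                "net_indel": c.net_indel,
                "in_frame": c.in_frame,
                "identity": round(c.identity, 4),
                "orientation": c.orientation,
            }
            for c in classifications
        ]
    )


def read_reads(path: str | Path) -> list[tuple[str, str]]:
    """Read junction reads from FASTQ, FASTA or one-sequence-per-line text."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".fastq", ".fq"):
        return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fastq")]
    if suffix in (".fasta", ".fa", ".fna"):
        return [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    reads = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if line:
                reads.append((f"read_{i}", line))
    return reads
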