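"""Sequence handling, SpCas9 target scanning and the PAM-anchored coordinate frame.

Every downstream module works in a single coordinate convention anchored on the
PAM: the three PAM bases are positions 0-2, the protospacer occupies positions
-20..-1, and the blunt Cas9 cut falls between positions -4 and -3 (three
nucleotides 5' of the PAM on the protospacer strand).  Minus-strand sites are
re-expressed on the protospacer strand at construction time, so nothing
downstream ever branches on strand.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

log = logging.getLogger(__name__)

PROTOSPACER_LEN = 20
PAM_LEN = 3
#: distance from the cut boundary to the first PAM base on the protospacer strand
CUT_TO_PAM = 3
#: minimum sequence length able to host a full protospacer + PAM
MIN_SITE_SPAN = PROTOSPACER_LEN + PAM_LEN

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_DNA_RE = re.compile(r"^[ACGTN]+$")


class ConfigurationError(ValueError):
    """Malformed user configuration (e.g. an invalid IUPAC PAM pattern)."""


class ClassificationError(ValueError):
    """A base could not be classified (ambiguous nucleotide)."""


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMP)[::-1]


def _validate_dna(seq: str, what: str = "sequence") -> None:
    if not seq or not _DNA_RE.match(seq):
        raise ValueError(f"{what} must be a non-empty string over A,C,G,T,N: {seq!r}")


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence, uppercase-normalised on ingest (U becomes T)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        norm = self.seq.upper().replace("U", "T")
        _validate_dna(norm, f"sequence {self.id!r}")
        object.__setattr__(self, "seq", norm)

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-record) FASTA file into :class:`SequenceRecord` objects."""
    records = [SequenceRecord(id=r.id, seq=str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


@dataclass(frozen=True)
class CutSite:
    """A Cas9 target with its PAM-anchored coordinate frame.

    ``pam_start`` is the 0-based forward-strand index of the leftmost base of
    the PAM footprint; ``cut_offset`` is the forward-strand index of the
    boundary between positions -4 and -3, i.e. ``source.seq[:cut_offset]``
    lies 5' of the cut on the forward strand.
    """

    source_id: str
    strand: str  # "+" or "-"
    protospacer: str
    pam: str
    pam_start: int
    cut_offset: int
    source: SequenceRecord = field(repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.protospacer) != PROTOSPACER_LEN or len(self.pam) != PAM_LEN:
            raise ValueError("protospacer must be 20 nt and PAM 3 nt")

    # -- PAM-anchored coordinate helpers ------------------------------------

    def _forward_index(self, position: int) -> int:
        """Forward-strand index of PAM-anchored ``position`` (protospacer strand)."""
        if self.strand == "+":
            return self.pam_start + position
        return self.pam_start + (PAM_LEN - 1) - position

    def available_window(self) -> tuple[int, int]:
        """Inclusive range of PAM-anchored positions resolvable on the source."""
        n = len(self.source.seq)
        if self.strand == "+":
            return -self.pam_start, n - 1 - self.pam_start
        return self.pam_start + PAM_LEN - 1 - (n - 1), self.pam_start + PAM_LEN - 1


def nucleotide_at(site: CutSite, position: int) -> str:
    """Protospacer-strand base at a PAM-anchored ``position``.

    Position 0 is the first PAM base; position -4 is the base immediately
    5' of the blunt cut.
    """
    idx = site._forward_index(position)
    if not 0 <= idx < len(site.source.seq):
        lo, hi = site.available_window()
        raise IndexError(
            f"position {position} outside the available context "
            f"[{lo}, {hi}] of {site.source_id}"
        )
    base = site.source.seq[idx]
    return base if site.strand == "+" else revcomp(base)


def sw_class(site: CutSite, positions: Sequence[int] = (-6, -5, -4)) -> str:
    """Strong/weak classification of the bases at the given positions.

    G and C are strong (S); A and T are weak (W).  The default positions
    -6..-4 yield the eight classes used to stratify guides by the sequence
    context immediately 5' of the cut.
    """
    out = []
    for pos in positions:
        base = nucleotide_at(site, pos)
        if base in "GC":
            out.append("S")
        elif base in "AT":
            out.append("W")
        else:
            raise ClassificationError(
                f"ambiguous base {base!r} at position {pos} of {site.source_id}"
            )
    return "".join(out)


def context_window(
    site: CutSite, left_len: int, right_len: int, strict: bool = False
) -> tuple[str, str]:
    """Protospacer-strand sequence context around the cut.

    Returns ``(left, right)`` where ``left`` ends at the cut boundary and
    ``right`` starts at it; ``left + right`` reconstructs the locus around
    the cut on the protospacer strand.  A window that exceeds the source is
    truncated with a warning, or raises in ``strict`` mode.
    """
    if left_len < 0 or right_len < 0:
        raise ValueError("window lengths must be non-negative")
    seq = site.source.seq
    n = len(seq)
    if site.strand == "+":
        lo, hi = site.cut_offset - left_len, site.cut_offset + right_len
    else:
        lo, hi = site.cut_offset - right_len, site.cut_offset + left_len
    if lo < 0 or hi > n:
        msg = (
            f"context window ({left_len}, {right_len}) exceeds sequence "
            f"{site.source_id} (length {n}); truncating"
        )
        if strict:
            raise IndexError(msg)
        log.warning(msg)
        lo, hi = max(lo, 0), min(hi, n)
    if site.strand == "+":
        return seq[lo : site.cut_offset], seq[site.cut_offset : hi]
    # minus strand: protospacer-strand left-of-cut is the reverse complement
    # of the forward-strand sequence right of the boundary
    left = revcomp(seq[site.cut_offset : hi])
    right = revcomp(seq[lo : site.cut_offset])
    return left, right


def _compile_iupac(pattern: str) -> list[str]:
    try:
        return [IUPAC[ch] for ch in pattern.upper()]
    except KeyError as exc:
        raise ConfigurationError(f"invalid IUPAC code {exc.args[0]!r} in PAM pattern {pattern!r}")


def _matches(seq: str, allowed: list[str]) -> bool:
    return len(seq) == len(allowed) and all(b in a for b, a in zip(seq, allowed))


def find_cut_sites(
    record: SequenceRecord, pam_pattern: str = "NGG", both_strands: bool = True
) -> list[CutSite]:
    """Scan a sequence for Cas9 targets with the given PAM pattern.

    One :class:`CutSite` is reported per PAM occurrence whose full 20-nt
    protospacer lies in-bounds.  Minus-strand sites are reported in
    protospacer-strand orientation.  Sites whose protospacer or PAM contains
    N are dropped (a count is logged).  Order is deterministic: forward
    strand 5'->3', then reverse strand 5'->3' along the forward axis.
    """
    if len(pam_pattern) != PAM_LEN:
        raise ConfigurationError(f"PAM pattern must be 3 nt, got {pam_pattern!r}")
    allowed = _compile_iupac(pam_pattern)
    seq = record.seq
    if len(seq) < MIN_SITE_SPAN:
        log.warning("sequence %s shorter than %d nt; no sites scanned", record.id, MIN_SITE_SPAN)
        return []
    sites: list[CutSite] = []
    dropped_n = 0
    # forward strand: PAM at [p, p+3), protospacer at [p-20, p)
    for p in range(PROTOSPACER_LEN, len(seq) - PAM_LEN + 1):
        pam = seq[p : p + PAM_LEN]
        if not _matches(pam, allowed):
            continue
        proto = seq[p - PROTOSPACER_LEN : p]
        if "N" in proto or "N" in pam:
            dropped_n += 1
            continue
        sites.append(
            CutSite(
                source_id=record.id, strand="+", protospacer=proto, pam=pam,
                pam_start=p, cut_offset=p - CUT_TO_PAM, source=record,
            )
        )
    if both_strands:
        # minus strand: PAM footprint at forward [p, p+3), protospacer
        # footprint at forward [p+3, p+23)
        for p in range(0, len(seq) - MIN_SITE_SPAN + 1):
            pam = revcomp(seq[p : p + PAM_LEN])
            if not _matches(pam, allowed):
                continue
            proto = revcomp(seq[p + PAM_LEN : p + MIN_SITE_SPAN])
            if "N" in proto or "N" in pam:
                dropped_n += 1
                continue
            sites.append(
                CutSite(
                    source_id=record.id, strand="-", protospacer=proto, pam=pam,
                    pam_start=p, cut_offset=p + PAM_LEN + CUT_TO_PAM, source=record,
                )
            )
    if dropped_n:
        log.info("dropped %d site(s) overlapping N in %s", dropped_n, record.id)
    return sites


def sites_to_table(sites: Iterable[CutSite]) -> pd.DataFrame:
    """Tabulate sites for reporting (pam_start is 1-based in reports)."""
    rows = []
    for s in sites:
        rows.append(
            {
                "source_id": s.source_id,
                "strand": s.strand,
                "pam_start": s.pam_start + 1,
                "protospacer": s.protospacer,
                "pam": s.pam,
                "sw_class": sw_class(s),
                "base_at_minus4": nucleotide_at(s, -4),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "source_id", "strand", "pam_start", "protospacer", "pam",
            "sw_class", "base_at_minus4",
        ],
    )
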