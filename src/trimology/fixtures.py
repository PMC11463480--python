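"""Seeded synthetic-data generation: loci with planted Cas9 sites and
junction-read mixtures with known truth labels.

Everything here is driven by a single NumPy generator seeded from the run
configuration, so fixtures are byte-identical across runs with the same
seed.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .reads import CATEGORIES, JunctionModel
from .seqcore import SequenceRecord, revcomp

log = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))

#: minimum spacing between planted PAMs: a full protospacer plus margin so
#: planted sites never overwrite each other
_MIN_SPACING = 30


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]


def generate_fixture_locus(
    seed: int,
    length: int = 2000,
    planted_pams: int = 10,
    minus4_mix: Mapping[str, float] | None = None,
    source_id: str = "synthetic_locus",
) -> tuple[SequenceRecord, pd.DataFrame]:
    """Random locus with planted forward-strand NGG sites and known -4 bases.

    The truth table lists every planted site (0-based ``pam_start``, strand,
    -4 base).  Background sequence may contain additional NGG occurrences; a
    scanner must recover at least the planted set.  ``minus4_mix`` controls
    the -4-base composition of the planted sites (default: uniform);
    fractional counts are resolved by largest remainder.
    """
    if length < 200:
        raise ValueError("length must be >= 200")
    rng = np.random.default_rng(seed)
    spacing = length // (planted_pams + 1)
    if planted_pams > 0 and spacing < _MIN_SPACING:
        raise ValueError(
            f"cannot plant {planted_pams} sites in {length} nt "
            f"(need >= {_MIN_SPACING} nt spacing)"
        )
    seq = _random_seq(rng, length)
    mix = dict(minus4_mix or {b: 0.25 for b in "ACGT"})
    total = sum(mix.values())
    if not np.isclose(total, 1.0):
        mix = {b: f / total for b, f in mix.items()}
    # largest-remainder apportionment of planted sites to -4 bases
    quotas = {b: f * planted_pams for b, f in mix.items()}
    counts = {b: int(np.floor(q)) for b, q in quotas.items()}
    leftover = planted_pams - sum(counts.values())
    for b in sorted(mix, key=lambda b: (counts[b] + 1e-9) - quotas[b])[:leftover]:
        counts[b] += 1
    minus4_bases = [b for b in sorted(counts) for _ in range(counts[b])]
    rng.shuffle(minus4_bases)

    rows = []
    for i in range(planted_pams):
        pam_start = (i + 1) * spacing
        seq[pam_start + 1] = "G"
        seq[pam_start + 2] = "G"
        seq[pam_start - 4] = minus4_bases[i]
        rows.append(
            {
                "source_id": source_id,
                "pam_start": pam_start,
                "strand": "+",
                "base_at_minus4": minus4_bases[i],
            }
        )
    record = SequenceRecord(id=source_id, seq="".join(seq))
    truth = pd.DataFrame(rows, columns=["source_id", "pam_start", "strand", "base_at_minus4"])
    return record, truth


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_junction_reads(
    model: JunctionModel,
    mixture: Mapping[str, float],
    n: int,
    seed: int,
    error_rate: float = 0.005,
    rc_fraction: float = 0.0,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Draw junction reads from a known outcome mixture.

    Each read starts from the model's expected perfect product; the sampled
    category determines the deletion applied (whole units from the tandem
    run, trims into the genome or cassette, or both), after which per-base
    substitution errors at ``error_rate`` are added.  Truth labels are
    returned alongside.  ``rc_fraction`` of reads are emitted
    reverse-complemented.
    """
    keys = list(mixture)
    fractions = np.array([mixture[k] for k in keys], dtype=float)
    if (fractions < 0).any() or abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("mixture fractions must be non-negative and sum to 1")
    unknown = set(keys) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown mixture categories: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    perfect = model.expected_perfect
    run_start, run_end = model.unit_run()
    k = model.arm.unit_len
    total_units = (run_end - run_start) // k if k else 0
    genome_is_left = model.side == "left"
    # trims leave an anchor long enough that the alignment cannot trade the
    # deletion for a free end gap
    c_hi = min(9, len(model.cassette_stub) - 11)
    needs_cassette = {"cassette_trimmed", "both_trimmed"} & set(keys)
    if needs_cassette and c_hi <= 2:
        raise ValueError(
            "cassette_stub too short to simulate cassette trimming; use >= 16 nt"
        )

    def _apply(category: str) -> str:
        if category == "scarless_NHEJ":
            return perfect
        if category == "trimology_repair":
            lost = int(rng.integers(1, max(total_units, 2)))
            return perfect[:run_start] + model.arm.unit * (total_units - lost) + perfect[run_end:]
        g = int(rng.integers(2, 9))
        c = int(rng.integers(2, c_hi)) if c_hi > 2 else 2
        u = int(rng.integers(0, 2)) * k
        if category == "genome_trimmed":
            if genome_is_left:
                return perfect[: run_start - g] + perfect[run_start + u :]
            return perfect[: run_end - u] + perfect[run_end + g :]
        if category == "cassette_trimmed":
            if genome_is_left:
                return perfect[: run_end - u] + perfect[run_end + c :]
            return perfect[: run_start - c] + perfect[run_start + u :]
        if category == "both_trimmed":
            if genome_is_left:
                return perfect[: run_start - g] + perfect[run_end + c :]
            return perfect[: run_start - c] + perfect[run_end + g :]
        raise ValueError(f"cannot simulate category {category!r}")

    labels = rng.choice(len(keys), size=n, p=fractions)
    reads: list[tuple[str, str]] = []
    rows = []
    for i, li in enumerate(labels):
        category = keys[li]
        seq = _mutate(rng, _apply(category), error_rate)
        rc = rng.random() < rc_fraction
        if rc:
            seq = revcomp(seq)
        read_id = f"read_{i:05d}"
        reads.append((read_id, seq))
        rows.append({"read_id": read_id, "category": category, "reverse_complemented": rc})
    truth = pd.DataFrame(rows, columns=["read_id", "category", "reverse_complemented"])
    return reads, truth


def write_fastq(reads: Sequence[tuple[str, str]], path) -> None:
    """Write simulated reads as FASTQ with uniform placeholder qualities."""
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")
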