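"""Trimology repair arms, knock-in donor designs and their release geometry.

A trimology arm is a k-nt unit (default k = 3) equal to the genome bases
immediately adjacent to the Cas9 cut on one side, repeated n times in tandem.
Concatenating the genome flank with such an arm creates a degenerate run of
(at least) n + 1 unit copies spanning the junction; microhomology-mediated
repair that deletes a whole number of units from this run is "repair via
microhomology usage", and the one-unit collapse is the perfect, seamless
repair product.  Which physical copy was lost is undecidable inside a
degenerate run, so all accounting is by resulting copy number.

The module also emits the two standard wet-lab layouts for producing such
donors: inverted type IIS (PaqCI) release sites for in vitro linearisation
from plasmids, and overhang-PCR primer pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .predictor import OutcomeDistribution, plus_one_fraction
from .seqcore import CutSite, context_window, revcomp

log = logging.getLogger(__name__)

#: default cassette-proximal stub standing in for the donor interior in
#: junction predictions (first four codons of eGFP)
DEFAULT_CASSETTE_STUB = "ATGGTGAGCAAG"

#: PaqCI recognition sequence; the enzyme cuts 4/8 nt downstream leaving a
#: 4-nt 5' overhang
PAQCI_SITE = "CACCTGC"
PAQCI_TOP_CUT = 4
PAQCI_BOTTOM_CUT = 8
#: sacrificial spacer absorbing the 4-nt overhang so that the double-stranded
#: core of the released fragment is exactly the designed donor
DEFAULT_PAQCI_SPACER = "ACTGACTG"

Predictor = Callable[[str, str], OutcomeDistribution]


@dataclass(frozen=True)
class TrimologyArm:
    """A tandem-repeat microhomology repair arm."""

    side: str  # "left" | "right"
    unit: str
    repeats: int

    def __post_init__(self) -> None:
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.repeats < 0:
            raise ValueError("repeats must be >= 0")
        if not self.unit:
            raise ValueError("unit must be non-empty")

    @property
    def unit_len(self) -> int:
        return len(self.unit)

    @property
    def seq(self) -> str:
        return self.unit * self.repeats


def build_trimology_arm(
    site: CutSite, side: str, unit_len: int = 3, repeats: int = 1
) -> TrimologyArm:
    """Build a repair arm whose unit is the genome sequence flanking the cut.

    The left arm's unit is the ``unit_len`` bases immediately 5' of the cut,
    the right arm's unit the ``unit_len`` bases immediately 3' of it (both on
    the protospacer strand).  ``repeats = 0`` yields an empty arm (a pure
    NHEJ / HiTi donor).
    """
    if unit_len < 1:
        raise ValueError("unit_len must be >= 1")
    if side == "left":
        unit = context_window(site, unit_len, 0, strict=True)[0]
    elif side == "right":
        unit = context_window(site, 0, unit_len, strict=True)[1]
    else:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return TrimologyArm(side=side, unit=unit, repeats=repeats)


@dataclass(frozen=True)
class PrimerPair:
    forward: str
    reverse: str


@dataclass(frozen=True)
class DigestFragment:
    """One fragment of a simulated type IIS digest.

    ``core`` is the double-stranded portion; ``left_overhang`` and
    ``right_overhang`` are 5' single-stranded extensions given on their own
    strand (top strand at the left end, bottom strand at the right end).
    """

    core: str
    left_overhang: str = ""
    right_overhang: str = ""


@dataclass(frozen=True)
class DigestReport:
    cut_positions: tuple[tuple[int, int], ...]  # (top, bottom) per site
    fragments: tuple[DigestFragment, ...]
    released_core: str | None
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class PaqmanLayout:
    seq: str
    spacer: str
    digest: DigestReport


@dataclass(frozen=True)
class DonorDesign:
    """A cassette flanked by trimology arms, plus optional production layouts."""

    cassette: str
    left_arm: TrimologyArm
    right_arm: TrimologyArm
    left_site: CutSite
    right_site: CutSite
    paqman: PaqmanLayout | None = None
    primers: PrimerPair | None = None

    @property
    def full_seq(self) -> str:
        return self.left_arm.seq + self.cassette + self.right_arm.seq


def design_donor(
    cassette: str,
    left_site: CutSite,
    right_site: CutSite | None = None,
    unit_len: int = 3,
    repeats: int = 5,
    unit_len_right: int | None = None,
    repeats_right: int | None = None,
) -> DonorDesign:
    """Design a knock-in donor with trimology arms matching the cut site(s).

    In single-gRNA mode (``right_site`` omitted) both arms derive from one
    site; in dual-gRNA mode the left arm matches the left site's 5' flank and
    the right arm the right site's 3' flank.  Per-side unit length / repeat
    overrides are explicit; the default is symmetric.
    """
    if not cassette:
        raise ValueError("cassette must be non-empty")
    cassette = cassette.upper()
    right_site = right_site or left_site
    left_arm = build_trimology_arm(left_site, "left", unit_len, repeats)
    right_arm = build_trimology_arm(
        right_site,
        "right",
        unit_len if unit_len_right is None else unit_len_right,
        repeats if repeats_right is None else repeats_right,
    )
    return DonorDesign(
        cassette=cassette,
        left_arm=left_arm,
        right_arm=right_arm,
        left_site=left_site,
        right_site=right_site,
    )


# ---------------------------------------------------------------------------
# microhomology-usage metric


def _unit_run(junction: str, cut: int, unit: str) -> tuple[int, int]:
    """Extent [start, end) of the unit-phased tandem run spanning the cut."""
    k = len(unit)
    a = 0
    while cut - (a + 1) * k >= 0 and junction[cut - (a + 1) * k : cut - a * k] == unit:
        a += 1
    b = 0
    while junction[cut + b * k : cut + (b + 1) * k] == unit:
        b += 1
    return cut - a * k, cut + b * k


@dataclass(frozen=True)
class MuHUsage:
    """Microhomology-usage summary at one donor junction (percent scale)."""

    usage_pct: float
    perfect_pct: float
    plus_one_pct: float
    distribution: OutcomeDistribution = field(repr=False, compare=False)


def junction_flanks(
    site: CutSite,
    arm: TrimologyArm,
    cassette_stub: str = DEFAULT_CASSETTE_STUB,
    flank_len: int = 30,
) -> tuple[str, str]:
    """Predictor flanks for the genome-donor junction carrying ``arm``."""
    if arm.side == "left":
        genome = context_window(site, flank_len, 0, strict=True)[0]
        return genome, arm.seq + cassette_stub
    genome = context_window(site, 0, flank_len, strict=True)[1]
    return cassette_stub + arm.seq, genome


def mu_h_usage(
    predictor: Predictor,
    site: CutSite,
    arm: TrimologyArm,
    cassette_stub: str = DEFAULT_CASSETTE_STUB,
    flank_len: int = 30,
) -> MuHUsage:
    """Percent of predicted repair that mobilises at least one trimology unit.

    The junction (genome flank | arm + stub, or mirrored for right arms) is
    fed to the predictor; outcomes whose product removes a positive whole
    number of unit copies from the tandem run spanning the junction count as
    microhomology usage.  The one-unit collapse is the perfect-repair
    sub-case and is reported separately.  Partial-unit deletions count as
    trimming, not usage.
    """
    if arm.unit != build_trimology_arm(site, arm.side, arm.unit_len, 1).unit:
        raise ValueError("arm unit does not match the site's flank; rebuild the arm")
    left, right = junction_flanks(site, arm, cassette_stub, flank_len)
    dist = predictor(left, right)
    x, cut = dist.junction, dist.cut
    run_start, run_end = _unit_run(x, cut, arm.unit)
    k = arm.unit_len
    left_copies = (cut - run_start) // k
    right_copies = (run_end - cut) // k
    plus_one = 100.0 * plus_one_fraction(dist)
    if left_copies == 0 or right_copies == 0:
        return MuHUsage(0.0, 0.0, plus_one, dist)
    total = left_copies + right_copies
    freq_by_product = {o.product: o.frequency for o in dist.outcomes}
    usage = 0.0
    perfect = 0.0
    for lost in range(1, total + 1):
        product = x[:run_start] + arm.unit * (total - lost) + x[run_end:]
        freq = freq_by_product.get(product, 0.0)
        usage += freq
        if lost == 1:
            perfect = freq
    return MuHUsage(100.0 * usage, 100.0 * perfect, plus_one, dist)


@dataclass(frozen=True)
class SweepMatrix:
    """Microhomology usage (percent) over unit lengths x tandem repeats."""

    unit_lens: tuple[int, ...]
    repeats: tuple[int, ...]
    usage_pct: np.ndarray = field(compare=False)
    perfect_pct: np.ndarray = field(compare=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.usage_pct,
            index=pd.Index(self.unit_lens, name="unit_len"),
            columns=pd.Index(self.repeats, name="repeats"),
        )

    def repeat_curve(self, unit_len: int = 3) -> pd.Series:
        """Usage as a function of repeat count for one unit length."""
        return self.to_dataframe().loc[unit_len]


def tandem_sweep(
    predictor: Predictor,
    site: CutSite,
    unit_lens: Sequence[int] = range(2, 7),
    repeats: Sequence[int] = range(1, 9),
    side: str = "left",
    cassette_stub: str = DEFAULT_CASSETTE_STUB,
    flank_len: int = 30,
) -> SweepMatrix:
    """Sweep arm unit length (default 2-6) and repeat count (default 1-8)."""
    unit_lens = tuple(unit_lens)
    repeats = tuple(repeats)
    usage = np.zeros((len(unit_lens), len(repeats)))
    perfect = np.zeros_like(usage)
    for i, k in enumerate(unit_lens):
        for j, n in enumerate(repeats):
            arm = build_trimology_arm(site, side, k, n)
            res = mu_h_usage(predictor, site, arm, cassette_stub, flank_len)
            usage[i, j] = res.usage_pct
            perfect[i, j] = res.perfect_pct
    return SweepMatrix(unit_lens, repeats, usage, perfect)


# ---------------------------------------------------------------------------
# production layouts


def simulate_paqci_digest(seq: str) -> DigestReport:
    """Simulate a PaqCI digest of a linear double-stranded sequence.

    Recognition on the top strand cuts 4 nt (top) / 8 nt (bottom) downstream
    of the site; recognition on the bottom strand cuts the mirrored distances
    upstream.  Fragments are reported with their double-stranded core and
    4-nt 5' overhangs.
    """
    cuts: list[tuple[int, int]] = []  # (top, bottom)
    warnings: list[str] = []
    for i in range(len(seq) - len(PAQCI_SITE) + 1):
        window = seq[i : i + len(PAQCI_SITE)]
        if window == PAQCI_SITE:
            top = i + len(PAQCI_SITE) + PAQCI_TOP_CUT
            bottom = i + len(PAQCI_SITE) + PAQCI_BOTTOM_CUT
        elif window == revcomp(PAQCI_SITE):
            top = i - PAQCI_BOTTOM_CUT
            bottom = i - PAQCI_TOP_CUT
        else:
            continue
        if not (0 <= top <= len(seq) and 0 <= bottom <= len(seq)):
            warnings.append(f"recognition site at {i} cuts outside the sequence; skipped")
            continue
        cuts.append((top, bottom))
    cuts.sort()
    fragments: list[DigestFragment] = []
    top_edges = [(0, 0)] + cuts + [(len(seq), len(seq))]
    for (t1, b1), (t2, b2) in zip(top_edges[:-1], top_edges[1:]):
        core_start, core_end = max(t1, b1), min(t2, b2)
        fragments.append(
            DigestFragment(
                core=seq[core_start:core_end],
                left_overhang=seq[t1:b1] if t1 < b1 else revcomp(seq[b1:t1]),
                right_overhang=revcomp(seq[t2:b2]) if t2 < b2 else seq[b2:t2],
            )
        )
    return DigestReport(
        cut_positions=tuple(cuts),
        fragments=tuple(fragments),
        released_core=None,
        warnings=tuple(warnings),
    )


def paqman_layout(donor: DonorDesign, spacer: str = DEFAULT_PAQCI_SPACER) -> PaqmanLayout:
    """Flank the donor with inverted PaqCI sites for in vitro release.

    The two recognition sites sit on opposite strands outside the arms and
    cut inward; the 8-nt sacrificial spacers absorb the enzyme's 4-nt 5'
    overhangs, so the double-stranded core of the released fragment is
    exactly the designed donor.  A recognition site occurring inside the
    cassette or arms triggers a design warning.
    """
    spacer = spacer.upper()
    if len(spacer) != PAQCI_BOTTOM_CUT:
        raise ValueError(f"spacer must be {PAQCI_BOTTOM_CUT} nt, got {len(spacer)}")
    core = donor.full_seq
    warnings = []
    for motif in (PAQCI_SITE, revcomp(PAQCI_SITE)):
        pos = [i for i in range(len(core)) if core.startswith(motif, i)]
        if pos:
            warnings.append(
                f"PaqCI recognition sequence {motif} occurs inside the donor at "
                f"position(s) {pos}; the donor will self-cut"
            )
            log.warning(warnings[-1])
    layout_seq = PAQCI_SITE + spacer + core + revcomp(spacer) + revcomp(PAQCI_SITE)
    report = simulate_paqci_digest(layout_seq)
    released = next((f.core for f in report.fragments if f.core == core), None)
    report = replace(
        report,
        released_core=released,
        warnings=report.warnings + tuple(warnings),
    )
    return PaqmanLayout(seq=layout_seq, spacer=spacer, digest=report)


def overhang_primers(donor: DonorDesign, binding_len: int = 20) -> PrimerPair:
    """Overhang-PCR primers regenerating the donor from a cassette template.

    The forward primer carries the left arm as a 5' overhang followed by the
    first ``binding_len`` nt of the cassette; the reverse primer is the
    reverse complement of the cassette's last ``binding_len`` nt plus the
    right arm.  Both are reported 5'->3'.
    """
    if binding_len < 1:
        raise ValueError("binding_len must be >= 1")
    if len(donor.cassette) < binding_len:
        raise ValueError(
            f"binding_len {binding_len} exceeds cassette length {len(donor.cassette)}"
        )
    forward = donor.left_arm.seq + donor.cassette[:binding_len]
    reverse = revcomp(donor.cassette[-binding_len:] + donor.right_arm.seq)
    return PrimerPair(forward=forward, reverse=reverse)


def simulate_overhang_pcr(donor: DonorDesign, primers: PrimerPair) -> str:
    """Reconstruct the PCR product of the primer pair on the cassette template.

    Requires non-overlapping primer binding regions (cassette at least twice
    the binding length), so the product is forward primer + template interior
    + reverse-primer complement.
    """
    binding_f = len(primers.forward) - len(donor.left_arm.seq)
    binding_r = len(primers.reverse) - len(donor.right_arm.seq)
    if binding_f + binding_r > len(donor.cassette):
        raise ValueError("primer binding regions overlap; use a longer cassette")
    interior = donor.cassette[binding_f : len(donor.cassette) - binding_r]
    return primers.forward + interior + revcomp(primers.reverse)
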