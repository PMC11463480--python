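"""ssODN edit-template design scored by joint perfect-repair probability.

An edit template of left-arm extent L and right-arm extent R is the genomic
window [cut-L, cut+R) with the requested substitutions applied, reported
5'->3' on the protospacer strand.  Each template-genome junction is scored
by concatenating the unedited genome flank with the template: this tandem-
duplicates the arm's homology, and the microhomology-mediated collapse of
that duplication -- keeping the edited copy -- is precisely the seamless
intended product.  The per-junction score is the predicted frequency of that
product (percent); the combined score is the product of the two junction
scores as probabilities (percent convention: left x right / 100), i.e. the
joint co-occurrence of perfect repair at both junctions.  Scores are stored
at full precision and displayed rounded to the nearest integer.

Scanning the combined score over a grid of (L, R) arm lengths yields the
score matrix from which the optimal template is the (tie-broken) argmax.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from .predictor import OutcomeDistribution, perfect_repair_fraction
from .seqcore import CutSite, context_window, nucleotide_at

log = logging.getLogger(__name__)

Predictor = Callable[[str, str], OutcomeDistribution]

#: offset of a PAM-anchored position from the cut boundary: position -4 is
#: the base immediately 5' of the cut, so cut-relative offset = position + 3
_PAM_TO_CUT = 3


class DesignError(ValueError):
    """An edit specification that no template in the search space can carry."""


class GenomeMismatchError(ValueError):
    """An edit's reference base disagrees with the genome."""


@dataclass(frozen=True)
class Substitution:
    """A single-base edit at a PAM-anchored position."""

    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.ref not in "ACGT" or self.alt not in "ACGT":
            raise ValueError("ref and alt must be single A/C/G/T bases")
        if self.ref == self.alt:
            raise ValueError(f"alt equals ref at position {self.position}")

    @property
    def cut_offset(self) -> int:
        """Signed offset from the cut boundary (-1 = first base 5' of cut)."""
        return self.position + _PAM_TO_CUT


@dataclass(frozen=True)
class EditSpec:
    """An ordered set of substitutions with distinct positions."""

    substitutions: tuple[Substitution, ...]

    def __post_init__(self) -> None:
        positions = [s.position for s in self.substitutions]
        if len(positions) != len(set(positions)):
            raise ValueError("edit positions must be distinct")
        object.__setattr__(
            self,
            "substitutions",
            tuple(sorted(self.substitutions, key=lambda s: s.position)),
        )

    def __len__(self) -> int:
        return len(self.substitutions)

    def min_arms(self) -> tuple[int, int]:
        """Minimal (L, R) covering every edit position."""
        min_l = max((-s.cut_offset for s in self.substitutions), default=0)
        min_r = max((s.cut_offset + 1 for s in self.substitutions), default=0)
        return max(min_l, 0), max(min_r, 0)


def parse_edit(text: str) -> Substitution:
    """Parse an edit of the form ``<position><ref>><alt>``, e.g. ``-6C>G``."""
    import re

    m = re.fullmatch(r"([+-]?\d+)([ACGT])>([ACGT])", text.strip().upper())
    if not m:
        raise ValueError(f"cannot parse edit {text!r}; expected e.g. '-6C>G'")
    return Substitution(position=int(m.group(1)), ref=m.group(2), alt=m.group(3))


@dataclass(frozen=True)
class SsodnDesign:
    """An edit-carrying single-stranded template with per-junction scores."""

    site: CutSite
    edits: EditSpec
    L: int
    R: int
    seq: str
    score_left: float | None = None
    score_right: float | None = None
    pythia_score_pct: float | None = None

    @property
    def displayed_score(self) -> int | None:
        return None if self.pythia_score_pct is None else display_score(self.pythia_score_pct)


def build_ssodn(site: CutSite, edits: EditSpec, L: int, R: int) -> SsodnDesign:
    """Construct the edited template of arm extents (L, R); scores unset.

    Raises :class:`DesignError` (naming the minimal covering arms) when an
    edit falls outside the template, and :class:`GenomeMismatchError` when a
    reference base disagrees with the genome.
    """
    if L < 1 or R < 1:
        raise ValueError("arm extents L and R must be >= 1")
    min_l, min_r = edits.min_arms()
    if L < min_l or R < min_r:
        raise DesignError(
            f"edits outside arms (L={L}, R={R}); minimal covering arms are "
            f"(L={max(min_l, 1)}, R={max(min_r, 1)})"
        )
    left, right = context_window(site, L, R, strict=True)
    template = list(left + right)
    for sub in edits.substitutions:
        idx = L + sub.cut_offset
        if template[idx] != sub.ref:
            raise GenomeMismatchError(
                f"position {sub.position}: genome has {template[idx]!r}, "
                f"edit expects ref {sub.ref!r}"
            )
        template[idx] = sub.alt
    return SsodnDesign(site=site, edits=edits, L=L, R=R, seq="".join(template))


def diff_against_genome(design: SsodnDesign) -> EditSpec:
    """Recover the edit specification by diffing the template with the genome."""
    left, right = context_window(design.site, design.L, design.R, strict=True)
    genome = left + right
    subs = [
        Substitution(position=i - design.L - _PAM_TO_CUT, ref=g, alt=t)
        for i, (g, t) in enumerate(zip(genome, design.seq))
        if g != t
    ]
    return EditSpec(tuple(subs))


def junction_score(
    predictor: Predictor,
    site: CutSite,
    design: SsodnDesign,
    side: str,
    flank_len: int = 30,
) -> float:
    """Perfect-repair score (percent) at one template-genome junction.

    Left junction: genome flank (ending at the cut) followed by the full
    template; the intended product deletes the flank's duplicated L bases,
    leaving the seamless edited sequence.  Right side mirrored.
    """
    if side == "left":
        flank = context_window(site, flank_len, 0, strict=True)[0]
        dist = predictor(flank, design.seq)
        x, cut = dist.junction, dist.cut
        if cut < design.L:
            raise ValueError(
                f"predictor window ({cut} nt) shorter than left arm L={design.L}"
            )
        intended = x[: cut - design.L] + x[cut:]
    elif side == "right":
        flank = context_window(site, 0, flank_len, strict=True)[1]
        dist = predictor(design.seq, flank)
        x, cut = dist.junction, dist.cut
        if len(x) - cut < design.R:
            raise ValueError(
                f"predictor window ({len(x) - cut} nt) shorter than right arm R={design.R}"
            )
        intended = x[:cut] + x[cut + design.R :]
    else:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    return 100.0 * perfect_repair_fraction(dist, intended)


def pythia_score(score_left: float, score_right: float) -> float:
    """Combined score: product of the two junction scores as probabilities.

    Both arguments and the result are on the percent scale, so the combined
    score is ``left * right / 100`` (e.g. 94 and 46 combine to 43.24,
    displayed as 43).
    """
    if not (0.0 <= score_left <= 100.0 and 0.0 <= score_right <= 100.0):
        raise ValueError("junction scores must be percentages in [0, 100]")
    return score_left * score_right / 100.0


def display_score(score_pct: float) -> int:
    """Nearest-integer display convention for combined scores."""
    return int(np.floor(score_pct + 0.5))


def score_design(
    predictor: Predictor, design: SsodnDesign, flank_len: int = 30
) -> SsodnDesign:
    """Fill in both junction scores and the combined score."""
    left = junction_score(predictor, design.site, design, "left", flank_len)
    right = junction_score(predictor, design.site, design, "right", flank_len)
    return replace(
        design,
        score_left=left,
        score_right=right,
        pythia_score_pct=pythia_score(left, right),
    )


@dataclass(frozen=True)
class PythiaMatrix:
    """Combined scores over a grid of left x right arm lengths.

    Cells whose arms do not cover every edit are invalid and hold NaN
    (they are not zero -- no template exists there).
    """

    L_range: tuple[int, ...]
    R_range: tuple[int, ...]
    scores: np.ndarray = field(compare=False)  # shape (len(L_range), len(R_range))
    score_left: np.ndarray = field(compare=False)
    score_right: np.ndarray = field(compare=False)

    def cell(self, L: int, R: int) -> float:
        return float(self.scores[self.L_range.index(L), self.R_range.index(R)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores,
            index=pd.Index(self.L_range, name="L"),
            columns=pd.Index(self.R_range, name="R"),
        )


def pythia_matrix(
    predictor: Predictor,
    site: CutSite,
    edits: EditSpec,
    L_range: Sequence[int] = range(1, 25),
    R_range: Sequence[int] = range(1, 25),
    flank_len: int = 30,
) -> PythiaMatrix:
    """Compute the combined-score matrix over all (L, R) in the given ranges."""
    L_range = tuple(L_range)
    R_range = tuple(R_range)
    min_l, min_r = edits.min_arms()
    shape = (len(L_range), len(R_range))
    scores = np.full(shape, np.nan)
    lefts = np.full(shape, np.nan)
    rights = np.full(shape, np.nan)
    any_valid = False
    for i, L in enumerate(L_range):
        for j, R in enumerate(R_range):
            if L < max(min_l, 1) or R < max(min_r, 1):
                continue
            design = score_design(predictor, build_ssodn(site, edits, L, R), flank_len)
            scores[i, j] = design.pythia_score_pct
            lefts[i, j] = design.score_left
            rights[i, j] = design.score_right
            any_valid = True
    if not any_valid:
        raise DesignError(
            f"no (L, R) cell in the given ranges covers all edits "
            f"(minimal arms L>={min_l}, R>={min_r})"
        )
    return PythiaMatrix(L_range, R_range, scores, lefts, rights)


def optimal_ssodn(
    predictor: Predictor,
    site: CutSite,
    edits: EditSpec,
    L_range: Sequence[int] = range(1, 25),
    R_range: Sequence[int] = range(1, 25),
    flank_len: int = 30,
) -> tuple[SsodnDesign, PythiaMatrix]:
    """Best-scoring template over the arm-length grid, with the full matrix.

    Ties are broken by shorter total length L+R, then smaller |L-R|, then
    smaller L, making the argmax deterministic.
    """
    matrix = pythia_matrix(predictor, site, edits, L_range, R_range, flank_len)
    best: tuple | None = None
    best_cell: tuple[int, int] | None = None
    for i, L in enumerate(matrix.L_range):
        for j, R in enumerate(matrix.R_range):
            s = matrix.scores[i, j]
            if np.isnan(s):
                continue
            key = (-s, L + R, abs(L - R), L)
            if best is None or key < best:
                best = key
                best_cell = (L, R)
    L, R = best_cell  # non-empty guaranteed by pythia_matrix
    design = build_ssodn(site, edits, L, R)
    i, j = matrix.L_range.index(L), matrix.R_range.index(R)
    design = replace(
        design,
        score_left=float(matrix.score_left[i, j]),
        score_right=float(matrix.score_right[i, j]),
        pythia_score_pct=float(matrix.scores[i, j]),
    )
    return design, matrix


def editing_window_scan(
    predictor: Predictor,
    site: CutSite,
    positions: Sequence[int] = range(-22, 18),
    alts: Sequence[str] | None = None,
    L_range: Sequence[int] = range(1, 25),
    R_range: Sequence[int] = range(1, 25),
    flank_len: int = 30,
) -> pd.DataFrame:
    """Maximal combined score per (position, substitution) across the window.

    For each PAM-anchored position and each alternative base (default: all
    three), the optimal template is searched over the arm-length grid.  The
    returned table has one row per (position, alt) with the maximal score,
    the optimal (L, R) and the total template length.  Positions outside the
    available context are skipped with a warning.
    """
    rows = []
    for pos in positions:
        try:
            ref = nucleotide_at(site, pos)
        except IndexError:
            log.warning("position %d outside context of %s; skipped", pos, site.source_id)
            continue
        pos_alts = alts or [b for b in "ACGT" if b != ref]
        for alt in pos_alts:
            if alt == ref:
                continue
            edits = EditSpec((Substitution(position=pos, ref=ref, alt=alt),))
            try:
                design, _ = optimal_ssodn(predictor, site, edits, L_range, R_range, flank_len)
            except DesignError:
                log.warning(
                    "no valid template for %d%s>%s within the arm ranges; skipped",
                    pos, ref, alt,
                )
                continue
            rows.append(
                {
                    "position": pos,
                    "ref": ref,
                    "alt": alt,
                    "max_score_pct": design.pythia_score_pct,
                    "optimal_L": design.L,
                    "optimal_R": design.R,
                    "total_length": design.L + design.R,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "position", "ref", "alt", "max_score_pct",
            "optimal_L", "optimal_R", "total_length",
        ],
    )


def sample_by_decile(
    matrix: PythiaMatrix, per_bin: int = 3, seed: int = 0
) -> pd.DataFrame:
    """Draw templates per decile bin of the combined score.

    Scores are binned into ten equal-width bins spanning 0-100 (the last bin
    closed at 100); ``per_bin`` valid cells are sampled without replacement
    from each populated bin (all of them when a bin holds fewer).  Three
    templates per decile over three guides reproduces a 90-template panel.
    """
    rng = np.random.default_rng(seed)
    rows = []
    cells = [
        (L, R, float(matrix.scores[i, j]))
        for i, L in enumerate(matrix.L_range)
        for j, R in enumerate(matrix.R_range)
        if not np.isnan(matrix.scores[i, j])
    ]
    for b in range(10):
        lo, hi = 10.0 * b, 10.0 * (b + 1)
        pool = [
            c for c in cells if lo <= c[2] < hi or (b == 9 and c[2] == 100.0)
        ]
        if not pool:
            continue
        take = min(per_bin, len(pool))
        for idx in sorted(rng.choice(len(pool), size=take, replace=False)):
            L, R, score = pool[idx]
            rows.append({"decile": b, "L": L, "R": R, "score_pct": score})
    return pd.DataFrame(rows, columns=["decile", "L", "R", "score_pct"])


# ---------------------------------------------------------------------------
# minimal-change codon reversion


@dataclass(frozen=True)
class CodonEdit:
    """Minimal-change reversion of a variant codon to a target amino acid."""

    variant_codon: str
    target_aa: str
    chosen_codon: str
    n_changes: int
    edit_positions: tuple[int, ...]  # 0-based offsets within the codon


def _codons_for(aa: str, table=None) -> list[str]:
    table = table or standard_dna_table
    aa = aa.upper()
    if aa == "*":
        return sorted(table.stop_codons)
    codons = sorted(c for c, a in table.forward_table.items() if a == aa)
    if not codons:
        raise ValueError(f"{aa!r} is not a standard amino acid")
    return codons


def codon_revert(variant_codon: str, wt_aa: str, codon_table=None) -> CodonEdit:
    """Minimal-Hamming-distance codon encoding the wild-type amino acid.

    Brute force over every codon of ``wt_aa`` (use ``'*'`` for a stop
    target); ties are broken lexicographically by codon.  The resulting
    per-base edits convert to an :class:`EditSpec` once the codon's genomic
    frame is known (see :func:`codon_edit_to_editspec`).
    """
    variant_codon = variant_codon.upper()
    if len(variant_codon) != 3 or any(b not in "ACGT" for b in variant_codon):
        raise ValueError(f"variant codon must be 3 nt over A/C/G/T: {variant_codon!r}")
    best: CodonEdit | None = None
    for codon in _codons_for(wt_aa, codon_table):
        diff = tuple(i for i in range(3) if codon[i] != variant_codon[i])
        if best is None or len(diff) < best.n_changes:
            best = CodonEdit(
                variant_codon=variant_codon,
                target_aa=wt_aa.upper(),
                chosen_codon=codon,
                n_changes=len(diff),
                edit_positions=diff,
            )
    return best


def codon_edit_to_editspec(edit: CodonEdit, codon_positions: Sequence[int]) -> EditSpec:
    """Map a codon reversion onto PAM-anchored genome positions.

    ``codon_positions`` gives the PAM-anchored position of each of the three
    codon bases on the protospacer strand (supplied by the caller; the
    designer does not infer gene models).
    """
    if len(codon_positions) != 3:
        raise ValueError("codon_positions must list the three codon base positions")
    subs = tuple(
        Substitution(
            position=codon_positions[i],
            ref=edit.variant_codon[i],
            alt=edit.chosen_codon[i],
        )
        for i in edit.edit_positions
    )
    return EditSpec(subs)
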