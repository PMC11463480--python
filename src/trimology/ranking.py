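"""Guide-RNA selection rules for tandem-microhomology (trimology) integration.

Three empirical rules favour efficient microhomology-mediated knock-in at a
candidate cut site: (1) a G at position -4 (the base immediately 5' of the
cut; the hierarchy is G > C > A > T), (2) a low predicted +1-insertion
fraction at the genome-donor junction (default threshold 25%), and (3) a
high predicted fraction of junction repair that mobilises the trimology
units (no published cutoff exists, so "high" defaults to at or above the
candidate pool's median, exposed as a percentile knob).

The module also reproduces the screen-design procedure: candidates are
restricted to a fixed PAM-proximal core (AGG at positions -3..-1), stratified
into the eight strong/weak classes at positions -6..-4, and within each
class binned by predicted microhomology-mediated repair at the unmodified
locus, picking one guide per quantile bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product as iter_product
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .donors import DEFAULT_CASSETTE_STUB, MuHUsage, build_trimology_arm, mu_h_usage
from .predictor import OutcomeDistribution
from .seqcore import CutSite, context_window, nucleotide_at, sw_class

log = logging.getLogger(__name__)

Predictor = Callable[[str, str], OutcomeDistribution]

#: -4 base hierarchy for integration efficiency (best first)
MINUS4_HIERARCHY = "GCAT"

ALL_SW_CLASSES = tuple("".join(p) for p in iter_product("SW", repeat=3))


@dataclass(frozen=True)
class RankedSite:
    site: CutSite
    base_minus4: str
    plus_one_pct: float
    mu_h_usage_pct: float
    perfect_pct: float
    rule_flags: tuple[bool, bool, bool]
    rank_score: int = 0

    @property
    def n_rules(self) -> int:
        return sum(self.rule_flags)


def rank_for_integration(
    predictor: Predictor,
    sites: Sequence[CutSite],
    unit_len: int = 3,
    repeats: int = 5,
    plus_one_threshold: float = 25.0,
    usage_percentile: float = 50.0,
    cassette_stub: str = DEFAULT_CASSETTE_STUB,
    flank_len: int = 30,
) -> list[RankedSite]:
    """Rank candidate sites for trimology integration by the three rules.

    Each site is evaluated at its left genome-donor junction with a
    ``unit_len`` x ``repeats`` arm.  Primary sort is by number of satisfied
    rules, then the -4 base hierarchy G > C > A > T, then microhomology
    usage descending; residual ties fall back to (source_id, pam_start) so
    the order is total and input-order independent.
    """
    if not sites:
        return []
    evaluated: list[tuple[CutSite, str, MuHUsage]] = []
    for site in sites:
        arm = build_trimology_arm(site, "left", unit_len, repeats)
        res = mu_h_usage(predictor, site, arm, cassette_stub, flank_len)
        evaluated.append((site, nucleotide_at(site, -4), res))
    usage_cutoff = float(
        np.percentile([r.usage_pct for _, _, r in evaluated], usage_percentile)
    )
    ranked = [
        RankedSite(
            site=site,
            base_minus4=minus4,
            plus_one_pct=res.plus_one_pct,
            mu_h_usage_pct=res.usage_pct,
            perfect_pct=res.perfect_pct,
            rule_flags=(
                minus4 == "G",
                res.plus_one_pct < plus_one_threshold,
                res.usage_pct >= usage_cutoff,
            ),
        )
        for site, minus4, res in evaluated
    ]
    ranked.sort(
        key=lambda r: (
            -r.n_rules,
            MINUS4_HIERARCHY.index(r.base_minus4),
            -r.mu_h_usage_pct,
            r.site.source_id,
            r.site.pam_start,
            r.site.strand,
        )
    )
    return [
        RankedSite(
            site=r.site,
            base_minus4=r.base_minus4,
            plus_one_pct=r.plus_one_pct,
            mu_h_usage_pct=r.mu_h_usage_pct,
            perfect_pct=r.perfect_pct,
            rule_flags=r.rule_flags,
            rank_score=i,
        )
        for i, r in enumerate(ranked)
    ]


def ranked_to_table(ranked: Sequence[RankedSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": r.rank_score,
                "source_id": r.site.source_id,
                "strand": r.site.strand,
                "pam_start": r.site.pam_start + 1,
                "protospacer": r.site.protospacer,
                "base_minus4": r.base_minus4,
                "plus_one_pct": r.plus_one_pct,
                "mu_h_usage_pct": r.mu_h_usage_pct,
                "perfect_pct": r.perfect_pct,
                "rule_minus4_G": r.rule_flags[0],
                "rule_low_plus_one": r.rule_flags[1],
                "rule_high_mu_h": r.rule_flags[2],
            }
            for r in ranked
        ]
    )


def mmej_deletion_mass(predictor: Predictor, site: CutSite, flank_len: int = 30) -> float:
    """Predicted microhomology-mediated deletion mass at the unmodified locus.

    Fraction of predicted repair at the bare cut (no exogenous donor) that is
    a deletion with at least 1 nt of flanking microhomology.
    """
    left, right = context_window(site, flank_len, flank_len, strict=True)
    dist = predictor(left, right)
    return sum(
        o.frequency for o in dist.outcomes if o.category == "deletion" and o.mh_len >= 1
    )


@dataclass(frozen=True)
class ScreenSelection:
    table: pd.DataFrame = field(compare=False)
    shortfalls: dict = field(compare=False)


def screen_selection(
    predictor: Predictor,
    sites: Sequence[CutSite],
    pam_core: str = "AGG",
    per_class: int = 4,
    exclusion_list: Iterable[str] = (),
    flank_len: int = 30,
) -> ScreenSelection:
    """Select a balanced guide panel across the eight strong/weak classes.

    Candidates are filtered to ``pam_core`` at positions -3..-1 and to
    sources not on the exclusion list, stratified by the S/W class of
    positions -6..-4, ranked within each class by predicted
    microhomology-mediated repair at the unmodified locus, split into
    ``per_class`` equal-frequency (quantile) bins, and the median-ranked
    candidate of each bin is selected.  Under-filled classes are reported as
    shortfalls; a full pool yields ``8 * per_class`` selections.
    """
    excluded = set(exclusion_list)
    candidates = []
    for site in sites:
        if site.source_id in excluded:
            continue
        core = "".join(nucleotide_at(site, p) for p in (-3, -2, -1))
        if core != pam_core.upper():
            continue
        candidates.append(
            {
                "site": site,
                "sw_class": sw_class(site),
                "mmej_mass": mmej_deletion_mass(predictor, site, flank_len),
            }
        )
    rows = []
    shortfalls: dict[str, int] = {}
    for cls in ALL_SW_CLASSES:
        members = sorted(
            (c for c in candidates if c["sw_class"] == cls),
            key=lambda c: (c["mmej_mass"], c["site"].source_id, c["site"].pam_start),
        )
        n_bins = min(per_class, len(members))
        if n_bins < per_class:
            shortfalls[cls] = per_class - n_bins
        if n_bins == 0:
            continue
        # equal-frequency bins over the within-class MMEJ-mass ranking
        bin_of = [min(i * n_bins // len(members), n_bins - 1) for i in range(len(members))]
        for b in range(n_bins):
            bin_members = [m for m, bi in zip(members, bin_of) if bi == b]
            pick = bin_members[len(bin_members) // 2]
            site = pick["site"]
            rows.append(
                {
                    "sw_class": cls,
                    "bin": b,
                    "source_id": site.source_id,
                    "strand": site.strand,
                    "pam_start": site.pam_start + 1,
                    "protospacer": site.protospacer,
                    "mmej_mass": pick["mmej_mass"],
                }
            )
    if shortfalls:
        log.warning("under-filled S/W classes: %s", shortfalls)
    table = pd.DataFrame(
        rows,
        columns=[
            "sw_class", "bin", "source_id", "strand", "pam_start",
            "protospacer", "mmej_mass",
        ],
    )
    return ScreenSelection(table=table, shortfalls=shortfalls)
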