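"""Repair-outcome genotypes and frequencies at a double-strand-break junction.

The junction is described by two flanks, ``left`` ending at the cut and
``right`` starting at it (both on the protospacer strand).  The genotype space
contains every deletion that spans the cut boundary, merged by product
sequence (degenerate placements within repeated sequence collapse to one
genotype), plus a single templated +1 insertion duplicating the base at
position -4.

Frequencies come from a pluggable predictor.  The shipped
:class:`SurrogatePredictor` is a mechanistic microhomology-strength model:
a deletion of length ``d`` with maximal microhomology ``m`` receives weight

    (m + GC(mh)) * exp(-d / tau_mh)        for m >= 1
    phi_mhless   * exp(-d / tau_mhless)    for m == 0

and the +1 insertion carries a fixed mass keyed to the -4 base (highest for
T, lowest for G, mirroring the observed inverse relationship between the -4
base and +1-insertion propensity).  Deletion weights are normalised to the
remaining mass, so every distribution sums to one.  An adapter class lets an
external outcome model (e.g. a trained deep-learning predictor) stand behind
the same contract.
"""

from __future__ import annotations

import json
import math
import re
import subprocess
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Callable, Mapping, Sequence

import pandas as pd

_ACGT_RE = re.compile(r"^[ACGT]+$")

NORMALISATION_TOL = 1e-9


class PredictorUnavailableError(RuntimeError):
    """The configured external predictor could not be reached."""


def _check_flank(seq: str, what: str) -> None:
    if not seq or not _ACGT_RE.match(seq):
        raise ValueError(f"{what} flank must be non-empty A/C/G/T, got {seq!r}")


@dataclass(frozen=True)
class RepairOutcome:
    """One resolved repair product at a junction.

    For deletions, ``del_start`` is the leftmost-aligned start of the deleted
    interval in the junction string and ``mh_len``/``mh_seq`` describe the
    maximal flanking microhomology that makes placements degenerate
    (``mh_len == 0`` means microhomology-less).  For the +1 insertion,
    ``inserted_base`` duplicates the base at position -4.
    """

    category: str  # "deletion" | "insertion_1bp"
    product: str
    frequency: float = 0.0
    del_start: int | None = None
    del_len: int = 0
    mh_len: int = 0
    mh_seq: str = ""
    inserted_base: str | None = None

    def __post_init__(self) -> None:
        if self.category not in ("deletion", "insertion_1bp"):
            raise ValueError(f"unknown outcome category {self.category!r}")
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"frequency out of [0,1]: {self.frequency}")


@dataclass(frozen=True)
class OutcomeDistribution:
    """Predicted repair outcomes at one junction.

    ``junction`` is the (possibly trimmed) flank concatenation actually fed
    to the predictor and ``cut`` the index of the cut boundary within it;
    every ``product`` is expressed in this window.
    """

    junction: str
    cut: int
    outcomes: tuple[RepairOutcome, ...]
    params_id: str

    def __post_init__(self) -> None:
        total = sum(o.frequency for o in self.outcomes)
        if abs(total - 1.0) > NORMALISATION_TOL:
            raise ValueError(
                f"outcome frequencies must sum to 1 (got {total!r}) [{self.params_id}]"
            )
        products = [o.product for o in self.outcomes]
        if len(products) != len(set(products)):
            raise ValueError("duplicate products in outcome distribution")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "product": o.product,
                    "category": o.category,
                    "del_len": o.del_len,
                    "mh_len": o.mh_len,
                    "mh_seq": o.mh_seq,
                    "frequency": o.frequency,
                }
                for o in self.outcomes
            ]
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "junction": self.junction,
                "cut": self.cut,
                "params_id": self.params_id,
                "outcomes": [
                    {
                        "product": o.product,
                        "category": o.category,
                        "del_start": o.del_start,
                        "del_len": o.del_len,
                        "mh_len": o.mh_len,
                        "mh_seq": o.mh_seq,
                        "inserted_base": o.inserted_base,
                        "frequency": o.frequency,
                    }
                    for o in self.outcomes
                ],
            }
        )


def enumerate_deletion_genotypes(
    left: str, right: str, max_del: int
) -> list[RepairOutcome]:
    """Enumerate cut-spanning deletion genotypes, merged by product.

    Every deletion of length 1..max_del whose interval touches the cut
    boundary (at least one placement with start <= cut <= end) contributes;
    placements yielding the same product are merged into one genotype with
    the leftmost-aligned start and the maximal microhomology annotation.
    Frequencies are left at zero.
    """
    _check_flank(left, "left")
    _check_flank(right, "right")
    if max_del < 1:
        raise ValueError("max_del must be >= 1")
    x = left + right
    cut = len(left)
    genotypes: dict[str, RepairOutcome] = {}
    for d in range(1, min(max_del, len(x)) + 1):
        seen_products: set[str] = set()
        for s in range(max(cut - d, 0), min(cut, len(x) - d) + 1):
            product = x[:s] + x[s + d :]
            if product in seen_products:
                continue
            seen_products.add(product)
            key = product
            if key in genotypes:
                continue  # same product reachable at another d is impossible (lengths differ)
            # canonical leftmost placement
            s_min = s
            while s_min > 0 and x[s_min - 1] == x[s_min + d - 1]:
                s_min -= 1
            # degeneracy run: x[t] == x[t+d] for t in [s_min, s_min + m_run)
            m_run = 0
            while s_min + d + m_run < len(x) and x[s_min + m_run] == x[s_min + d + m_run]:
                m_run += 1
            # microhomology proper is the cross-cut part of the repeat: the
            # left copy must lie 5' of the cut and the right copy 3' of it,
            # i.e. matched positions t with t < cut <= t + d
            mh_lo = max(s_min, cut - d)
            mh_hi = min(s_min + m_run, cut)
            m = max(0, mh_hi - mh_lo)
            genotypes[key] = RepairOutcome(
                category="deletion",
                product=product,
                del_start=s_min,
                del_len=d,
                mh_len=m,
                mh_seq=x[mh_lo:mh_hi] if m else "",
            )
    return sorted(genotypes.values(), key=lambda o: (o.del_len, o.del_start))


@dataclass(frozen=True)
class PredictorParams:
    """Parameters of the surrogate outcome model.

    ``tau_mh``/``tau_mhless`` are exponential length-decay constants (nt) for
    microhomology-mediated and microhomology-less deletions, ``phi_mhless``
    the relative weight of the microhomology-less channel, and
    ``insertion_mass_by_minus4`` the total +1-insertion fraction per -4 base.
    ``context_window`` is the number of nt of each flank retained around the
    cut before prediction.
    """

    max_del: int = 30
    tau_mh: float = 20.0
    tau_mhless: float = 10.0
    phi_mhless: float = 0.2
    insertion_mass_by_minus4: Mapping[str, float] = field(
        default_factory=lambda: MappingProxyType(
            {"T": 0.35, "A": 0.25, "C": 0.12, "G": 0.06}
        )
    )
    context_window: int = 30

    def __post_init__(self) -> None:
        if min(self.max_del, self.context_window) < 1:
            raise ValueError("max_del and context_window must be positive")
        if min(self.tau_mh, self.tau_mhless, self.phi_mhless) <= 0:
            raise ValueError("decay constants and weights must be positive")
        for base, mass in self.insertion_mass_by_minus4.items():
            if not 0.0 <= mass < 1.0:
                raise ValueError(f"insertion mass for {base} out of [0,1): {mass}")

    @property
    def params_id(self) -> str:
        return (
            f"surrogate-mh:D{self.max_del},tau{self.tau_mh:g},"
            f"tau0{self.tau_mhless:g},phi0{self.phi_mhless:g},W{self.context_window}"
        )


def _gc_count(seq: str) -> int:
    return seq.count("G") + seq.count("C")


def predict(
    left: str, right: str, params: PredictorParams | None = None
) -> OutcomeDistribution:
    """Predict the repair-outcome distribution at a junction (surrogate model).

    Flanks are trimmed to ``params.context_window`` nt each around the cut.
    Deterministic: identical inputs yield identical distributions.
    """
    params = params or PredictorParams()
    _check_flank(left, "left")
    _check_flank(right, "right")
    left = left[-params.context_window :]
    right = right[: params.context_window]
    minus4 = left[-1]
    try:
        p_ins = params.insertion_mass_by_minus4[minus4]
    except KeyError:
        raise ValueError(f"no +1-insertion mass configured for -4 base {minus4!r}")

    max_del = min(params.max_del, len(left), len(right))
    genotypes = enumerate_deletion_genotypes(left, right, max_del)
    weights = []
    for g in genotypes:
        if g.mh_len >= 1:
            w = (g.mh_len + _gc_count(g.mh_seq)) * math.exp(-g.del_len / params.tau_mh)
        else:
            w = params.phi_mhless * math.exp(-g.del_len / params.tau_mhless)
        weights.append(w)
    total_w = sum(weights)
    del_mass = 1.0 - p_ins
    outcomes = [
        RepairOutcome(
            category=g.category,
            product=g.product,
            frequency=del_mass * w / total_w,
            del_start=g.del_start,
            del_len=g.del_len,
            mh_len=g.mh_len,
            mh_seq=g.mh_seq,
        )
        for g, w in zip(genotypes, weights)
    ]
    if p_ins > 0:
        outcomes.append(
            RepairOutcome(
                category="insertion_1bp",
                product=left + minus4 + right,
                frequency=p_ins,
                inserted_base=minus4,
            )
        )
    return OutcomeDistribution(
        junction=left + right,
        cut=len(left),
        outcomes=tuple(outcomes),
        params_id=params.params_id,
    )


class SurrogatePredictor:
    """Callable wrapper binding :func:`predict` to one parameterisation."""

    def __init__(self, params: PredictorParams | None = None):
        self.params = params or PredictorParams()

    @property
    def params_id(self) -> str:
        return self.params.params_id

    def __call__(self, left: str, right: str) -> OutcomeDistribution:
        return predict(left, right, self.params)


def plus_one_fraction(dist: OutcomeDistribution) -> float:
    """Summed frequency of +1-insertion outcomes (fraction in [0,1])."""
    return sum(o.frequency for o in dist.outcomes if o.category == "insertion_1bp")


def perfect_repair_fraction(dist: OutcomeDistribution, intended_product: str) -> float:
    """Summed frequency of outcomes whose product equals ``intended_product``.

    The intended product must be expressed in the same junction window as the
    distribution's products; returns 0 if absent.
    """
    return sum(o.frequency for o in dist.outcomes if o.product == intended_product)


class ExternalPredictor:
    """Adapter exposing an external outcome model behind the same contract.

    The adapter is either a command (list of argv strings) spoken to over a
    JSON-lines subprocess boundary -- one request object
    ``{"left": ..., "right": ...}`` per line on stdin, one response object
    ``{"params_id": ..., "outcomes": [...]}`` per line on stdout -- or any
    callable mapping a request dict to such a response dict.  Responses are
    validated against the distribution invariants (frequencies sum to one,
    no duplicate products) before use, so downstream code is
    predictor-agnostic.
    """

    def __init__(self, adapter: Sequence[str] | Callable[[dict], dict]):
        self.adapter = adapter

    def __call__(self, left: str, right: str) -> OutcomeDistribution:
        _check_flank(left, "left")
        _check_flank(right, "right")
        request = {"left": left, "right": right}
        if callable(self.adapter):
            response = self.adapter(request)
        else:
            try:
                proc = subprocess.run(
                    list(self.adapter),
                    input=json.dumps(request) + "\n",
                    capture_output=True,
                    text=True,
                    check=True,
                )
            except (OSError, subprocess.SubprocessError) as exc:
                raise PredictorUnavailableError(
                    f"external predictor {self.adapter!r} unreachable ({exc}); "
                    "the built-in SurrogatePredictor can be used instead"
                ) from exc
            try:
                response = json.loads(proc.stdout.strip().splitlines()[-1])
            except (IndexError, json.JSONDecodeError) as exc:
                raise PredictorUnavailableError(
                    f"external predictor {self.adapter!r} returned malformed output"
                ) from exc
        outcomes = tuple(
            RepairOutcome(
                category=o["category"],
                product=o["product"],
                frequency=float(o["frequency"]),
                del_start=o.get("del_start"),
                del_len=int(o.get("del_len", 0)),
                mh_len=int(o.get("mh_len", 0)),
                mh_seq=o.get("mh_seq", ""),
                inserted_base=o.get("inserted_base"),
            )
            for o in response["outcomes"]
        )
        return OutcomeDistribution(
            junction=left + right,
            cut=len(left),
            outcomes=outcomes,
            params_id=str(response.get("params_id", "external")),
        )
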