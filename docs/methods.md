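# Methods

## Scope and model

The package designs CRISPR/Cas9 knock-in donors and single-stranded
oligonucleotide (ssODN) edit templates on the premise that repair of a
Cas9-induced double-strand break (DSB) is predictable from the local
sequence context on both sides of the break — including when one side is
exogenous donor DNA. Everything is computed on the protospacer strand in a
PAM-anchored frame: PAM bases are positions 0–2, the protospacer −20..−1,
and the blunt cut sits between −4 and −3. Minus-strand sites are fully
re-expressed on the protospacer strand at scan time, so no downstream
module branches on strand.

The main-text convention for strong/weak stratification is ambiguous in the
source material of this problem domain (three vs four positions left of the
cut); this package uses positions −6..−4, which yields exactly the eight
S/W classes the screen design requires alongside a fixed AGG core at
−3..−1.

## The junction outcome model

A junction is two flanks, `left` ending at the cut and `right` starting at
it. The genotype space is:

* every deletion of length 1..`max_del` with at least one placement
  spanning the cut boundary, **merged by product string** — placements
  inside repeated sequence are degenerate and must not be double-counted.
  Each genotype records its leftmost-aligned start and its *cross-cut*
  microhomology: the matched positions `t` (`x[t] == x[t+d]`) whose left
  copy lies 5′ of the cut and whose right copy lies 3′ of it. A repeat
  confined to one side of the break creates placement degeneracy but no
  annealing substrate, so it is not counted as microhomology.
* a single templated +1 insertion duplicating the −4 base.

The shipped surrogate assigns a deletion of length `d` with microhomology
length `m` (sequence μH) the weight `(m + GC(μH))·exp(−d/τ)` when `m ≥ 1`
and `φ₀·exp(−d/τ₀)` when `m = 0`; the +1 insertion carries a fixed total
mass per −4 base and the deletion block is normalised to the remainder.
This is a mechanistic microhomology-strength model in the tradition of
pattern-score approaches: annealing propensity grows with microhomology
length and GC content and decays exponentially with resection distance.
It is *not* a trained outcome predictor and is not expected to reproduce
any trained model's numeric outputs; it exists so every downstream
algorithm (usage metrics, score matrices, ranking, screens) is exact,
deterministic and testable offline. A trained predictor can stand behind
the same contract through `ExternalPredictor` (JSON-lines over a
subprocess, or any callable), and every distribution is validated against
the same invariants (frequencies sum to 1 within 1e−9, products unique).

Parameters (defaults): `max_del` 30 nt, `tau_mh` 20 nt, `tau_mhless`
10 nt, `phi_mhless` 0.2, insertion masses T 0.35 / A 0.25 / C 0.12 /
G 0.06, context window `W` 30 nt per side. The insertion masses implement
the observed hierarchy: a −4 G favours MMEJ (lowest +1 propensity), a −4 T
the opposite. τ values are on the scale of reported deletion-length decay
at Cas9 breaks; they are deliberately exposed rather than hidden because
the surrogate's absolute percentages are parameterisation-dependent. The
context window bounds predictor input; it is configurable and recorded in
every distribution's `params_id`.

## Trimology donors and the usage metric

A trimology arm repeats the k genome bases adjacent to the cut n times
(defaults k = 3, n = 5; n = 0 is a pure NHEJ/HiTi donor). Because the
genome flank itself ends (or begins) with the unit, the junction contains a
degenerate run of at least n+1 copies; which physical copy is lost during
repair is unobservable, so all accounting is by resulting copy number.
**% repair via μH** is the summed frequency of outcomes whose product
removes a positive whole number of units from that run; removing exactly
one unit is the *perfect repair* sub-case (the seamless designed fusion).
Partial-unit deletions count as trimming, not usage. Junction predictions
represent the donor interior by a fixed cassette-proximal stub (default:
the first 12 nt of the eGFP CDS), configurable per call.

Release layouts: the PaqCI recognition site (CACCTGC, cutting 4/8 nt
downstream with a 4-nt 5′ overhang) is placed on each side in inverted
orientation outside the arms, separated from the donor by an 8-nt
sacrificial spacer that absorbs the overhang, so a simulated digest
releases a fragment whose double-stranded core is exactly the designed
donor. Overhang-PCR primers are the left arm + the first `binding_len` nt
of the cassette, and the reverse complement of the last `binding_len` nt +
right arm.

## ssODN scoring

A template of arm extents (L, R) is the genomic window [cut−L, cut+R) with
the requested substitutions applied. Each junction is scored by
concatenating the unedited genome flank with the template: this tandem-
duplicates the arm homology (broken at edit positions), and the collapse of
that duplication — keeping the edited copy — is exactly the seamless
intended product. The junction score is 100 × the predicted frequency of
that product; the combined score is the product of the two junction scores
as probabilities (percent convention, `left × right / 100`), stored at full
precision and displayed rounded to the nearest integer. This construction
is the only one consistent with scoring the two junctions independently
and combining them multiplicatively.

The score matrix evaluates all (L, R) in configurable ranges (default 1–24
each); cells whose arms do not cover every edit are invalid (NaN), not
zero. The optimal template is the argmax with deterministic tie-breaks:
higher score, then shorter L+R, then smaller |L−R|, then smaller L. The
editing-window scan runs this optimisation for every position in a window
(default −22..+17) and every alternative base. Under the surrogate the
best achievable score decreases with the edit's distance from the cut,
because covering a distal edit forces a longer collapse deletion whose
weight decays exponentially — the same qualitative behaviour reported for
trained predictors, at different absolute values.

Codon reversion brute-forces all codons of the target amino acid for the
minimal Hamming distance (ties broken lexicographically); mapping the
chosen codon onto genomic coordinates is the caller's responsibility, as
gene-model inference is out of scope.

## Guide ranking and screen selection

Three rules flag a candidate site for trimology integration: a G at −4; a
predicted +1-insertion fraction at the donor junction below 25%; and
microhomology usage at or above a pool percentile (default: median — no
published cutoff exists, so the rule is directional and the percentile is
exposed). Ranking sorts by rules satisfied, then the −4 hierarchy
G > C > A > T, then usage, with identifier-based residual tie-breaks so the
order is total and input-order independent.

Screen selection filters to an AGG core at −3..−1, drops excluded sources,
stratifies by S/W class at −6..−4, ranks each class by predicted
MMEJ-deletion mass at the unmodified locus, splits the ranking into
`per_class` equal-frequency bins (`bin = floor(rank·b/m)`) and picks the
median-ranked member of each bin; a full pool yields 8 × `per_class`
guides and under-filled classes are reported as explicit shortfalls.

## Read classification

A junction model is genome flank + arm + cassette stub (mirrored for
right-side junctions). Reads are aligned with affine scoring (match +1,
mismatch −2, gap open −4, extend −1), orientation resolved by the better
score of read vs reverse complement, and identity below 80% over the
aligned columns yields `unaligned`. End gaps are penalised like internal
gaps by default: amplicon reads span the whole model, and free end gaps
would let a long junction-spanning deletion score better as an unaligned
tail (``free_end_gaps=True`` restores semi-global behaviour for truncated
reads). Each deletion interval is re-canonicalised over its
product-equivalence range to the placement maximising overlap with the
unit run — inside a degenerate repeat the aligner's gap position is
arbitrary, and the spec-level invariant is that unit losses are counted by
copy number only. Whole units lost within the run are `units_lost`;
partial-unit remainders and bases outside the run count as genome or
cassette trimming. Categories follow the trim/unit logic (no trims and no
losses → scarless NHEJ; unit losses only → trimology repair; otherwise the
trimmed categories), substitutions never count as trimming, and frame
calls use the net indel length modulo 3 only (no translation).

## Synthetic data

`generate_fixture_locus` plants non-overlapping forward-strand NGG sites
with controlled −4 bases (largest-remainder apportionment of the requested
mix) in otherwise uniform random sequence; background PAMs may occur, so a
scanner must recover at least the planted truth set.
`simulate_junction_reads` draws reads from a known category mixture —
whole-unit losses from the run, 2–8-nt trims into genome and/or cassette,
optional unit co-loss — then applies per-base substitution errors (default
0.5%). These fixtures emulate junction amplicons with clean deletion
boundaries and substitution-only noise; they do not model sequencing
indels, chimeric reads, coverage bias or PCR artefacts, so passing
recovery tests demonstrates correctness of the accounting, not robustness
to every real-library failure mode. Cassette-trim simulation requires a
stub of ≥ 16 nt so the post-trim anchor cannot be traded for an end gap;
predictor junctions keep the shorter 12-nt default.

## Problem sizes and numerics

Test and acceptance runs use 2-kb loci, 24×24 score grids, 50-site trend
panels and 5,000-read mixtures — sizes chosen so the full suite exercises
every code path in well under half an hour on one core while keeping
binomial noise on recovered fractions (~0.7 points at n = 5,000) well
inside the ±2-point recovery tolerance. Determinism: all randomness flows
through seeded NumPy generators; distributions, matrices and argmaxes are
reproducible bit-for-bit for identical inputs.

## Known limitations

* The surrogate's absolute percentages are not calibrated against any
  trained predictor or experiment; only its orderings and trends are
  meaningful, and conclusions that depend on absolute outcome frequencies
  require an external predictor behind the adapter.
* Insertions other than the templated +1, complex indels, and
  substitution outcomes are outside the genotype space.
* Junction scoring assumes SSTR/MMEJ-style collapse of the constructed
  duplication; it does not model strand-specific ssODN chemistry or repair
  pathway choice.
* Read classification assumes junction-specific amplicons spanning the
  model; paired-end merging, UMIs and variant calling are out of scope.
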