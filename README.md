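# trimology

Design tools for predictable CRISPR/Cas9 knock-in and small edits, built on
the observation that DNA repair at the interface between a Cas9-induced
double-strand break (DSB) and exogenous donor DNA is non-random and can be
modelled from local sequence context.

The package is for genome engineers designing:

* **Knock-in donors with trimology arms** — tandem repeats (1–8×) of the
  k-nt unit (default k = 3) flanking the cut, so that microhomology-mediated
  end joining (MMEJ) collapses the synthetic repeat and fuses genome and
  cargo with a predictable, frame-retaining scar.
* **ssODN edit templates** — single-stranded templates of left/right arm
  extents (L, R) carrying one or more substitutions, scored by the joint
  probability of perfect repair at both template–genome junctions.
* **Guide panels** — gRNA ranking by the empirical rules that favour MMEJ
  integration, and a balanced screen selection across the eight strong/weak
  (S/W) sequence classes at positions −6..−4.
* **Amplicon analyses** — classification of junction-spanning reads into
  scarless-NHEJ, trimology-repair and trimmed outcome categories.

## Coordinate convention

All positions are PAM-anchored on the protospacer strand: the NGG PAM is
positions 0–2, the protospacer −20..−1, and the blunt cut falls between
positions −4 and −3 (3 nt 5′ of the PAM). The base at −4 — immediately left
of the cut — is a key covariate: G > C > A > T for MMEJ integration, the
inverse of its +1-insertion propensity.

## The scores

At a junction with flanks *left* | *right*, the outcome model enumerates
every deletion genotype spanning the cut (merged by product sequence, with
cross-cut microhomology μH annotated) plus the templated +1 insertion, and
assigns frequencies. The shipped surrogate weights a deletion of length *d*
with microhomology *m* as

    w = (m + GC(μH)) · exp(−d / τ)       (m ≥ 1)
    w = φ₀ · exp(−d / τ₀)                (m = 0)

with the +1 insertion carrying a fixed mass keyed to the −4 base. A trained
outcome predictor can be substituted through a JSON-lines adapter without
touching any downstream code.

* **% repair via μH** — summed frequency of outcomes that delete a whole
  number of trimology units from the tandem run spanning the junction;
  the one-unit collapse is *perfect repair*.
* **Pythia score** — for an ssODN with junction perfect-repair scores
  `s_left` and `s_right` (percent), the combined score is
  `s_left × s_right / 100`, displayed rounded to the nearest integer.
  Scanning (L, R) over a grid (default 1–24 each) yields the score matrix;
  the optimal template is its tie-broken argmax.

## Worked example

```python
from trimology import (SequenceRecord, find_cut_sites, SurrogatePredictor,
                       design_donor, mu_h_usage, paqman_layout,
                       pythia_score, display_score)

locus = SequenceRecord("tubb2a", "ATATATATATATAT" + "GGGCGAGTTCGAGGAGGAGG" + "AGG"
                       + "CGCGCGCGCGCGCGCGCGCGCGCGCGCGCG")
site = next(s for s in find_cut_sites(locus, "NGG")
            if s.protospacer == "GGGCGAGTTCGAGGAGGAGG")
donor = design_donor("ATGGTGAGCAAGGGCGAGGAGCTGTTCACC", site, unit_len=3, repeats=5)
print(donor.left_arm.seq)                       # AGGAGGAGGAGGAGG
print(paqman_layout(donor).digest.released_core == donor.full_seq)  # True

usage = mu_h_usage(SurrogatePredictor(), site, donor.left_arm)
print(round(usage.usage_pct, 1), round(usage.perfect_pct, 1))  # 27.5 3.3

print(display_score(pythia_score(94, 46)))      # 43
```

The first two lines show the 5× trimology arm (the 3 bases left of the cut,
repeated) and that a simulated PaqCI digest of the release plasmid layout
returns exactly the designed donor. The usage line is the percent of
predicted junction repair that mobilises at least one trimology unit (and
the perfect one-unit-collapse subset). The last line is the combined-score
arithmetic for junction scores of 94% and 46%.

A command-line surface mirrors the library:

```
trimology scan locus.fasta
trimology design-ssodn locus.fasta --edit "-6C>G"
trimology classify-reads locus.fasta reads.fastq
trimology simulate --what reads --seed 7
```

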