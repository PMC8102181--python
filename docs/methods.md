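# Methods

## Assay model

`mrdkit` models a two-arm MRD assay for AML in morphological remission:

* a **smMIPS panel arm**: targeted capture where each probe-binding event
  tags one DNA molecule with a random 8-bp UMI, sequenced to a median raw
  depth in the ~15,000× range, error-corrected to ~11,000× consensus
  molecules, and interrogated only at the patient's prespecified diagnostic
  mutations (typically 1–6 per patient);
* a **FLT3-ITD arm**: a one-step PCR single amplicon sequenced to ~10⁶×
  without UMIs, screened for internal tandem duplications at read level.

All coordinates are target-local and 1-based in pileups and VCF output;
panel design intervals follow the 0-based half-open BED convention. Reads
are assumed pre-merged (overlap assembly of a fully overlapping pair is an
upstream concern); genome alignment is replaced by target-local assignment
(exact 16-mer prefix match, edlib fallback), which is an adapter concern
for real data, not core logic.

## Consensus error correction

Families are exact (target, UMI) string matches — no UMI edit-distance
merging, which is conservative and exactly testable. Families of size 1 are
discarded: a singleton cannot distinguish polymerase/sequencer error from a
true molecule. Consensus takes the modal A/C/G/T call per position when its
within-family fraction reaches the **quorum (default 0.70)**, else `N`;
families with more than **20% N** are dropped. The defaults make a 2-read
disagreement an `N` and discard heavily damaged families; both are
configurable. A batched numpy implementation produces byte-identical
pileups to the per-family reference path (asserted in tests).

Consensus reads whose length differs from the target are placed as
reference plus one contiguous indel block by exact mismatch-minimising
placement (leftmost tie-break, ≤2 substitutions elsewhere), falling back
to full edlib alignment. Indel events are left-normalised, so pileup keys,
error-model keys and caller lookups agree on one canonical placement.

## Background error model

For every (target, position, alternate allele) key — substitutions, and
specific insertion sequences / deletion lengths — control samples are
pooled and the rate estimated with a Jeffreys-like pseudocount:

    rate = (Σ alt + 0.5) / (Σ depth + 1)

Never-observed indel alleles therefore get a finite pseudocount-only rate.
An observed count is scored with the one-sided upper binomial tail at that
rate. Pooling (rather than per-control variance) is the default because
consensus molecule counts are the natural unit and control panels are
small; a beta-binomial family with a pooled method-of-moments intra-class
correlation is available (`family="betabinomial"`) for panels with real
between-control dispersion, falling back to the binomial when the controls
carry too few events to estimate it. Sites with zero pooled control depth
are *unmodeled*; the caller refuses to call there (untestable), never
reporting a silent p-value. Multiple-testing correction is
Benjamini–Hochberg **within the sample's tracked set only** (≤6 tests):
MRD tracking tests a handful of prespecified sites, not the whole panel.

## Detection thresholds

Defaults, all configurable and recorded in output headers:

| parameter | default | rationale |
|---|---|---|
| `q_max` | 0.05 | BH-corrected within the tracked set |
| `min_families` | 2 (all classes) | two independent consensus molecules |
| `min_depth` | 1,000 molecules | below this the site is untestable |
| `min_vaf` | none | LoD is an output, not a caller input |

The two-molecule rule follows the convention of UMI/duplex MRD assays and
is backed by a power analysis at the assay's working point: at 11,363×
consensus depth a 0.05% clone contributes 5.7 expected molecules, so
requiring ≥3 molecules caps detection at ~92% and any VAF floor equal to
the detection limit itself caps it near 50% — both incompatible with a
0.05% limit of detection at a ≥90% detection rate. With ≥2 molecules and
the site-specific binomial test (which typically demands ≥2–4 molecules
anyway at realistic backgrounds), detection at 0.05% is ~98% while
error-only false positivity stays within the q-value budget (verified by
simulation in the test suite). Specificity is carried by the error model,
not by a count floor.

`untestable` is a first-class status distinct from `not-detected`: silent
negatives at low consensus depth are the principal failure mode of MRD
assays. Tissue (BM/PB) is carried as metadata only; no numerical
adjustment is applied between sources.

### DTA policy

Mutations in DNMT3A, TET2 and ASXL1 frequently persist in remission as
clonal hematopoiesis of an ancestral clone. At post-consolidation a sample
is never called MRD-positive on DTA mutations alone; at post-induction a
sole persistent DTA clone may drive positivity under the default
`pi-permissive` policy (set `strict` to disable).

## FLT3-ITD detection

Reads are uniqued by full-sequence hash so each distinct sequence is
analysed once; supporting counts include all duplicate reads (in a
one-step PCR assay most reads are duplicates by design, and the VAF is a
read fraction). Since amplicon reads are full length and substitution
errors preserve length, only reads at least `min_itd_len` (6) longer than
the reference can carry a detectable duplication. For such a read with
length excess L, every placement p of the hypothesis
`read = ref[:p+L] + ref[p:]` is scored by substitution count using two
cumulative-sum arrays (O(n) total); the minimum wins with a leftmost
tie-break, accepted when ≤2 mismatches overall and both junction-flanking
12-mers match with ≤1 mismatch. Events merge within ±2 bases at equal
length; `min_support` defaults to 5 reads, which keeps false events at
zero across 10⁶-read error simulations while leaving margin at the 2×10⁻⁵
working fraction (20 supporting reads per million). VAFs are reported with
Wilson 95% intervals. Tandem duplications are left-normalised: a block
duplicated at p is indistinguishable from one at p−1 when
`ref[p-1] == ref[p-1+L]`, and both the detector and the simulator's truth
report the leftmost equivalent placement.

Out of scope: ITD detection from genome-wide alignments, FLT3-TKD point
mutations (handled by the SNV path), and duplications longer than the
reference window.

## Synthetic data

The generator emulates the assay's statistical structure, not its
chemistry:

* **Family sizes**: shifted Poisson `1 + Pois(λ)` with mean 1.296, the
  assay's raw/consensus coverage ratio (14,728/11,363). The retained
  (size ≥2) fraction is then `1 − e^(−λ) ≈ 0.256`, and drivers that target
  a consensus depth set `n_families = depth / 0.256`.
* **Spike-ins are molecule-level**: each family is mutant with probability
  VAF, then all its reads inherit the haplotype — MRD VAF is a molecule
  fraction, not a read fraction. Mutant-family counts are exact binomial
  draws recorded in the truth table.
* **Errors**: independent per-read substitutions from a 12-class spectrum;
  default total ~0.1%/base with C>T and G>A at 4× the transversion rate
  (the oxidative-damage signature seen in controls). Injected errors are
  tallied per class for spectrum-recovery tests.
* **Quality**: constant Q30 strings; quality-aware calling is not modelled.
* **UMIs** are drawn without replacement per target, so grouping truth is
  exact. Real 8-bp UMI spaces collide at high molecule counts; collision
  merging, PCR chimeras, arm-sequence artifacts and capture bias are *not*
  emulated. Passing tests therefore demonstrate correctness of the
  error-correction and calling logic under the assay's sampling
  statistics — not robustness to every wet-lab artifact.
* **ITD reads**: full-amplicon copies with exactly `round(fraction·n)`
  duplication-bearing reads and optional uniform substitution noise.

All randomness flows from one integer seed; replicate seeds are spawned
via `numpy.random.SeedSequence` and recorded in LoD tables for replay.

## Limit-of-detection experiment

For each (VAF, replicate) cell the driver runs an independent seeded
simulation at the requested consensus depth through the full consensus and
calling path, with one error model fitted from 3 spike-free controls per
experiment (as a laboratory would). LoD is the lowest grid VAF with
detection rate ≥0.90 (threshold configurable and reported). Default
problem sizes — 80-bp target, 11,363 consensus molecules (~44,350 families,
~57,000 reads per replicate), 4-point grid × 50 replicates — complete in
about two minutes on one core; they were chosen as the smallest faithful
rendering of the assay's working point.

## Numerical choices and degenerate inputs

* Binomial tails via `scipy.stats.binom.sf`; p-values clamped to (0, 1].
* Consensus ties at quorum ≤0.5 break to the alphabetically first base
  (documented, deterministic); any majority quorum turns a 2-read tie
  into `N`.
* Zero denominators in concordance/predictive metrics yield `None`
  ("undefined"), never 0; empty call lists classify as untestable.
* Reported percentages round half-up to one decimal.
* Families with members of unequal trimmed length are rejected (counted),
  not padded.

## Known limitations

* Target-local mapping assumes targets are prefix-distinguishable;
  genome-scale mapping, CEBPA-like GC-poor capture performance and
  allelic skew are outside the model.
* The binomial error model understates tail mass if controls are
  overdispersed and the beta-binomial option is not enabled.
* The ITD detector requires full-length amplicon reads; fragmented or
  trimmed reads reduce sensitivity and are not modelled.
* Survival analysis, competing-risk regression and patient-level
  predictive values for relapse are downstream analyses for standard
  statistical software and are deliberately not implemented.
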