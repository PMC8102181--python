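# mrdkit

Error-corrected NGS **measurable residual disease (MRD)** calling for acute
myeloid leukemia, built around single-molecule molecular inversion probe
(smMIPS) sequencing, plus an ultrasensitive read-level **FLT3-ITD** detector.

After induction or consolidation chemotherapy, most AML patients are in
morphological remission; relapse risk is driven by leukemic clones persisting
far below the microscope's ~5% sensitivity. `mrdkit` implements the
computational half of a panel-based MRD assay that tracks each patient's
*diagnostic* mutations at follow-up:

1. **UMI consensus error correction** — every captured DNA molecule carries
   an 8-bp unique molecular identifier (UMI). Reads sharing a (target, UMI)
   key form a single-molecule family; singleton families are discarded;
   surviving families are collapsed to a consensus sequence (modal base if
   its within-family fraction reaches a quorum, else `N`). Pileups count
   consensus *molecules*, so VAF is a molecule fraction.
2. **Site- and mutation-specific error model** — background rates are fitted
   per (site, alternate allele) from control samples as
   `(pooled alt + ½) / (pooled depth + 1)`; an observed alternate count `k`
   at consensus depth `d` is scored with the one-sided binomial tail
   `P(X ≥ k), X ~ Bin(d, rate)` (optional beta-binomial for overdispersed
   panels). The control spectrum shows the expected C>T / G>A excess of
   oxidative DNA damage.
3. **Tracked-mutation MRD calling** — a mutation is *detected* when its
   Benjamini–Hochberg q-value (within the patient's ≤6-mutation tracked set)
   clears `q_max = 0.05` and it is supported by ≥2 independent consensus
   molecules. A sample is MRD-positive on any detected non-DTA mutation;
   persistent **DNMT3A/TET2/ASXL1 (DTA)** clones — likely clonal
   hematopoiesis — never drive positivity at post-consolidation, and drive
   post-induction positivity only under the permissive policy. Sites with
   insufficient depth are *untestable*, never silently negative.
4. **FLT3-ITD detection** — internal tandem duplications are found in
   ultra-deep single-amplicon reads (no UMIs, ~10⁶× depth) by
   mismatch-minimising self-alignment with k-mer anchor verification,
   sensitive down to a 2×10⁻⁵ read fraction.
5. **Metrics** — concordance between NGS-MRD and flow-cytometry MRD
   (capture rates, agreement), predictive values with
   `accuracy = sens·prev + spec·(1−prev)`, and a limit-of-detection
   experiment driver.

A seeded synthetic-data module emulates the assay end to end (shifted-Poisson
family sizes with mean ≈ 1.30, matching the assay's 14,728×/11,363×
raw/consensus coverage ratio; molecule-level spike-ins; C>T/G>A-enriched
error spectrum), so every claim is testable against known ground truth.

## Worked example

Quantify a 0.05% NPM1-target SNV spike at the assay's working depth:

```python
import numpy as np
from mrdkit import (SimConfig, SpikeIn, TrackedMutation, simulate_sample,
                    consensus_pileup, call_tracked_mutations, classify_sample)
from mrdkit.consensus import Read
from mrdkit.errormodel import fit_error_model
from mrdkit.sequtil import random_sequence

refs = {"NPM1_t": random_sequence(80, np.random.default_rng(0))}
ref = refs["NPM1_t"]

controls = []
for seed in (1, 2, 3):                      # spike-free control samples
    s = simulate_sample(SimConfig(refs, n_families_per_target=44_350, seed=seed))
    ps, _ = consensus_pileup((Read.from_tuple(r) for r in s.reads), refs)
    controls.append(ps)
model = fit_error_model(controls)

spike = SpikeIn("NPM1_t", 41, ref[40], "A", vaf=0.0005)   # 0.05%
s = simulate_sample(SimConfig(refs, n_families_per_target=44_350,
                              spike_ins=[spike], seed=9))
pileups, stats = consensus_pileup((Read.from_tuple(r) for r in s.reads), refs)

mut = TrackedMutation("P01", "NPM1", "NPM1_t", 41, ref[40], "A", "snv", 0.42)
(call,) = call_tracked_mutations(pileups, [mut], model)
print(stats.n_reads, stats.n_consensus_reads)
print(call.alt_families, call.consensus_depth, round(call.vaf, 6),
      f"{call.p_value:.3g}", call.status)
print(classify_sample([call], "P01", "PI").status)
```

prints

```
57436 11309
4 11309 0.000354 2.75e-05 detected
MRD-positive
```

57,436 raw reads collapse to 11,309 consensus molecules (singleton UMI
families discarded); the spike is supported by 4 independent molecules —
a measured VAF of 0.035% against a fitted background of ~1.5×10⁻⁵ — giving
p = 2.7×10⁻⁵, a detected call, and an MRD-positive sample.

The same pipeline is scriptable from the shell:

```bash
mrdkit simulate --config sim.yaml --out-prefix run/s
mrdkit consensus --fastq run/s.R1.fastq --references refs.fasta --out run/pileup.tsv
mrdkit fit-errors --pileup ctl1.tsv --pileup ctl2.tsv --out model.json
mrdkit call-mrd --pileup run/pileup.tsv --tracked tracked.vcf --model model.json \
    --references refs.fasta --time-point PI --out-prefix run/P01
mrdkit concordance --counts table1_pi.tsv
```

`mrdkit concordance` on the post-induction 2×2 table (68/70/17/40) prints the
two capture rates, 80.0 and 49.3 (% of FCM⁺ caught by NGS, and of NGS⁺ caught
by FCM).

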