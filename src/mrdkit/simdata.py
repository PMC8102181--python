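"""Synthetic smMIPS-like read simulator with known ground truth.

Two generators are provided:

* :func:`simulate_sample` — UMI-tagged panel reads. Each original molecule
  (a "family") gets a unique 8-bp UMI and a haplotype (reference, or carrying
  one or more spiked-in mutations assigned per molecule at the configured
  VAF). The molecule is then read ``size`` times, where ``size`` follows a
  shifted Poisson whose mean defaults to the assay's raw/consensus coverage
  ratio (14,728/11,363 ≈ 1.30). Per-read substitution errors follow a
  configurable 12-class spectrum whose default is enriched for C>T and G>A,
  the signature of oxidative DNA damage seen in control samples.
* :func:`simulate_itd_reads` — ultra-deep single-amplicon reads for the
  FLT3-ITD path, with an exact (rounded) count of reads carrying a tandem
  duplication at a configured fraction.

All randomness is governed by a single integer seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .sequtil import decode, decode_rows, encode, revcomp, write_fastq

logger = logging.getLogger(__name__)

SUBSTITUTION_CLASSES = tuple(
    f"{a}>{b}" for a in "ACGT" for b in "ACGT" if a != b
)

#: Default per-base, per-class substitution error probabilities. C>T and G>A
#: are 4x the transversion rate; overall ~0.1% per base, a realistic
#: post-filter short-read error rate.
DEFAULT_ERROR_RATES: dict[str, float] = {
    cls: (8e-4 if cls in ("C>T", "G>A") else 2e-4) for cls in SUBSTITUTION_CLASSES
}

#: Mean reads per molecule implied by the assay's median raw (14,728x) over
#: consensus (11,363x) coverage.
DEFAULT_FAMILY_SIZE_MEAN = 14728 / 11363


@dataclass(frozen=True)
class SpikeIn:
    """A mutation injected at the molecule level.

    ``ref``/``alt`` follow VCF conventions on the target-local reference:
    equal length 1 for SNVs, ``len(alt) > len(ref) == 1`` for insertions
    (``alt[0] == ref``), ``len(ref) > len(alt) == 1`` for deletions.
    ``pos`` is 1-based.
    """

    target: str
    pos: int
    ref: str
    alt: str
    vaf: float

    @property
    def label(self) -> str:
        return f"{self.target}:{self.pos}{self.ref}>{self.alt}"

    @property
    def var_class(self) -> str:
        if len(self.ref) == len(self.alt) == 1:
            return "snv"
        if len(self.alt) > len(self.ref):
            return "ins"
        return "del"


@dataclass
class SimConfig:
    """Configuration of one simulated smMIPS sample."""

    reference_sequences: dict[str, str]
    n_families_per_target: int
    family_size_mean: float = DEFAULT_FAMILY_SIZE_MEAN
    umi_length: int = 8
    error_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ERROR_RATES)
    )
    spike_ins: list[SpikeIn] = field(default_factory=list)
    itd_spec: Optional[tuple[str, int, int, float]] = None  # (target, pos, length, fraction)
    seed: int = 0
    quality_char: str = "?"  # Q30

    def __post_init__(self) -> None:
        if not self.reference_sequences:
            raise ValueError("at least one target reference is required")
        if self.umi_length < 4:
            raise ValueError("umi_length must be >= 4")
        if self.family_size_mean < 1:
            raise ValueError("family_size_mean must be >= 1 (sizes are >= 1)")
        if self.n_families_per_target < 1:
            raise ValueError("n_families_per_target must be >= 1")
        if self.n_families_per_target > 4**self.umi_length:
            raise ValueError(
                "n_families_per_target exceeds the UMI space 4^umi_length; "
                "increase umi_length"
            )
        for cls, rate in self.error_rates.items():
            if cls not in SUBSTITUTION_CLASSES:
                raise ValueError(f"unknown substitution class {cls!r}")
            if not 0 <= rate < 1:
                raise ValueError(f"error rate for {cls} must be in [0,1)")
        for spike in self.spike_ins:
            self._validate_spike(spike)
        if self.itd_spec is not None:
            target, pos, length, fraction = self.itd_spec
            ref = self._target_ref(target)
            if not 1 <= pos <= len(ref) - length + 1:
                raise ValueError(
                    f"ITD block ({pos}, len {length}) outside target {target!r}"
                )
            if not 0 < fraction < 1:
                raise ValueError("ITD fraction must be in (0,1)")

    def _target_ref(self, target: str) -> str:
        try:
            return self.reference_sequences[target]
        except KeyError:
            raise ValueError(f"unknown target {target!r}") from None

    def _validate_spike(self, spike: SpikeIn) -> None:
        ref_seq = self._target_ref(spike.target)
        if not 0 < spike.vaf < 1:
            raise ValueError(f"spike-in VAF must be in (0,1): {spike.label}")
        end = spike.pos - 1 + len(spike.ref)
        if spike.pos < 1 or end > len(ref_seq):
            raise ValueError(
                f"spike-in at {spike.target}:{spike.pos} outside target "
                f"(length {len(ref_seq)})"
            )
        if ref_seq[spike.pos - 1 : end] != spike.ref:
            raise ValueError(
                f"spike-in ref mismatch at {spike.target}:{spike.pos}: "
                f"expected {ref_seq[spike.pos - 1:end]!r}, got {spike.ref!r}"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        spikes = [SpikeIn(**s) for s in raw.pop("spike_ins", [])]
        itd = raw.pop("itd_spec", None)
        return cls(spike_ins=spikes, itd_spec=tuple(itd) if itd else None, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            "reference_sequences": dict(self.reference_sequences),
            "n_families_per_target": self.n_families_per_target,
            "family_size_mean": self.family_size_mean,
            "umi_length": self.umi_length,
            "error_rates": dict(self.error_rates),
            "spike_ins": [vars(s) for s in self.spike_ins],
            "itd_spec": list(self.itd_spec) if self.itd_spec else None,
            "seed": self.seed,
        }
        with open(path, "w") as handle:
            yaml.safe_dump(raw, handle, sort_keys=False)


@dataclass
class SimulatedSample:
    """Reads plus the per-molecule truth table of one simulated sample."""

    config: SimConfig
    reads: list[tuple[str, str, str]]  # (name, sequence=UMI+payload, quality)
    truth: pd.DataFrame  # target, family_id, umi, haplotype, size, n_errors
    injected_error_counts: dict[str, int]

    def mutant_family_count(self, spike: SpikeIn) -> int:
        """Number of molecules carrying ``spike`` (from the truth table)."""
        return int(self.truth["haplotype"].str.contains(spike.label, regex=False).sum())

    def write_fastq_pair(self, r1_path: str | Path, r2_path: str | Path) -> int:
        """Emit an R1/R2 pair: R1 = UMI + payload, R2 = reverse complement
        of the payload (a fully overlapping pair, pre-merge)."""
        umi_len = self.config.umi_length
        q = self.config.quality_char
        n = write_fastq(((name, seq, q * len(seq)) for name, seq, q_ in self.reads), r1_path)
        write_fastq(
            (
                (name, revcomp(seq[umi_len:]), q * (len(seq) - umi_len))
                for name, seq, _ in self.reads
            ),
            r2_path,
        )
        return n

    def write_truth(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            handle.write(f"# seed={self.config.seed}\n")
            self.truth.to_csv(handle, sep="\t", index=False)


def _umi_strings(rng: np.random.Generator, n: int, length: int) -> list[str]:
    # Distinct UMIs per target: grouping truth is then exact. Barcode
    # collisions of a real 8-bp UMI space are not emulated.
    space = 4**length
    codes = rng.choice(space, size=n, replace=False)
    digits = (codes[:, None] // (4 ** np.arange(length))[None, :]) % 4
    return decode_rows(digits.astype(np.uint8))


def _apply_spikes(ref: str, spikes: Sequence[SpikeIn]) -> str:
    seq = ref
    for spike in sorted(spikes, key=lambda s: -s.pos):
        i = spike.pos - 1
        seq = seq[:i] + spike.alt + seq[i + len(spike.ref) :]
    return seq


def _inject_errors(
    matrix: np.ndarray,
    error_rates: dict[str, float],
    rng: np.random.Generator,
) -> tuple[np.ndarray, dict[str, int]]:
    """Mutate a (reads x positions) code matrix in place per the class rates.

    Returns per-read injected error counts and per-class tallies.
    """
    per_read = np.zeros(matrix.shape[0], dtype=np.int64)
    class_counts: dict[str, int] = {}
    if not error_rates or matrix.size == 0:
        return per_read, class_counts

    total_rate = np.zeros(4)
    alt_codes = np.zeros((4, 3), dtype=np.uint8)
    cum_probs = np.zeros((4, 3))
    for b, base in enumerate("ACGT"):
        alts = [a for a in range(4) if a != b]
        rates = [error_rates.get(f"{base}>{'ACGT'[a]}", 0.0) for a in alts]
        total_rate[b] = sum(rates)
        alt_codes[b] = alts
        if total_rate[b] > 0:
            cum_probs[b] = np.cumsum(rates) / total_rate[b]
        else:
            cum_probs[b] = [1 / 3, 2 / 3, 1.0]

    err = rng.random(matrix.shape) < total_rate[matrix]
    rows, cols = np.nonzero(err)
    if rows.size == 0:
        return per_read, class_counts
    orig = matrix[rows, cols]
    pick = (rng.random(rows.size)[:, None] >= cum_probs[orig]).sum(axis=1)
    new = alt_codes[orig, pick]
    matrix[rows, cols] = new
    per_read = np.bincount(rows, minlength=matrix.shape[0])
    for b in range(4):
        for a in range(4):
            if a == b:
                continue
            cnt = int(np.sum((orig == b) & (new == a)))
            if cnt:
                class_counts[f"{'ACGT'[b]}>{'ACGT'[a]}"] = cnt
    return per_read, class_counts


def simulate_sample(config: SimConfig) -> SimulatedSample:
    """Generate UMI-tagged reads and the molecule-level truth table."""
    rng = np.random.default_rng(config.seed)
    spikes = list(config.spike_ins)
    if config.itd_spec is not None:
        target, pos, length, fraction = config.itd_spec
        ref = config.reference_sequences[target]
        block = ref[pos - 1 : pos - 1 + length]
        # A tandem duplication is an insertion of the block after its last base.
        anchor = pos - 1 + length  # 1-based position of the base before the insertion
        spikes.append(
            SpikeIn(target, anchor, ref[anchor - 1], ref[anchor - 1] + block, fraction)
        )

    reads: list[tuple[str, str, str]] = []
    truth_rows: list[dict] = []
    error_totals: dict[str, int] = {}
    family_id = 0

    for target, ref in config.reference_sequences.items():
        n_fam = config.n_families_per_target
        sizes = 1 + rng.poisson(config.family_size_mean - 1.0, size=n_fam)
        umis = _umi_strings(rng, n_fam, config.umi_length)

        target_spikes = [s for s in spikes if s.target == target]
        spike_mask = np.zeros((n_fam, len(target_spikes)), dtype=bool)
        for j, spike in enumerate(target_spikes):
            if spike.vaf * n_fam < 1:
                logger.warning(
                    "expected mutant families < 1 for %s (vaf=%g, n=%d)",
                    spike.label, spike.vaf, n_fam,
                )
            spike_mask[:, j] = rng.random(n_fam) < spike.vaf

        combo_keys = [tuple(np.nonzero(row)[0]) for row in spike_mask]
        combos: dict[tuple[int, ...], np.ndarray] = {}
        for i, key in enumerate(combo_keys):
            combos.setdefault(key, []).append(i)

        fam_names = np.empty(n_fam, dtype=object)
        fam_errors = np.zeros(n_fam, dtype=np.int64)
        fam_reads: dict[int, list[str]] = {}

        for key, fam_idx in combos.items():
            fam_idx = np.asarray(fam_idx)
            hap_spikes = [target_spikes[j] for j in key]
            hap = _apply_spikes(ref, hap_spikes)
            hap_codes = encode(hap)
            group_sizes = sizes[fam_idx]
            n_reads = int(group_sizes.sum())
            matrix = np.tile(hap_codes, (n_reads, 1))
            per_read, class_counts = _inject_errors(matrix, config.error_rates, rng)
            for cls, cnt in class_counts.items():
                error_totals[cls] = error_totals.get(cls, 0) + cnt
            payloads = decode_rows(matrix)
            starts = np.concatenate(([0], np.cumsum(group_sizes)[:-1]))
            per_fam_err = np.add.reduceat(per_read, starts)
            label = ";".join(s.label for s in hap_spikes) or "ref"
            for j, fi in enumerate(fam_idx):
                lo = starts[j]
                fam_reads[int(fi)] = payloads[lo : lo + group_sizes[j]]
                fam_errors[fi] = per_fam_err[j]
                fam_names[fi] = label

        for i in range(n_fam):
            fid = family_id + i
            umi = umis[i]
            for j, payload in enumerate(fam_reads.get(i, [])):
                seq = umi + payload
                reads.append(
                    (f"sim:{target}:{fid}:{j}", seq, config.quality_char * len(seq))
                )
            truth_rows.append(
                {
                    "target": target,
                    "family_id": fid,
                    "umi": umi,
                    "haplotype": fam_names[i],
                    "size": int(sizes[i]),
                    "n_errors": int(fam_errors[i]),
                }
            )
        family_id += n_fam

    truth = pd.DataFrame(truth_rows)
    assert len(reads) == int(truth["size"].sum()), "read/family-size conservation"
    return SimulatedSample(config, reads, truth, error_totals)


@dataclass
class ItdSimResult:
    """Ultra-deep amplicon reads with an exact number of ITD-bearing reads."""

    reads: list[str]
    n_itd: int
    itd_position: int  # 1-based start of the duplicated block on the reference
    itd_length: int
    duplicated_sequence: str
    itd_indices: np.ndarray
    seed: int
    reference: str = ""

    @property
    def canonical_position(self) -> int:
        """1-based leftmost equivalent placement of the duplicated block.

        A tandem duplication starting at p is indistinguishable from one
        starting at p-1 whenever ref[p-1] == ref[p-1+L]; detectors
        normalise to the leftmost placement, so truth comparisons should
        use this coordinate."""
        p = self.itd_position - 1
        L = self.itd_length
        while p > 0 and self.reference[p - 1] == self.reference[p - 1 + L]:
            p -= 1
        return p + 1

    @property
    def canonical_sequence(self) -> str:
        p = self.canonical_position - 1
        return self.reference[p : p + self.itd_length]

    def write_fastq(self, path: str | Path, quality_char: str = "?") -> int:
        return write_fastq(
            (
                (f"amplicon:{i}", seq, quality_char * len(seq))
                for i, seq in enumerate(self.reads)
            ),
            path,
        )


def simulate_itd_reads(
    reference_window: str,
    n_reads: int,
    itd: tuple[int, int],
    fraction: float,
    seed: int,
    error_rate: float = 0.0,
    anchor: int = 12,
) -> ItdSimResult:
    """Simulate single-amplicon reads, a fixed fraction carrying a tandem
    duplication of the reference block at ``itd = (pos_1based, length)``.

    Exactly ``round(fraction * n_reads)`` reads carry the duplication; the
    rest are reference (plus independent substitution errors when
    ``error_rate`` > 0).
    """
    pos, length = itd
    ref = reference_window
    if length < 3:
        raise ValueError("ITD length must be >= 3")
    if length > len(ref) - 2 * anchor:
        raise ValueError(
            f"ITD length {length} too long for reference of {len(ref)} bp "
            f"with {anchor} bp anchors"
        )
    if not 1 <= pos <= len(ref) - length + 1:
        raise ValueError(f"ITD block at {pos} (len {length}) outside the reference")
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0,1)")

    rng = np.random.default_rng(seed)
    block = ref[pos - 1 : pos - 1 + length]
    itd_read = ref[: pos - 1 + length] + ref[pos - 1 :]
    n_itd = int(round(fraction * n_reads))
    itd_idx = np.sort(rng.choice(n_reads, size=n_itd, replace=False)) if n_itd else np.array([], dtype=int)

    reads: list[str] = [ref] * n_reads
    for i in itd_idx:
        reads[i] = itd_read

    if error_rate > 0:
        lengths = np.full(n_reads, len(ref))
        lengths[itd_idx] = len(itd_read)
        n_err = rng.binomial(lengths, error_rate)
        for i in np.nonzero(n_err)[0]:
            seq = list(reads[i])
            cols = rng.choice(len(seq), size=n_err[i], replace=False)
            for c in cols:
                choices = [b for b in "ACGT" if b != seq[c]]
                seq[c] = choices[rng.integers(3)]
            reads[i] = "".join(seq)

    return ItdSimResult(
        reads=reads,
        n_itd=n_itd,
        itd_position=pos,
        itd_length=length,
        duplicated_sequence=block,
        itd_indices=itd_idx,
        seed=seed,
        reference=ref,
    )
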