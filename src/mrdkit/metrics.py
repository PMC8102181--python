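"""Dual-modality concordance, predictive values, and the limit-of-detection
experiment driver.

Concordance compares the molecular (NGS) and flow-cytometric (FCM) MRD
calls on the same patients as capture rates — what fraction of one
modality's positives the other recovers — plus overall agreement.
Predictive metrics follow the standard screening definitions with

    accuracy = sensitivity * prevalence + specificity * (1 - prevalence)

which is checked internally against the raw-count identity
(tp + tn) / total.

The LoD driver runs the full simulate → consensus → call pipeline over a
grid of spike-in VAFs with independent seeds and derives the limit of
detection as the lowest VAF whose empirical detection rate reaches the
rate threshold (0.90 by default).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .caller import CallThresholds, TrackedMutation, call_tracked_mutations
from .consensus import ConsensusParams, Read, consensus_pileup
from .errormodel import ErrorModel
from .sequtil import random_sequence
from .simdata import (
    DEFAULT_ERROR_RATES,
    DEFAULT_FAMILY_SIZE_MEAN,
    SimConfig,
    SpikeIn,
    simulate_sample,
)


def percent(x: float, ndigits: int = 1) -> float:
    """Percentage with round-half-up at ``ndigits`` decimals (printed style:
    80.0, 49.3, 70.9)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x * 100)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# concordance


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cross-classification of NGS-MRD vs FCM-MRD calls."""

    ngs_pos_fcm_pos: int
    ngs_pos_fcm_neg: int
    ngs_neg_fcm_pos: int
    ngs_neg_fcm_neg: int
    label: str = ""

    def __post_init__(self) -> None:
        counts = (self.ngs_pos_fcm_pos, self.ngs_pos_fcm_neg,
                  self.ngs_neg_fcm_pos, self.ngs_neg_fcm_neg)
        if any(c < 0 for c in counts):
            raise ValueError("contingency counts must be non-negative")
        if sum(counts) == 0:
            raise ValueError("contingency table is empty")

    @property
    def total(self) -> int:
        return (self.ngs_pos_fcm_pos + self.ngs_pos_fcm_neg
                + self.ngs_neg_fcm_pos + self.ngs_neg_fcm_neg)

    @classmethod
    def from_labels(cls, ngs: Sequence[bool], fcm: Sequence[bool], label: str = ""):
        if len(ngs) != len(fcm):
            raise ValueError("label vectors differ in length")
        a = sum(1 for n, f in zip(ngs, fcm) if n and f)
        b = sum(1 for n, f in zip(ngs, fcm) if n and not f)
        c = sum(1 for n, f in zip(ngs, fcm) if not n and f)
        d = sum(1 for n, f in zip(ngs, fcm) if not n and not f)
        return cls(a, b, c, d, label)

    @classmethod
    def from_tsv(cls, path) -> "ContingencyTable":
        """4-field TSV: ngs+fcm+, ngs+fcm-, ngs-fcm+, ngs-fcm- (one data row)."""
        df = pd.read_csv(path, sep="\t")
        row = df.iloc[0]
        return cls(int(row.iloc[0]), int(row.iloc[1]),
                   int(row.iloc[2]), int(row.iloc[3]))


@dataclass
class ConcordanceResult:
    ngs_capture_of_fcm_pos: Optional[float]  # fraction of FCM+ also NGS+
    fcm_capture_of_ngs_pos: Optional[float]  # fraction of NGS+ also FCM+
    agreement: float

    def as_percent(self) -> dict[str, Optional[float]]:
        return {
            k: (percent(v) if v is not None else None)
            for k, v in (
                ("ngs_capture_of_fcm_pos", self.ngs_capture_of_fcm_pos),
                ("fcm_capture_of_ngs_pos", self.fcm_capture_of_ngs_pos),
                ("agreement", self.agreement),
            )
        }


def concordance(table: ContingencyTable) -> ConcordanceResult:
    """Capture rates between the two MRD modalities; undefined rates (zero
    denominator) are reported as None, never as 0."""
    a, b = table.ngs_pos_fcm_pos, table.ngs_pos_fcm_neg
    c, d = table.ngs_neg_fcm_pos, table.ngs_neg_fcm_neg
    fcm_pos = a + c
    ngs_pos = a + b
    return ConcordanceResult(
        ngs_capture_of_fcm_pos=(a / fcm_pos) if fcm_pos else None,
        fcm_capture_of_ngs_pos=(a / ngs_pos) if ngs_pos else None,
        agreement=(a + d) / table.total,
    )


# ---------------------------------------------------------------------------
# predictive metrics


@dataclass
class PredictiveMetrics:
    sensitivity: Optional[float]
    specificity: Optional[float]
    prevalence: float
    ppv: Optional[float]
    npv: Optional[float]
    accuracy: Optional[float]


def predictive_metrics(tp: int, fp: int, fn: int, tn: int) -> PredictiveMetrics:
    """Screening metrics from a confusion table; accuracy by the
    prevalence-weighted formula, cross-checked against raw counts."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be non-negative")
    total = tp + fp + fn + tn
    if total == 0:
        raise ValueError("empty confusion table")
    prevalence = (tp + fn) / total
    sens = tp / (tp + fn) if tp + fn else None
    spec = tn / (tn + fp) if tn + fp else None
    ppv = tp / (tp + fp) if tp + fp else None
    npv = tn / (tn + fn) if tn + fn else None
    accuracy = None
    if sens is not None and spec is not None:
        accuracy = sens * prevalence + spec * (1 - prevalence)
        direct = (tp + tn) / total
        assert math.isclose(accuracy, direct, rel_tol=1e-12, abs_tol=1e-12), (
            "prevalence-weighted accuracy must equal the raw-count accuracy"
        )
    return PredictiveMetrics(sens, spec, prevalence, ppv, npv, accuracy)


# ---------------------------------------------------------------------------
# limit-of-detection experiment


@dataclass
class LodExperimentResult:
    table: pd.DataFrame  # var_class, vaf, consensus_depth, reps, detected, rate, seeds
    lod: dict[str, Optional[float]]  # per variant class, in VAF fraction
    rate_threshold: float
    seed: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def _spike_for_class(ref: str, pos: int, var_class: str) -> tuple[str, str]:
    refbase = ref[pos - 1]
    if var_class == "snv":
        alt = next(b for b in "ACGT" if b != refbase)
        return refbase, alt
    if var_class == "ins":
        # NPM1-type 4-bp insertion after the anchor base
        return refbase, refbase + "CTAG"
    if var_class == "del":
        return ref[pos - 1 : pos + 2], refbase
    raise ValueError(f"unsupported variant class for the LoD driver: {var_class}")


def retained_family_fraction(family_size_mean: float) -> float:
    """Fraction of molecules surviving the singleton filter under the
    shifted-Poisson family-size model."""
    lam = family_size_mean - 1.0
    return 1.0 - math.exp(-lam)


def lod_experiment(
    vaf_grid: Sequence[float],
    consensus_depth: int = 11363,
    reps: int = 50,
    seed: int = 0,
    var_class: str = "snv",
    rate_threshold: float = 0.90,
    thresholds: Optional[CallThresholds] = None,
    error_rates: Optional[dict[str, float]] = None,
    family_size_mean: float = DEFAULT_FAMILY_SIZE_MEAN,
    n_controls: int = 3,
    target_length: int = 80,
    spike_pos: int = 41,
    consensus_params: ConsensusParams = ConsensusParams(),
) -> LodExperimentResult:
    """Empirical limit of detection of the simulate → consensus → call
    pipeline for one tracked mutation.

    One background error model is fitted from ``n_controls`` spike-free
    control samples, then each (VAF, replicate) cell runs an independent
    seeded simulation at the requested consensus depth and asks the caller
    whether the tracked mutation is detected. LoD per class is the lowest
    VAF on the grid with detection rate >= ``rate_threshold``.
    """
    if not vaf_grid:
        raise ValueError("vaf_grid must be non-empty")
    if reps < 10:
        raise ValueError("at least 10 replicates are required")
    thresholds = thresholds or CallThresholds()
    error_rates = dict(DEFAULT_ERROR_RATES) if error_rates is None else error_rates

    root = np.random.SeedSequence(seed)
    n_points = len(vaf_grid)
    children = root.spawn(n_points * reps + n_controls + 1)
    ref = random_sequence(target_length, np.random.default_rng(children[-1]))
    refs = {"TGT1": ref}
    spike_ref, spike_alt = _spike_for_class(ref, spike_pos, var_class)
    n_families = int(round(consensus_depth / retained_family_fraction(family_size_mean)))

    def _seed_of(ss: np.random.SeedSequence) -> int:
        return int(ss.generate_state(1)[0] % 2**31)

    def _run(sim_seed: int, vaf: Optional[float]):
        spikes = []
        if vaf is not None:
            spikes = [SpikeIn("TGT1", spike_pos, spike_ref, spike_alt, vaf)]
        cfg = SimConfig(
            reference_sequences=refs,
            n_families_per_target=n_families,
            family_size_mean=family_size_mean,
            error_rates=error_rates,
            spike_ins=spikes,
            seed=sim_seed,
        )
        sample = simulate_sample(cfg)
        pileups, _ = consensus_pileup(
            (Read.from_tuple(r) for r in sample.reads), refs, params=consensus_params
        )
        return pileups

    control_pileups = [
        _run(_seed_of(children[n_points * reps + i]), None) for i in range(n_controls)
    ]
    model = ErrorModel().fit(control_pileups)

    tracked = TrackedMutation(
        patient_id="LOD", gene="SPIKE", target="TGT1", pos=spike_pos,
        ref=spike_ref, alt=spike_alt, var_class=var_class, diagnostic_vaf=0.5,
    )

    rows = []
    for gi, vaf in enumerate(vaf_grid):
        seeds = [_seed_of(children[gi * reps + r]) for r in range(reps)]
        detected = 0
        for s in seeds:
            pileups = _run(s, vaf)
            calls = call_tracked_mutations(pileups, [tracked], model, thresholds)
            if calls[0].status == "detected":
                detected += 1
        rows.append(
            {
                "var_class": var_class,
                "vaf": vaf,
                "consensus_depth": consensus_depth,
                "reps": reps,
                "detected": detected,
                "rate": detected / reps,
                "seeds": json.dumps(seeds),
            }
        )
    table = pd.DataFrame(rows)
    qualifying = table[table["rate"] >= rate_threshold]["vaf"]
    lod = {var_class: (float(qualifying.min()) if len(qualifying) else None)}
    return LodExperimentResult(table, lod, rate_threshold, seed)
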