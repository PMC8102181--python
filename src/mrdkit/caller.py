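"""Tracked-mutation MRD calling and sample classification.

MRD is assessed by quantifying the patient's *diagnostic* mutations in a
follow-up sample: for each tracked mutation the consensus pileup yields
the supporting molecule count and consensus depth, the background error
model yields a one-sided p-value, and Benjamini–Hochberg correction is
applied within the (small, prespecified) tracked set of the sample. A
mutation is *detected* when its q-value clears ``q_max`` and it is
supported by at least ``min_families`` independent consensus molecules.
Sites with insufficient consensus depth, or absent from the panel or the
error model, are *untestable* — a first-class status, never silently
negative.

Sample classification applies the DTA policy: persistence of mutations
in the clonal-hematopoiesis-prone genes DNMT3A/TET2/ASXL1 never drives
positivity at the end of consolidation; at the end of induction a sole
persistent DTA clone may drive positivity under the permissive policy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import pysam
from statsmodels.stats.multitest import multipletests

from .consensus import PileupSet, _left_align_deletion, _left_align_insertion
from .errormodel import ErrorModel, UnmodeledSiteError

DTA_GENES = frozenset({"DNMT3A", "TET2", "ASXL1"})

VARIANT_CLASSES = ("snv", "ins", "del", "itd")


@dataclass(frozen=True)
class TrackedMutation:
    """A diagnostic mutation monitored at MRD time points.

    ``pos`` is 1-based on the target-local reference; ``ref``/``alt`` follow
    VCF conventions (anchor-base style for indels).
    """

    patient_id: str
    gene: str
    target: str
    pos: int
    ref: str
    alt: str
    var_class: str
    diagnostic_vaf: float = 0.5

    def __post_init__(self) -> None:
        if self.var_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant class {self.var_class!r}")
        if not 0 < self.diagnostic_vaf <= 1:
            raise ValueError("diagnostic VAF must be in (0, 1]")

    @property
    def is_dta(self) -> bool:
        return self.gene in DTA_GENES

    @property
    def key(self) -> tuple:
        return (self.gene, self.target, self.pos, self.ref, self.alt)

    @property
    def label(self) -> str:
        return f"{self.gene}:{self.target}:{self.pos}:{self.ref}>{self.alt}"

    @classmethod
    def infer_class(cls, ref: str, alt: str) -> str:
        if len(ref) == len(alt) == 1:
            return "snv"
        if len(alt) > len(ref):
            return "ins"
        return "del"


@dataclass
class CallThresholds:
    """Detection criteria.

    ``min_families`` is the minimum number of independent consensus
    molecules supporting the variant (two molecules for every class — see
    the methods note for the power analysis behind this choice);
    ``min_vaf`` is an optional per-class reporting floor, disabled by
    default because the assay's limit of detection is an *output* of the
    LoD experiment, not an input to the caller.
    """

    q_max: float = 0.05
    min_families: dict[str, int] = field(
        default_factory=lambda: {"snv": 2, "ins": 2, "del": 2, "itd": 2}
    )
    min_depth: int = 1000
    min_vaf: dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "q_max": self.q_max,
            "min_families": dict(self.min_families),
            "min_depth": self.min_depth,
            "min_vaf": dict(self.min_vaf),
        }


@dataclass
class MrdVariantCall:
    mutation: TrackedMutation
    alt_families: int
    consensus_depth: int
    vaf: float
    p_value: Optional[float]
    q_value: Optional[float]
    status: str  # detected / not-detected / untestable
    reason: Optional[str] = None


@dataclass
class SampleMrdResult:
    patient_id: str
    time_point: str  # "PI" or "PC"
    tissue: str  # "BM" or "PB" (metadata only; no numerical adjustment)
    calls: list[MrdVariantCall]
    status: str  # MRD-positive / MRD-negative / untestable
    basis: list[str]  # labels of the mutations driving positivity

    def to_json(self, path: str | Path, thresholds: Optional[CallThresholds] = None) -> None:
        payload = {
            "patient_id": self.patient_id,
            "time_point": self.time_point,
            "tissue": self.tissue,
            "status": self.status,
            "basis": self.basis,
            "calls": [
                {
                    "mutation": c.mutation.label,
                    "gene": c.mutation.gene,
                    "is_dta": c.mutation.is_dta,
                    "alt_families": c.alt_families,
                    "consensus_depth": c.consensus_depth,
                    "vaf": c.vaf,
                    "p_value": c.p_value,
                    "q_value": c.q_value,
                    "status": c.status,
                    "reason": c.reason,
                }
                for c in self.calls
            ],
        }
        if thresholds is not None:
            payload["thresholds"] = thresholds.as_dict()
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=1)


def _lookup_counts(
    pileups: PileupSet, mut: TrackedMutation
) -> tuple[int, int, str | tuple, int]:
    """(alt molecule count, consensus depth, error-model alt key,
    error-model position) for a tracked mutation.

    Indels are left-normalised so the pileup event keys, the fitted model
    keys and the caller's lookup all agree on one canonical placement.
    """
    tp = pileups[mut.target]
    if mut.var_class == "snv":
        alt_key: str | tuple = mut.alt
        count = tp.base_count(mut.pos, mut.alt)
        model_pos = mut.pos
    elif mut.var_class in ("ins", "itd"):
        inserted = mut.alt[len(mut.ref) :]
        anchor0, norm_seq = _left_align_insertion(tp.ref, mut.pos, inserted)
        alt_key = ("ins", norm_seq)
        count = tp.ins_count(mut.pos, inserted)
        model_pos = anchor0
    else:  # deletion: VCF anchor base at pos, deleted bases follow
        length = len(mut.ref) - len(mut.alt)
        start0 = _left_align_deletion(tp.ref, mut.pos, length)
        alt_key = ("del", length)
        count = tp.del_count(mut.pos + 1, length)
        model_pos = start0 + 1
    depth = tp.site_depth(mut.pos)
    return count, depth, alt_key, model_pos


def call_tracked_mutations(
    pileups: PileupSet,
    tracked: Sequence[TrackedMutation],
    model: ErrorModel,
    thresholds: CallThresholds = CallThresholds(),
) -> list[MrdVariantCall]:
    """Quantify each tracked mutation and assign detected / not-detected /
    untestable status (BH-corrected within this tracked set)."""
    calls: list[MrdVariantCall] = []
    for mut in tracked:
        if mut.target not in pileups:
            calls.append(
                MrdVariantCall(mut, 0, 0, 0.0, None, None, "untestable",
                               reason="target absent from panel design")
            )
            continue
        count, depth, alt_key, model_pos = _lookup_counts(pileups, mut)
        if depth < thresholds.min_depth:
            calls.append(
                MrdVariantCall(mut, count, depth, 0.0, None, None, "untestable",
                               reason=f"consensus depth {depth} < {thresholds.min_depth}")
            )
            continue
        try:
            p = model.site_pvalue(mut.target, model_pos, alt_key, count, depth)
        except UnmodeledSiteError:
            calls.append(
                MrdVariantCall(mut, count, depth, 0.0, None, None, "untestable",
                               reason="site unmodeled in error model")
            )
            continue
        vaf = count / depth
        calls.append(MrdVariantCall(mut, count, depth, vaf, p, None, "pending"))

    testable = [c for c in calls if c.status == "pending"]
    if testable:
        _, qvals, _, _ = multipletests(
            [c.p_value for c in testable], method="fdr_bh"
        )
        for call, q in zip(testable, qvals):
            call.q_value = float(q)
            min_fam = thresholds.min_families.get(call.mutation.var_class, 2)
            floor = thresholds.min_vaf.get(call.mutation.var_class, 0.0)
            detected = (
                q < thresholds.q_max
                and call.alt_families >= min_fam
                and call.vaf >= floor
            )
            call.status = "detected" if detected else "not-detected"
    return calls


def classify_sample(
    calls: Sequence[MrdVariantCall],
    patient_id: str,
    time_point: str,
    tissue: str = "BM",
    dta_policy: str = "pi-permissive",
) -> SampleMrdResult:
    """Classify one sample from its tracked-mutation calls.

    Positivity requires a detected non-DTA mutation, except at the
    post-induction (PI) time point where a sole persistent DTA clone may
    drive positivity under ``dta_policy="pi-permissive"``. At post
    consolidation (PC), DTA-only positivity is always negative. A sample
    with no testable call is *untestable*, not negative.
    """
    if time_point not in ("PI", "PC"):
        raise ValueError("time_point must be 'PI' or 'PC'")
    if dta_policy not in ("pi-permissive", "strict"):
        raise ValueError("dta_policy must be 'pi-permissive' or 'strict'")
    calls = list(calls)
    testable = [c for c in calls if c.status in ("detected", "not-detected")]
    if not testable:
        return SampleMrdResult(patient_id, time_point, tissue, calls, "untestable", [])
    detected = [c for c in testable if c.status == "detected"]
    non_dta = [c for c in detected if not c.mutation.is_dta]
    basis = [c.mutation.label for c in non_dta]
    positive = bool(non_dta)
    if not positive and detected and time_point == "PI" and dta_policy == "pi-permissive":
        positive = True
        basis = [c.mutation.label for c in detected]
    status = "MRD-positive" if positive else "MRD-negative"
    return SampleMrdResult(patient_id, time_point, tissue, calls, status, basis)


@dataclass
class KineticsResult:
    patient_id: str
    category: str  # neg/neg, pos->neg, neg->pos, pos/pos, unevaluable
    gained: list[str]
    lost: list[str]


def mrd_kinetics(pi: SampleMrdResult, pc: SampleMrdResult) -> KineticsResult:
    """Between-time-point MRD kinetics: sample-level category plus the
    per-mutation gain/loss lists."""
    if pi.patient_id != pc.patient_id:
        raise ValueError(
            f"patient ids differ: {pi.patient_id!r} vs {pc.patient_id!r}"
        )
    det_pi = {c.mutation.label for c in pi.calls if c.status == "detected"}
    det_pc = {c.mutation.label for c in pc.calls if c.status == "detected"}
    gained = sorted(det_pc - det_pi)
    lost = sorted(det_pi - det_pc)
    if "untestable" in (pi.status, pc.status):
        category = "unevaluable"
    else:
        a = "pos" if pi.status == "MRD-positive" else "neg"
        b = "pos" if pc.status == "MRD-positive" else "neg"
        category = {"negneg": "neg/neg", "posneg": "pos->neg",
                    "negpos": "neg->pos", "pospos": "pos/pos"}[a + b]
    return KineticsResult(pi.patient_id, category, gained, lost)


# ---------------------------------------------------------------------------
# VCF / TSV I/O


def read_tracked_vcf(path: str | Path) -> list[TrackedMutation]:
    """Read tracked mutations from a VCF.

    Expected INFO keys: GENE, PATIENT, optional VCLASS (inferred from
    ref/alt lengths when absent; ITD records must set VCLASS=itd) and
    optional DVAF (diagnostic VAF).
    """
    muts = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = dict(rec.info)
            alt = rec.alts[0]
            var_class = info.get("VCLASS") or TrackedMutation.infer_class(rec.ref, alt)
            muts.append(
                TrackedMutation(
                    patient_id=str(info.get("PATIENT", "unknown")),
                    gene=str(info["GENE"]),
                    target=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=alt,
                    var_class=str(var_class),
                    diagnostic_vaf=float(info.get("DVAF", 0.5)),
                )
            )
    return muts


def write_calls_vcf(
    calls: Sequence[MrdVariantCall],
    references: dict[str, str],
    path: str | Path,
) -> None:
    """Write MRD calls as a VCF with assay-specific INFO keys."""
    header = pysam.VariantHeader()
    for target, ref in references.items():
        header.contigs.add(target, length=len(ref))
    header.info.add("GENE", 1, "String", "Gene symbol of the tracked mutation")
    header.info.add("ALTFAM", 1, "Integer", "Supporting consensus families")
    header.info.add("CONSDEPTH", 1, "Integer", "Consensus depth at the site")
    header.info.add("VAF", 1, "Float", "Variant allele fraction (molecule fraction)")
    header.info.add("P", 1, "Float", "One-sided background-model p-value")
    header.info.add("Q", 1, "Float", "BH q-value within the tracked set")
    header.info.add("STATUS", 1, "String", "detected / not-detected / untestable")
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in calls:
            mut = call.mutation
            rec = out.new_record(
                contig=mut.target,
                start=mut.pos - 1,
                alleles=(mut.ref, mut.alt),
            )
            rec.info["GENE"] = mut.gene
            rec.info["ALTFAM"] = call.alt_families
            rec.info["CONSDEPTH"] = call.consensus_depth
            rec.info["VAF"] = call.vaf
            if call.p_value is not None:
                rec.info["P"] = call.p_value
            if call.q_value is not None:
                rec.info["Q"] = call.q_value
            rec.info["STATUS"] = call.status
            out.write(rec)


def calls_to_frame(calls: Sequence[MrdVariantCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "patient_id": c.mutation.patient_id,
            "gene": c.mutation.gene,
            "target": c.mutation.target,
            "pos": c.mutation.pos,
            "ref": c.mutation.ref,
            "alt": c.mutation.alt,
            "var_class": c.mutation.var_class,
            "is_dta": c.mutation.is_dta,
            "alt_families": c.alt_families,
            "consensus_depth": c.consensus_depth,
            "vaf": c.vaf,
            "p_value": c.p_value,
            "q_value": c.q_value,
            "status": c.status,
        }
        for c in calls
    )
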