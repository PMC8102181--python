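"""UMI extraction, single-molecule family grouping, quorum consensus and
per-site consensus pileups.

The pipeline mirrors single-molecule molecular inversion probe (smMIPS)
error correction: each capture event tags one DNA molecule with a random
UMI; reads sharing (target, UMI) form a family; singleton families are
discarded; surviving families are collapsed to a consensus sequence
(modal base if its within-family fraction reaches the quorum, else N);
consensus reads are piled up per target position. The pileup — counts of
consensus *molecules* per allele — is the unit the error model and the
MRD caller consume, and its per-site depth is the assay's "consensus
coverage".

Reads are expected pre-merged (paired-end assembly is an upstream step);
mapping is target-local, by matching the read payload to the panel's
target references.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import edlib
import numpy as np
import pandas as pd

from .sequtil import BASES, N, decode, encode

# ---------------------------------------------------------------------------
# records


@dataclass
class Read:
    """A (merged) read moving through the pipeline."""

    name: str
    sequence: str
    quality: Optional[str] = None
    mate_sequence: Optional[str] = None
    umi: Optional[str] = None
    target: Optional[str] = None

    @classmethod
    def from_tuple(cls, rec: tuple) -> "Read":
        return cls(*rec[:3])


@dataclass(frozen=True)
class UmiConvention:
    """Where the UMI sits: first ``length`` bases of read 1 by default."""

    length: int = 8
    offset: int = 0


@dataclass
class UmiFamily:
    target: str
    umi: str
    members: list[Read]

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def family_key(self) -> tuple[str, str]:
        return (self.target, self.umi)


@dataclass
class ConsensusRead:
    target: str
    sequence: str
    family_size: int
    n_fraction: float
    umi: Optional[str] = None


class UmiExtractionError(ValueError):
    pass


class UnequalReadLengthsError(ValueError):
    """Members of a family differ in trimmed length; positional consensus
    is refused (no padding) and the family is rejected upstream."""


# ---------------------------------------------------------------------------
# operations


def extract_umi(read: Read | tuple, convention: UmiConvention = UmiConvention()) -> Read:
    """Split the UMI off the read and record it in the read name.

    The UMI is taken from ``[offset, offset+length)`` of read 1; an ``N``
    inside the UMI is kept as a distinct symbol (such families simply never
    merge with their ACGT neighbours).
    """
    if not isinstance(read, Read):
        read = Read.from_tuple(read)
    lo, hi = convention.offset, convention.offset + convention.length
    if len(read.sequence) <= hi:
        raise UmiExtractionError(
            f"read {read.name!r} shorter than UMI span ({hi} bases)"
        )
    umi = read.sequence[lo:hi]
    trimmed = read.sequence[:lo] + read.sequence[hi:]
    quality = None
    if read.quality is not None:
        quality = read.quality[:lo] + read.quality[hi:]
    return replace(
        read,
        name=f"{read.name}:UMI:{umi}",
        sequence=trimmed,
        quality=quality,
        umi=umi,
    )


@dataclass
class GroupingStats:
    n_reads: int = 0
    n_unassigned: int = 0
    n_singleton_reads: int = 0
    n_keys: int = 0
    n_families: int = 0


def group_families(
    reads: Iterable[Read], min_size: int = 2
) -> tuple[list[UmiFamily], GroupingStats]:
    """Group reads by exact (target, UMI) match and drop families below
    ``min_size`` (singletons, by default)."""
    stats = GroupingStats()
    buckets: dict[tuple[str, str], list[Read]] = defaultdict(list)
    for read in reads:
        stats.n_reads += 1
        if read.target is None or read.umi is None:
            stats.n_unassigned += 1
            continue
        buckets[(read.target, read.umi)].append(read)
    stats.n_keys = len(buckets)
    families = []
    for (target, umi), members in buckets.items():
        if len(members) >= min_size:
            families.append(UmiFamily(target, umi, members))
        else:
            stats.n_singleton_reads += len(members)
    stats.n_families = len(families)
    return families, stats


def consensus_family(
    family: UmiFamily, quorum: float = 0.70, max_n_fraction: float = 0.20
) -> Optional[ConsensusRead]:
    """Collapse a family to its consensus sequence.

    At each position the consensus base is the modal A/C/G/T call if its
    fraction of the family size reaches ``quorum``, else N (ties at
    quorum <= 0.5 break toward the alphabetically first base). Returns
    ``None`` when the N fraction exceeds ``max_n_fraction``.
    """
    lengths = {len(r.sequence) for r in family.members}
    if len(lengths) != 1:
        raise UnequalReadLengthsError(
            f"family {family.family_key} has trimmed lengths {sorted(lengths)}"
        )
    matrix = np.vstack([encode(r.sequence) for r in family.members])
    counts = np.stack([(matrix == b).sum(axis=0) for b in range(4)])
    modal = counts.argmax(axis=0)
    frac = counts.max(axis=0) / family.size
    consensus = np.where(frac >= quorum, modal, N).astype(np.uint8)
    n_fraction = float((consensus == N).mean())
    if n_fraction > max_n_fraction:
        return None
    return ConsensusRead(
        target=family.target,
        sequence=decode(consensus),
        family_size=family.size,
        n_fraction=n_fraction,
        umi=family.umi,
    )


# ---------------------------------------------------------------------------
# target assignment (target-local mapping; no genome alignment)


def assign_target(
    sequence: str,
    references: dict[str, str],
    prefix_index: Optional[dict[str, str]] = None,
    k: int = 16,
    max_dist_frac: float = 0.15,
) -> Optional[str]:
    """Assign a trimmed read to a panel target.

    Exact match of the first ``k`` payload bases wins; otherwise the read is
    aligned (edlib, global) against each target and the best hit is taken if
    its edit distance is at most ``max_dist_frac`` of the read length.
    """
    if prefix_index is None:
        prefix_index = build_prefix_index(references, k)
    hit = prefix_index.get(sequence[:k])
    if hit is not None:
        return hit
    best, best_dist = None, None
    limit = int(max_dist_frac * len(sequence))
    for target, ref in references.items():
        dist = edlib.align(sequence, ref, mode="NW", k=limit)["editDistance"]
        if dist != -1 and (best_dist is None or dist < best_dist):
            best, best_dist = target, dist
    return best


def build_prefix_index(references: dict[str, str], k: int = 16) -> dict[str, str]:
    index: dict[str, str] = {}
    for target, ref in references.items():
        key = ref[:k]
        if key in index:
            raise ValueError(f"targets {index[key]!r} and {target!r} share a {k}-mer prefix")
        index[key] = target
    return index


# ---------------------------------------------------------------------------
# pileups


def _left_align_insertion(ref: str, anchor0: int, seq: str) -> tuple[int, str]:
    """Shift an insertion of ``seq`` before 0-based ref index ``anchor0``
    to its leftmost equivalent placement."""
    while anchor0 > 0 and seq[-1] == ref[anchor0 - 1]:
        seq = ref[anchor0 - 1] + seq[:-1]
        anchor0 -= 1
    return anchor0, seq


def _left_align_deletion(ref: str, start0: int, length: int) -> int:
    while start0 > 0 and ref[start0 + length - 1] == ref[start0 - 1]:
        start0 -= 1
    return start0


@dataclass
class TargetPileup:
    """Per-site consensus-molecule counts over one target (1-based sites)."""

    target: str
    ref: str
    counts: np.ndarray = None  # (5, L): A C G T N
    dels: np.ndarray = None  # (L,): deleted-molecule count per site
    ins_events: dict[tuple[int, str], int] = field(default_factory=dict)
    del_events: dict[tuple[int, int], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        L = len(self.ref)
        if self.counts is None:
            self.counts = np.zeros((5, L), dtype=np.int64)
        if self.dels is None:
            self.dels = np.zeros(L, dtype=np.int64)

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=0) + self.dels

    def add_consensus(self, sequence: str) -> None:
        if len(sequence) == len(self.ref):
            codes = encode(sequence)
            for b in range(5):
                self.counts[b] += codes == b
            return
        self._add_aligned(sequence)

    def add_consensus_matrix(self, matrix: np.ndarray) -> None:
        """Vectorised add of equal-length consensus reads (rows = reads)."""
        if matrix.shape[1] != len(self.ref):
            raise ValueError("matrix width must equal the target length")
        for b in range(5):
            self.counts[b] += (matrix == b).sum(axis=0)

    def _add_aligned(self, sequence: str, max_block_mismatch: int = 2) -> None:
        # Consensus reads come from one molecule, so a length difference is
        # almost always one contiguous insertion or deletion. Try the exact
        # single-block placement first (mismatch-minimising, leftmost); it
        # avoids alignment-path ambiguity where an aligner may split an
        # insert whose bases partly match the reference.
        if self._add_single_block(sequence, max_block_mismatch):
            return
        aln = edlib.align(sequence, self.ref, mode="NW", task="path")
        qpos = rpos = 0
        for n_ops, op in _parse_cigar(aln["cigar"]):
            if op in "=XM":
                codes = encode(sequence[qpos : qpos + n_ops])
                for b in range(5):
                    self.counts[b, rpos : rpos + n_ops] += codes == b
                qpos += n_ops
                rpos += n_ops
            elif op == "I":
                anchor0, seq = _left_align_insertion(
                    self.ref, rpos, sequence[qpos : qpos + n_ops]
                )
                key = (anchor0, seq)  # anchor0 = 1-based position of preceding base
                self.ins_events[key] = self.ins_events.get(key, 0) + 1
                qpos += n_ops
            elif op == "D":
                start0 = _left_align_deletion(self.ref, rpos, n_ops)
                key = (start0 + 1, n_ops)
                self.del_events[key] = self.del_events.get(key, 0) + 1
                self.dels[rpos : rpos + n_ops] += 1
                rpos += n_ops
            else:  # pragma: no cover
                raise ValueError(f"unexpected cigar op {op!r}")

    def _add_single_block(self, sequence: str, max_mismatch: int) -> bool:
        """Place the read as reference plus one contiguous indel block.

        Returns True (and records the counts) when a placement with at most
        ``max_mismatch`` substitutions exists; ties break leftmost.
        """
        ref_codes = encode(self.ref)
        read_codes = encode(sequence)
        n, m = ref_codes.size, read_codes.size
        L = m - n
        if L == 0:
            return False
        if L > 0:  # insertion of L read bases before ref index p
            prefix = np.concatenate(([0], np.cumsum(read_codes[:n] != ref_codes)))
            tail_mm = np.concatenate(([0], np.cumsum(read_codes[L:] != ref_codes)))
            span = n + 1
            total = prefix[:span] + (tail_mm[n] - tail_mm[:span])
        else:  # deletion of -L reference bases starting at ref index p
            D = -L
            prefix = np.concatenate(([0], np.cumsum(read_codes != ref_codes[:m])))
            tail_mm = np.concatenate(([0], np.cumsum(read_codes != ref_codes[D:])))
            span = m + 1
            total = prefix[:span] + (tail_mm[m] - tail_mm[:span])
        p = int(np.argmin(total))
        if int(total[p]) > max_mismatch:
            return False
        if L > 0:
            anchor0, seq = _left_align_insertion(self.ref, p, sequence[p : p + L])
            self.ins_events[(anchor0, seq)] = self.ins_events.get((anchor0, seq), 0) + 1
            body = np.concatenate((read_codes[:p], read_codes[p + L :]))
        else:
            D = -L
            start0 = _left_align_deletion(self.ref, p, D)
            key = (start0 + 1, D)
            self.del_events[key] = self.del_events.get(key, 0) + 1
            self.dels[p : p + D] += 1
            body = read_codes
        # positional base counts on the covered reference positions
        if L > 0:
            for b in range(5):
                self.counts[b] += body == b
        else:
            D = -L
            for b in range(5):
                self.counts[b, :p] += body[:p] == b
                self.counts[b, p + D :] += body[p:] == b
        return True

    # -- accessors (1-based positions) --

    def base_count(self, pos: int, base: str) -> int:
        return int(self.counts[BASES.index(base), pos - 1])

    def ins_count(self, pos: int, inserted: str) -> int:
        anchor0, seq = _left_align_insertion(self.ref, pos, inserted)
        return self.ins_events.get((anchor0, seq), 0)

    def del_count(self, pos: int, length: int) -> int:
        start0 = _left_align_deletion(self.ref, pos - 1, length)
        return self.del_events.get((start0 + 1, length), 0)

    def site_depth(self, pos: int) -> int:
        return int(self.depth[pos - 1])


def _parse_cigar(cigar: str) -> Iterable[tuple[int, str]]:
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


class PileupSet:
    """Consensus pileups for all panel targets of one sample."""

    def __init__(self, references: dict[str, str]):
        self.targets: dict[str, TargetPileup] = {
            t: TargetPileup(t, ref) for t, ref in references.items()
        }

    def __getitem__(self, target: str) -> TargetPileup:
        return self.targets[target]

    def __contains__(self, target: str) -> bool:
        return target in self.targets

    def __iter__(self):
        return iter(self.targets.values())

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for tp in self.targets.values():
            depth = tp.depth
            for i, refbase in enumerate(tp.ref):
                pos = i + 1
                ins = {
                    seq: cnt
                    for (p, seq), cnt in sorted(tp.ins_events.items())
                    if p == pos
                }
                dels_ev = {
                    str(ln): cnt
                    for (p, ln), cnt in sorted(tp.del_events.items())
                    if p == pos
                }
                rows.append(
                    {
                        "target": tp.target,
                        "pos": pos,
                        "ref": refbase,
                        "A": tp.counts[0, i],
                        "C": tp.counts[1, i],
                        "G": tp.counts[2, i],
                        "T": tp.counts[3, i],
                        "N": tp.counts[4, i],
                        "del": tp.dels[i],
                        "ins_json": json.dumps(ins) if ins else "{}",
                        "del_json": json.dumps(dels_ev) if dels_ev else "{}",
                        "depth": int(depth[i]),
                    }
                )
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PileupSet":
        df = pd.read_csv(path, sep="\t", dtype={"ins_json": str, "del_json": str})
        refs = {
            t: "".join(sub.sort_values("pos")["ref"]) for t, sub in df.groupby("target")
        }
        ps = cls(refs)
        for _, row in df.iterrows():
            tp = ps[row["target"]]
            i = int(row["pos"]) - 1
            for b, base in enumerate("ACGTN"):
                tp.counts[b, i] = row[base]
            tp.dels[i] = row["del"]
            for seq, cnt in json.loads(row["ins_json"]).items():
                tp.ins_events[(int(row["pos"]), seq)] = int(cnt)
            for ln, cnt in json.loads(row["del_json"]).items():
                tp.del_events[(int(row["pos"]), int(ln))] = int(cnt)
        return ps


# ---------------------------------------------------------------------------
# panel design (BED-like, 0-based half-open)


@dataclass(frozen=True)
class DesignInterval:
    target: str
    start: int  # 0-based
    end: int  # half-open
    name: str


def load_design(path: str | Path) -> list[DesignInterval]:
    rows = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            rows.append(
                DesignInterval(fields[0], int(fields[1]), int(fields[2]), fields[3])
            )
    return rows


def design_from_references(references: dict[str, str]) -> list[DesignInterval]:
    return [
        DesignInterval(t, 0, len(ref), t) for t, ref in references.items()
    ]


def write_design(design: Sequence[DesignInterval], path: str | Path) -> None:
    with open(path, "w") as handle:
        for iv in design:
            handle.write(f"{iv.target}\t{iv.start}\t{iv.end}\t{iv.name}\n")


def build_pileup(
    consensus_reads: Iterable[ConsensusRead],
    references: dict[str, str],
    design: Optional[Sequence[DesignInterval]] = None,
) -> tuple[PileupSet, int]:
    """Pile consensus reads onto the design targets.

    Returns the pileup set and the count of consensus reads excluded
    because their target is outside the design.
    """
    if design is None:
        design = design_from_references(references)
    allowed = {iv.target for iv in design}
    pileups = PileupSet({t: references[t] for t in allowed if t in references})
    excluded = 0
    for cr in consensus_reads:
        if cr.target not in pileups:
            excluded += 1
            continue
        pileups[cr.target].add_consensus(cr.sequence)
    return pileups, excluded


# ---------------------------------------------------------------------------
# vectorised end-to-end driver


@dataclass
class ConsensusParams:
    umi: UmiConvention = UmiConvention()
    quorum: float = 0.70
    max_n_fraction: float = 0.20
    min_family_size: int = 2
    assign_k: int = 16
    max_dist_frac: float = 0.15


@dataclass
class PipelineStats:
    n_reads: int = 0
    n_umi_rejected: int = 0
    n_unassigned: int = 0
    n_singleton_reads: int = 0
    n_families: int = 0
    n_unequal_length: int = 0
    n_dropped_n_fraction: int = 0
    n_consensus_reads: int = 0
    n_outside_design: int = 0


def consensus_pileup(
    reads: Iterable[Read | tuple],
    references: dict[str, str],
    design: Optional[Sequence[DesignInterval]] = None,
    params: ConsensusParams = ConsensusParams(),
) -> tuple[PileupSet, PipelineStats]:
    """Run extract → assign → group → consensus → pileup, vectorised.

    Produces pileups identical to composing :func:`extract_umi`,
    :func:`group_families`, :func:`consensus_family` and
    :func:`build_pileup` read by read (asserted in the test suite), but
    collapses equal-shape families in batched numpy operations.
    """
    if design is None:
        design = design_from_references(references)
    stats = PipelineStats()
    prefix_index = build_prefix_index(references, params.assign_k)
    span = params.umi.offset + params.umi.length

    buckets: dict[tuple[str, str], list[str]] = defaultdict(list)
    for read in reads:
        seq = read.sequence if isinstance(read, Read) else read[1]
        stats.n_reads += 1
        if len(seq) <= span:
            stats.n_umi_rejected += 1
            continue
        umi = seq[params.umi.offset : span]
        payload = seq[: params.umi.offset] + seq[span:]
        target = assign_target(
            payload, references, prefix_index, params.assign_k, params.max_dist_frac
        )
        if target is None:
            stats.n_unassigned += 1
            continue
        buckets[(target, umi)].append(payload)

    # batch families by (target, size, length); odd shapes fall back per family
    groups: dict[tuple[str, int, int], list[list[str]]] = defaultdict(list)
    for (target, umi), members in buckets.items():
        if len(members) < params.min_family_size:
            stats.n_singleton_reads += len(members)
            continue
        stats.n_families += 1
        lengths = {len(m) for m in members}
        if len(lengths) != 1:
            stats.n_unequal_length += 1
            continue
        groups[(target, len(members), lengths.pop())].append(members)

    allowed = {iv.target for iv in design}
    pileups = PileupSet({t: references[t] for t in allowed if t in references})

    for (target, size, length), fams in groups.items():
        flat = "".join("".join(members) for members in fams)
        matrix = encode(flat).reshape(len(fams), size, length)
        counts = np.stack([(matrix == b).sum(axis=1) for b in range(4)])
        modal = counts.argmax(axis=0)
        frac = counts.max(axis=0) / size
        cons = np.where(frac >= params.quorum, modal, N).astype(np.uint8)
        n_frac = (cons == N).mean(axis=1)
        keep = n_frac <= params.max_n_fraction
        stats.n_dropped_n_fraction += int((~keep).sum())
        cons = cons[keep]
        stats.n_consensus_reads += cons.shape[0]
        if target not in pileups:
            stats.n_outside_design += cons.shape[0]
            stats.n_consensus_reads -= cons.shape[0]
            continue
        tp = pileups[target]
        if length == len(tp.ref):
            tp.add_consensus_matrix(cons)
        else:
            for row in cons:
                tp.add_consensus(decode(row))
    return pileups, stats
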