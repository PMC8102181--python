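"""Ultrasensitive FLT3 internal tandem duplication detection from
ultra-deep single-amplicon reads.

The one-step PCR FLT3 assay sequences one amplicon at ~10^6-fold depth
with no UMIs, so detection is read-level and must work from a handful of
supporting reads in a million. Reads are full-length amplicon copies;
an ITD inserts an exact duplication of a reference block, so ITD-bearing
reads are longer than the reference by the duplication length. The
detector:

1. Uniques read sequences (hash with multiplicity) so each distinct
   sequence is analysed once; support counts all reads.
2. Screens candidates: reads at least ``min_itd_len`` longer than the
   reference (substitution errors cannot create an insertion).
3. Places the duplication by exact mismatch-minimising self-alignment:
   for insertion length L, the candidate placement p asserts
   ``read == ref[:p+L] + ref[p:]``; cumulative prefix/suffix mismatch
   arrays give the mismatch count of every p in O(n), the minimum wins,
   ties break leftmost.
4. Verifies both junctions with flanking k-mer anchors (<= 1 mismatch
   each) and requires the total mismatch count <= ``max_mismatches``.
5. Merges events within ``pos_tol`` bases at equal length, then filters
   by ``min_support`` reads.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .sequtil import encode


@dataclass
class ItdParams:
    k: int = 12  # anchor k-mer length
    min_itd_len: int = 6
    min_support: int = 5
    pos_tol: int = 2  # event-merge tolerance on position
    max_mismatches: int = 2  # across the whole read at the best placement
    max_anchor_mismatches: int = 1  # per junction anchor


@dataclass
class ItdEvent:
    """A detected internal tandem duplication on the amplicon reference."""

    position: int  # 1-based start of the duplicated block
    length: int
    sequence: str  # the duplicated reference block
    support: int
    total_reads: int
    mismatches: int = 0  # at the representative placement

    def __post_init__(self) -> None:
        if self.support > self.total_reads:
            raise ValueError("supporting reads cannot exceed total reads")
        if self.support <= 0:
            raise ValueError("an event requires at least one supporting read")

    @property
    def vaf(self) -> float:
        return self.support / self.total_reads

    def confidence_interval(self, alpha: float = 0.05) -> tuple[float, float]:
        lo, hi = proportion_confint(self.support, self.total_reads,
                                    alpha=alpha, method="wilson")
        return float(lo), float(hi)


def itd_vaf(event: ItdEvent, total_reads: int) -> tuple[float, tuple[float, float]]:
    """Supporting-read fraction with its Wilson 95% interval."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if total_reads < event.support:
        raise ValueError("total_reads cannot be below the supporting count")
    lo, hi = proportion_confint(event.support, total_reads, method="wilson")
    return event.support / total_reads, (float(lo), float(hi))


def _best_placement(
    read_codes: np.ndarray, ref_codes: np.ndarray, L: int
) -> tuple[int, int]:
    """Mismatch-minimising tandem-duplication placement.

    For each p in [0, n-L], the ITD hypothesis is
    ``read == ref[:p+L] + ref[p:]``; mismatches(p) decomposes into a prefix
    term (read[:p+L] vs ref[:p+L]) and a suffix term (read[p+L:] vs ref[p:]),
    both available from cumulative sums. Returns (p, mismatches), leftmost
    minimum.
    """
    n = ref_codes.size
    prefix_mm = np.concatenate(([0], np.cumsum(read_codes[:n] != ref_codes)))
    # suffix_mm[p] = mismatches of read[p+L:] vs ref[p:]
    tail_eq = read_codes[L:] != ref_codes  # length n
    suffix_total = np.concatenate(([0], np.cumsum(tail_eq)))
    total = np.empty(n - L + 1, dtype=np.int64)
    for p in range(n - L + 1):
        total[p] = prefix_mm[p + L] + (suffix_total[n] - suffix_total[p])
    p = int(np.argmin(total))
    return p, int(total[p])


def _anchors_ok(
    read_codes: np.ndarray,
    ref_codes: np.ndarray,
    p: int,
    L: int,
    params: ItdParams,
) -> bool:
    """Both junction-flanking k-mers must match the reference nearly exactly."""
    k, max_mm = params.k, params.max_anchor_mismatches
    n = ref_codes.size
    # left anchor: the k read bases ending at the junction (end of first copy)
    lo = max(p + L - k, 0)
    left = int(np.sum(read_codes[lo : p + L] != ref_codes[lo : p + L]))
    # right anchor: the k read bases starting at the junction (start of second copy)
    hi = min(p + k, n)
    right = int(np.sum(read_codes[p + L : p + L + (hi - p)] != ref_codes[p:hi]))
    return left <= max_mm and right <= max_mm


def detect_itd(
    reads: Iterable[str],
    amplicon_reference: str,
    params: ItdParams = ItdParams(),
) -> list[ItdEvent]:
    """Detect internal tandem duplications in single-amplicon reads."""
    ref = amplicon_reference
    if len(ref) < 2 * params.k + params.min_itd_len:
        raise ValueError(
            f"reference of {len(ref)} bp is shorter than "
            f"2*k + min_itd_len = {2 * params.k + params.min_itd_len}"
        )
    ref_codes = encode(ref)

    unique = Counter(reads)
    total_reads = sum(unique.values())

    raw: dict[tuple[int, int], dict] = {}
    for seq, multiplicity in unique.items():
        L = len(seq) - len(ref)
        if L < params.min_itd_len:
            continue
        if L > len(ref):
            continue  # longer than a single full duplication; out of scope
        read_codes = encode(seq)
        p, mm = _best_placement(read_codes, ref_codes, L)
        if mm > params.max_mismatches:
            continue
        if not _anchors_ok(read_codes, ref_codes, p, L, params):
            continue
        key = (p, L)
        entry = raw.setdefault(key, {"support": 0, "mm": mm})
        entry["support"] += multiplicity
        entry["mm"] = min(entry["mm"], mm)

    # merge events within pos_tol at equal length
    merged: list[dict] = []
    for (p, L), entry in sorted(raw.items()):
        for ev in merged:
            if ev["L"] == L and abs(ev["p"] - p) <= params.pos_tol:
                ev["support"] += entry["support"]
                if entry["support"] > ev["top_support"]:
                    ev["p_rep"], ev["top_support"] = p, entry["support"]
                ev["mm"] = min(ev["mm"], entry["mm"])
                break
        else:
            merged.append(
                {"p": p, "p_rep": p, "L": L, "support": entry["support"],
                 "top_support": entry["support"], "mm": entry["mm"]}
            )

    events = []
    for ev in merged:
        if ev["support"] < params.min_support:
            continue
        p, L = ev["p_rep"], ev["L"]
        events.append(
            ItdEvent(
                position=p + 1,
                length=L,
                sequence=ref[p : p + L],
                support=ev["support"],
                total_reads=total_reads,
                mismatches=ev["mm"],
            )
        )
    events.sort(key=lambda e: (e.position, e.length))
    return events


def events_to_tsv_rows(events: Sequence[ItdEvent]) -> list[dict]:
    rows = []
    for ev in events:
        lo, hi = ev.confidence_interval()
        rows.append(
            {
                "position": ev.position,
                "length": ev.length,
                "sequence": ev.sequence,
                "support": ev.support,
                "total_reads": ev.total_reads,
                "vaf": ev.vaf,
                "vaf_ci95_low": lo,
                "vaf_ci95_high": hi,
            }
        )
    return rows
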