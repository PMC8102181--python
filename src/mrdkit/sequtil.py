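"""Nucleotide encoding and FASTQ I/O helpers.

Sequences are held as python strings at module boundaries and as
``numpy.uint8`` code arrays (A=0, C=1, G=2, T=3, N=4) inside the
vectorised kernels.
"""

from __future__ import annotations

import gzip
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

BASES = "ACGTN"
A, C, G, T, N = range(5)

_ENCODE = np.full(256, N, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 code array."""
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to a nucleotide string."""
    return _DECODE[codes].tobytes().decode()


def decode_rows(codes: np.ndarray) -> list[str]:
    """Decode a 2-D code array to one string per row."""
    flat = _DECODE[codes].tobytes().decode()
    width = codes.shape[1]
    return [flat[i : i + width] for i in range(0, len(flat), width)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))


def _open_text(path: str | Path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (name, sequence, quality) records from a (optionally gzipped) FASTQ."""
    with _open_text(path, "r") as handle:
        yield from FastqGeneralIterator(handle)


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> int:
    """Write (name, sequence, quality) records as 4-line FASTQ; returns record count."""
    n = 0
    with _open_text(path, "w") as handle:
        for name, seq, qual in records:
            handle.write(f"@{name}\n{seq}\n+\n{qual}\n")
            n += 1
    return n
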