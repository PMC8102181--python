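import numpy as np
import pytest

from mrdkit.consensus import PileupSet, Read, TargetPileup
from mrdkit.sequtil import random_sequence
from mrdkit.simdata import SimConfig, SpikeIn, simulate_sample

ZERO_ERRORS = {
    f"{a}>{b}": 0.0 for a in "ACGT" for b in "ACGT" if a != b
}


@pytest.fixture(scope="session")
def panel_refs() -> dict[str, str]:
    """Two short panel targets with distinct prefixes."""
    rng = np.random.default_rng(12345)
    return {"NPM1e12": random_sequence(80, rng), "NRASe2": random_sequence(60, rng)}


@pytest.fixture()
def small_sample(panel_refs):
    """An error-free simulated sample with one 5% SNV spike."""
    ref = panel_refs["NPM1e12"]
    alt = next(b for b in "ACGT" if b != ref[30])
    spike = SpikeIn("NPM1e12", 31, ref[30], alt, 0.05)
    cfg = SimConfig(
        reference_sequences=panel_refs,
        n_families_per_target=800,
        error_rates=dict(ZERO_ERRORS),
        spike_ins=[spike],
        seed=11,
    )
    return simulate_sample(cfg), spike


def reads_with_targets(sample) -> list[Read]:
    """Pipeline-ready reads with UMI and target taken from the simulator
    truth (bypasses extraction/assignment for tests that isolate grouping)."""
    umi_len = sample.config.umi_length
    out = []
    for name, seq, qual in sample.reads:
        _, target, fid, _ = name.split(":")
        out.append(
            Read(name, seq[umi_len:], qual[umi_len:], umi=seq[:umi_len], target=target)
        )
    return out


def pileup_with_counts(
    ref: str,
    depth: int,
    target: str = "TGT",
    base_alts: dict[tuple[int, str], int] | None = None,
    ins_alts: dict[tuple[int, str], int] | None = None,
) -> PileupSet:
    """Build a pileup directly from per-site counts: every site carries
    ``depth`` reference molecules minus whatever alternates are placed."""
    ps = PileupSet({target: ref})
    tp: TargetPileup = ps[target]
    for i, refbase in enumerate(ref):
        tp.counts["ACGTN".index(refbase), i] = depth
    for (pos, alt), cnt in (base_alts or {}).items():
        tp.counts["ACGTN".index(alt), pos - 1] += cnt
        tp.counts["ACGTN".index(ref[pos - 1]), pos - 1] -= cnt
    for (pos, seq), cnt in (ins_alts or {}).items():
        tp.ins_events[(pos, seq)] = cnt
    return ps
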