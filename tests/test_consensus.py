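"""UMI extraction, family grouping, quorum consensus and pileup
construction, checked against truth tables and brute-force oracles."""

import numpy as np
import pytest

from mrdkit.consensus import (
    ConsensusRead,
    PileupSet,
    Read,
    UmiConvention,
    UmiExtractionError,
    UmiFamily,
    UnequalReadLengthsError,
    build_pileup,
    consensus_family,
    consensus_pileup,
    extract_umi,
    group_families,
)
from mrdkit.simdata import SimConfig, SpikeIn, simulate_sample

from conftest import ZERO_ERRORS, reads_with_targets


class TestExtractUmi:
    def test_construction_example(self):
        read = Read("r1", "ACGTACGT" + "TTTTGGGG", "I" * 16)
        out = extract_umi(read)
        assert out.umi == "ACGTACGT"
        assert out.sequence == "TTTTGGGG"
        assert out.quality == "I" * 8
        assert out.name.endswith(":UMI:ACGTACGT")

    def test_short_read_rejected(self):
        with pytest.raises(UmiExtractionError):
            extract_umi(Read("r", "ACGTAC"))

    def test_umi_with_n_is_kept_distinct(self):
        reads = [
            extract_umi(Read(f"r{i}", "ACGTNCGT" + "AAAA")) for i in range(2)
        ]
        for r in reads:
            r.target = "T"
        families, _ = group_families(reads)
        assert len(families) == 1
        assert families[0].umi == "ACGTNCGT"

    def test_extracted_umis_match_truth_table(self, panel_refs):
        cfg = SimConfig(panel_refs, 500, error_rates=dict(ZERO_ERRORS), seed=21)
        sample = simulate_sample(cfg)
        truth_umi = dict(zip(sample.truth["family_id"], sample.truth["umi"]))
        for name, seq, qual in sample.reads[:1000]:
            fid = int(name.split(":")[2])
            out = extract_umi(Read(name, seq, qual))
            assert out.umi == truth_umi[fid]

    def test_configurable_offset(self):
        read = Read("r", "GG" + "ACGTACGTAC" + "TTTT")
        out = extract_umi(read, UmiConvention(length=10, offset=2))
        assert out.umi == "ACGTACGTAC"
        assert out.sequence == "GGTTTT"


class TestGroupFamilies:
    def test_worked_example_against_dict_oracle(self):
        reads = [
            Read("a", "A", umi="AAAAAAAA", target="tA"),
            Read("b", "A", umi="AAAAAAAA", target="tA"),
            Read("c", "A", umi="CCCCCCCC", target="tA"),
            Read("d", "A", umi="AAAAAAAA", target="tB"),
            Read("e", "A", umi="GGGGGGGG", target="tB"),
        ]
        families, stats = group_families(reads)
        assert len(families) == 1
        assert families[0].family_key == ("tA", "AAAAAAAA")
        assert families[0].size == 2
        assert stats.n_singleton_reads == 3

    def test_all_singletons_yield_no_families(self):
        reads = [Read(f"r{i}", "A", umi=f"{i:08d}", target="t") for i in range(10)]
        families, stats = group_families(reads)
        assert families == []
        assert stats.n_singleton_reads == 10

    def test_empty_input(self):
        families, stats = group_families([])
        assert families == [] and stats.n_reads == 0

    def test_random_grouping_matches_bruteforce(self):
        rng = np.random.default_rng(5)
        reads = [
            Read(f"r{i}", "A",
                 umi="UMI" + str(rng.integers(30)),
                 target=f"t{rng.integers(3)}")
            for i in range(400)
        ]
        expected: dict[tuple[str, str], int] = {}
        for r in reads:
            expected[(r.target, r.umi)] = expected.get((r.target, r.umi), 0) + 1
        families, stats = group_families(reads)
        assert {f.family_key: f.size for f in families} == {
            k: v for k, v in expected.items() if v >= 2
        }
        assert stats.n_singleton_reads == sum(v for v in expected.values() if v < 2)

    def test_retained_fraction_matches_truth_exactly(self, panel_refs):
        cfg = SimConfig(panel_refs, 2000, error_rates=dict(ZERO_ERRORS), seed=22)
        sample = simulate_sample(cfg)
        families, stats = group_families(reads_with_targets(sample))
        truth = sample.truth
        retained_truth = truth.loc[truth["size"] >= 2, "size"].sum()
        assert stats.n_reads - stats.n_singleton_reads == retained_truth
        assert len(families) == (truth["size"] >= 2).sum()


class TestConsensusFamily:
    @staticmethod
    def family(seqs, target="t", umi="AAAAAAAA"):
        return UmiFamily(target, umi, [Read(f"r{i}", s) for i, s in enumerate(seqs)])

    def test_unanimous_family(self):
        cons = consensus_family(self.family(["ACGT"] * 3))
        assert cons.sequence == "ACGT"
        assert cons.n_fraction == 0.0
        assert cons.family_size == 3

    def test_below_quorum_position_becomes_n(self):
        cons = consensus_family(
            self.family(["ACGT", "ACGT", "ACTT"]), quorum=0.7, max_n_fraction=1.0
        )
        assert cons.sequence == "ACNT"  # 2/3 G < 0.7 at position 3
        assert cons.n_fraction == 0.25

    def test_two_read_tie_is_n_for_any_majority_quorum(self):
        for quorum in (0.51, 0.7, 0.9):
            cons = consensus_family(
                self.family(["ACGT", "ACTT"]), quorum=quorum, max_n_fraction=1.0
            )
            assert cons.sequence == "ACNT"

    def test_unequal_lengths_refused(self):
        with pytest.raises(UnequalReadLengthsError):
            consensus_family(self.family(["ACGT", "ACG"]))

    def test_heavily_damaged_family_dropped(self):
        # 2 of 4 positions tie -> n_fraction 0.5 > 0.2
        assert consensus_family(self.family(["ACGT", "TGGT"])) is None

    def test_error_suppression_rate(self, panel_refs):
        """With 1% per-read error and family size >= 3, consensus bases
        disagree with the molecule haplotype at < 0.05% (quorum 0.7)."""
        ref = panel_refs["NPM1e12"]
        rates = {cls: 0.01 / 12 for cls in ZERO_ERRORS}
        cfg = SimConfig({"NPM1e12": ref}, 4000, family_size_mean=4.0,
                        error_rates=rates, seed=23)
        sample = simulate_sample(cfg)
        families, _ = group_families(reads_with_targets(sample), min_size=3)
        mismatches = bases = 0
        for fam in families:
            cons = consensus_family(fam, quorum=0.7)
            if cons is None:
                continue
            bases += len(cons.sequence)
            mismatches += sum(
                1 for a, b in zip(cons.sequence, ref) if a != "N" and a != b
            )
        assert bases >= 10**5
        assert mismatches / bases < 5e-4


class TestBuildPileup:
    def test_single_read_single_target(self):
        refs = {"t": "ACGT"}
        pileups, excluded = build_pileup(
            [ConsensusRead("t", "ACGT", 2, 0.0)], refs
        )
        tp = pileups["t"]
        assert excluded == 0
        assert [tp.site_depth(p) for p in range(1, 5)] == [1, 1, 1, 1]
        assert tp.base_count(1, "A") == tp.base_count(2, "C") == 1
        assert tp.base_count(1, "C") == 0

    def test_read_outside_design_excluded(self):
        refs = {"t": "ACGT"}
        pileups, excluded = build_pileup(
            [ConsensusRead("other", "ACGT", 2, 0.0)], refs
        )
        assert excluded == 1

    def test_error_free_sim_has_zero_nonref_counts(self, small_sample, panel_refs):
        sample, spike = small_sample
        families, _ = group_families(reads_with_targets(sample))
        cons = [consensus_family(f) for f in families]
        pileups, _ = build_pileup([c for c in cons if c], panel_refs)
        for tp in pileups:
            ref = panel_refs[tp.target]
            for pos in range(1, len(ref) + 1):
                if tp.target == spike.target and pos == spike.pos:
                    continue
                for base in "ACGT":
                    if base != ref[pos - 1]:
                        assert tp.base_count(pos, base) == 0

    def test_spike_fraction_matches_truth_among_retained(self, panel_refs):
        ref = panel_refs["NPM1e12"]
        alt = next(b for b in "ACGT" if b != ref[40])
        spike = SpikeIn("NPM1e12", 41, ref[40], alt, 0.01)
        cfg = SimConfig(panel_refs, 10_000, error_rates=dict(ZERO_ERRORS),
                        spike_ins=[spike], seed=24)
        sample = simulate_sample(cfg)
        families, _ = group_families(reads_with_targets(sample))
        cons = [c for f in families if (c := consensus_family(f))]
        pileups, _ = build_pileup(cons, panel_refs)
        tp = pileups["NPM1e12"]

        truth = sample.truth
        retained = truth[(truth["size"] >= 2) & (truth["target"] == "NPM1e12")]
        truth_frac = retained["haplotype"].str.contains(spike.label, regex=False).mean()
        observed = tp.base_count(41, alt) / tp.site_depth(41)
        se = np.sqrt(max(truth_frac, 1e-9) * (1 - truth_frac) / len(retained))
        assert abs(observed - truth_frac) <= 3 * se

    def test_depth_conservation_every_site(self, small_sample, panel_refs):
        """Site depth equals the retained consensus molecules on the target
        and decomposes exactly into base + N + deletion counts."""
        sample, _ = small_sample
        pileups, stats = consensus_pileup(
            (Read.from_tuple(r) for r in sample.reads), panel_refs
        )
        truth = sample.truth
        per_target = 0
        for tp in pileups:
            expected = int(
                ((truth["target"] == tp.target) & (truth["size"] >= 2)).sum()
            )
            assert (tp.depth == expected).all()
            assert (tp.depth == tp.counts.sum(axis=0) + tp.dels).all()
            per_target += expected
        assert stats.n_consensus_reads == per_target

    def test_insertion_and_deletion_events(self):
        ref = "ACGTACGTTACG"
        refs = {"t": ref}
        with_ins = ref[:6] + "CTAG" + ref[6:]
        with_del = ref[:4] + ref[7:]
        pileups, _ = build_pileup(
            [
                ConsensusRead("t", with_ins, 2, 0.0),
                ConsensusRead("t", with_del, 2, 0.0),
                ConsensusRead("t", ref, 2, 0.0),
            ],
            refs,
        )
        tp = pileups["t"]
        assert tp.ins_count(6, "CTAG") == 1
        assert tp.del_count(5, 3) == 1
        assert (tp.depth == 3).all()

    def test_insertion_left_normalisation(self):
        # duplicated homopolymer insertion shifts to the leftmost placement
        ref = "GGAAACTTTT"
        refs = {"t": ref}
        with_ins = "GGAAAACTTTT"  # one extra A, placeable anywhere in the run
        pileups, _ = build_pileup([ConsensusRead("t", with_ins, 2, 0.0)], refs)
        tp = pileups["t"]
        assert tp.ins_count(2, "A") == 1  # anchored after the last G
        assert tp.ins_count(5, "A") == 1  # equivalent placement, same event


class TestVectorisedDriver:
    def test_matches_per_family_composition(self, panel_refs, tmp_path):
        """The batched driver and the read-by-read composition of the four
        pipeline operations produce byte-identical pileups."""
        ref = panel_refs["NPM1e12"]
        spikes = [
            SpikeIn("NPM1e12", 41, ref[40],
                    next(b for b in "ACGT" if b != ref[40]), 0.05),
            SpikeIn("NPM1e12", 20, ref[19], ref[19] + "CTAG", 0.03),
        ]
        cfg = SimConfig(panel_refs, 600, spike_ins=spikes, seed=25)
        sample = simulate_sample(cfg)

        fast, _ = consensus_pileup(
            (Read.from_tuple(r) for r in sample.reads), panel_refs
        )

        from mrdkit.consensus import assign_target, build_prefix_index

        index = build_prefix_index(panel_refs)
        extracted = []
        for rec in sample.reads:
            read = extract_umi(Read.from_tuple(rec))
            read.target = assign_target(read.sequence, panel_refs, index)
            extracted.append(read)
        families, _ = group_families(extracted)
        cons = []
        for fam in families:
            try:
                c = consensus_family(fam)
            except UnequalReadLengthsError:
                continue
            if c:
                cons.append(c)
        slow, _ = build_pileup(cons, panel_refs)

        fast.to_tsv(tmp_path / "fast.tsv")
        slow.to_tsv(tmp_path / "slow.tsv")
        assert (tmp_path / "fast.tsv").read_bytes() == (tmp_path / "slow.tsv").read_bytes()

    def test_determinism_byte_identical(self, small_sample, panel_refs, tmp_path):
        sample, _ = small_sample
        for tag in ("a", "b"):
            pileups, _ = consensus_pileup(
                (Read.from_tuple(r) for r in sample.reads), panel_refs
            )
            pileups.to_tsv(tmp_path / f"{tag}.tsv")
        assert (tmp_path / "a.tsv").read_bytes() == (tmp_path / "b.tsv").read_bytes()

    def test_pileup_tsv_round_trip(self, small_sample, panel_refs, tmp_path):
        sample, spike = small_sample
        pileups, _ = consensus_pileup(
            (Read.from_tuple(r) for r in sample.reads), panel_refs
        )
        pileups.to_tsv(tmp_path / "p.tsv")
        loaded = PileupSet.from_tsv(tmp_path / "p.tsv")
        for tp in pileups:
            lt = loaded[tp.target]
            assert (lt.counts == tp.counts).all()
            assert (lt.dels == tp.dels).all()
            assert lt.ins_events == tp.ins_events
            assert lt.del_events == tp.del_events
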