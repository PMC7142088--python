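import itertools

import numpy as np
import pytest

from punchcard.channel import (
    ReadPairBatch,
    apply_pattern,
    denature,
    sim_reads,
)
from punchcard.codec import NickPattern, encode_payload
from punchcard.pipeline import RunConfig, roundtrip, simulate_layout
from punchcard.readout import (
    AlignmentRecord,
    DecodingError,
    InferredFragment,
    ReferenceIndex,
    accumulate_evidence,
    align,
    decode_run,
    decode_well,
    expected_length_set,
    infer_fragment,
    size_gate,
)
from punchcard.seqcore import revcomp


def _pattern(reg, symbols, mode="binary"):
    return NickPattern(reg.id, tuple(symbols), mode)


def _simulate(reg, symbols, mode="binary", coverage=2, err_rate=0.0, seed=0):
    fs = denature(apply_pattern(reg, _pattern(reg, symbols, mode)))
    return sim_reads(fs, {reg.id: reg.sequence}, coverage=coverage, err_rate=err_rate, seed=seed)


class TestAlign:
    def test_exact_substring_maps_at_origin(self, register10):
        index = ReferenceIndex({register10.id: register10.sequence})
        rec = align(register10.sequence[37:137], index)
        assert (rec.start, rec.end, rec.orientation, rec.mismatches) == (37, 137, "forward", 0)

    def test_single_substitution_still_maps(self, register10):
        index = ReferenceIndex({register10.id: register10.sequence})
        read = list(register10.sequence[37:137])
        read[50] = "A" if read[50] != "A" else "C"
        rec = align("".join(read), index)
        assert (rec.start, rec.end, rec.mismatches) == (37, 137, 1)

    def test_reverse_orientation_coordinates(self, register10):
        index = ReferenceIndex({register10.id: register10.sequence})
        rec = align(revcomp(register10.sequence[300:400]), index)
        assert (rec.start, rec.end, rec.orientation) == (300, 400, "reverse")

    def test_panel_demultiplexing_with_truth_tags(self, panel5):
        index = ReferenceIndex({r.id: r.sequence for r in panel5})
        reg = panel5.registers[2]
        batch = _simulate(reg, [1, 0, 1, 0, 1, 0][: reg.n_sites], seed=4)
        for pair in batch.pairs:
            rec = align(pair.seq1, index)
            assert rec is not None and rec.register_id == reg.id

    def test_read_shorter_than_seed_is_unmapped(self, register10):
        index = ReferenceIndex({register10.id: register10.sequence})
        assert align(register10.sequence[:19], index) is None

    def test_foreign_sequence_is_unmapped(self, register10):
        index = ReferenceIndex({register10.id: register10.sequence})
        from punchcard.seqcore import make_genome

        assert align(make_genome(1000, 0.5, 99).sequence[:100], index) is None


class TestFragmentInference:
    def _rec(self, rid, start, end, orientation):
        return AlignmentRecord("r", rid, start, end, orientation, 0)

    def test_overlapping_mates_span_fragment(self):
        f = infer_fragment(
            self._rec("R", 0, 100, "forward"), self._rec("R", 50, 150, "reverse")
        )
        assert (f.start, f.end, f.template_length, f.strand) == (0, 150, 150, "sense")

    def test_fully_contained_short_fragment(self):
        f = infer_fragment(
            self._rec("R", 10, 40, "reverse"), self._rec("R", 10, 40, "forward")
        )
        assert f.template_length == 30 and f.strand == "antisense"

    @pytest.mark.parametrize(
        "m1,m2",
        [
            (("A", 0, 100, "forward"), ("B", 0, 100, "reverse")),
            (("A", 0, 100, "forward"), ("A", 50, 150, "forward")),
        ],
    )
    def test_discordant_pairs_rejected(self, m1, m2):
        with pytest.raises(DecodingError):
            infer_fragment(self._rec(*m1), self._rec(*m2))


class TestSizeGate:
    def test_plus_minus_one_base_rule(self):
        f = lambda t: InferredFragment("R", 0, t, "sense")
        expected = {100, 150, 200}
        assert size_gate(f(150), expected)
        assert size_gate(f(149), expected) and size_gate(f(151), expected)
        assert not size_gate(f(160), expected)

    def test_expected_set_contains_all_pairwise_distances(self, register10):
        exp = expected_length_set(register10)
        b = register10.cut_bonds
        assert b[0] in exp and 450 - b[-1] in exp
        assert b[3] - b[1] in exp and 450 in exp


class TestEvidence:
    def test_full_pattern_gives_two_boundaries_per_site(self, register10):
        fs = denature(apply_pattern(register10, _pattern(register10, [1] * 10)))
        frags = [
            InferredFragment(f.register_id, f.start, f.end, f.strand)
            for f in fs.fragments
        ]
        table = accumulate_evidence(frags, {register10.id: register10})
        for site in register10.sites:
            assert table.sites[register10.id][site.ordinal]["sense"] == 2

    def test_full_length_fragment_gives_no_site_evidence(self, register10):
        frags = [InferredFragment(register10.id, 0, 450, "sense")]
        table = accumulate_evidence(frags, {register10.id: register10})
        assert all(
            c["sense"] == 0 and c["antisense"] == 0
            for c in table.sites[register10.id].values()
        )
        assert table.end_counts[register10.id] == 2

    def test_single_nick_at_site_three_evidences_only_site_three(self, register10):
        b3 = register10.sites[2].cut_bond
        frags = [
            InferredFragment(register10.id, 0, b3, "sense"),
            InferredFragment(register10.id, b3, 450, "sense"),
        ]
        table = accumulate_evidence(frags, {register10.id: register10})
        for site in register10.sites:
            expect = 2 if site.ordinal == 3 else 0
            assert table.sites[register10.id][site.ordinal]["sense"] == expect


class TestCalling:
    def test_code_238_called_from_full_evidence(self, register10):
        batch = _simulate(register10, [0, 1, 1, 0, 0, 0, 0, 1, 0, 0])
        patterns, _ = decode_well(batch, {register10.id: register10})
        assert patterns[register10.id].symbols == (0, 1, 1, 0, 0, 0, 0, 1, 0, 0)

    def test_zero_evidence_declares_all_zeros(self, register10):
        batch = _simulate(register10, [0] * 10)
        patterns, _ = decode_well(batch, {register10.id: register10})
        assert patterns[register10.id].symbols == (0,) * 10

    def test_hole_inference_survives_a_missing_middle_fragment(self, register10):
        """A dropped inter-nick fragment's cuts are still called from its
        neighbours' boundaries."""
        truth = [0, 0, 1, 0, 1, 0, 0, 0, 0, 0]
        fs = denature(apply_pattern(register10, _pattern(register10, truth)))
        b3, b5 = register10.sites[2].cut_bond, register10.sites[4].cut_bond
        kept = [f for f in fs.fragments if not (f.start == b3 and f.end == b5)]
        assert len(kept) == len(fs.fragments) - 1
        batch = sim_reads(
            type(fs)(kept), {register10.id: register10.sequence}, coverage=2
        )
        patterns, _ = decode_well(batch, {register10.id: register10})
        assert patterns[register10.id].symbols == tuple(truth)

    def test_ternary_truth_1212121211_decodes_exactly(self, register_two_sided):
        truth = [1, 2, 1, 2, 1, 2, 1, 2, 1, 1]
        batch = _simulate(register_two_sided, truth, mode="ternary")
        patterns, _ = decode_well(
            batch, {register_two_sided.id: register_two_sided}, mode="ternary"
        )
        assert patterns[register_two_sided.id].symbols == tuple(truth)

    def test_decoder_is_read_order_invariant(self, register10):
        truth = [1, 0, 0, 1, 0, 1, 1, 0, 0, 1]
        batch = _simulate(register10, truth, coverage=3, seed=2)
        rng = np.random.default_rng(0)
        shuffled = ReadPairBatch(
            [batch.pairs[i] for i in rng.permutation(len(batch.pairs))]
        )
        a, _ = decode_well(batch, {register10.id: register10})
        b, _ = decode_well(shuffled, {register10.id: register10})
        assert a[register10.id].symbols == b[register10.id].symbols == tuple(truth)

    def test_coverage_monotonicity_never_flips_a_correct_call(self, register10):
        truth = [1, 1, 0, 0, 1, 0, 1, 0, 0, 1]
        for coverage in (1, 2, 4, 8):
            batch = _simulate(register10, truth, coverage=coverage, seed=6)
            patterns, _ = decode_well(batch, {register10.id: register10})
            assert patterns[register10.id].symbols == tuple(truth)

    def test_empty_well_raises_naming_register(self, register10):
        with pytest.raises(DecodingError, match=register10.id):
            decode_well(ReadPairBatch([]), {register10.id: register10}, well="A1")


class TestEndToEnd:
    def test_80_bit_sample_set_recovers_perfectly(self):
        """Eight 10-bit blocks at coverage 5, err 0.001 -> bit accuracy 100%."""
        cfg = RunConfig(genome_length=4000, seed=1, coverage=5, err_rate=0.001)
        payload = bytes(range(10))  # 80 bits
        recovered, report = roundtrip(payload, cfg)
        assert recovered == payload
        assert report["bit_accuracy"] == 1.0

    def test_single_read_coverage_errorless_recovery(self):
        cfg = RunConfig(genome_length=4000, seed=2, coverage=1, err_rate=0.0)
        payload = b"\x5a\xa5\xff\x00\x13"
        recovered, _ = roundtrip(payload, cfg)
        assert recovered == payload

    def test_five_register_panel_random_patterns_coverage_one(self, panel5):
        rng = np.random.default_rng(12)
        registers = {r.id: r for r in panel5}
        for trial in range(20):
            reg = panel5.registers[trial % 5]
            truth = list(rng.integers(0, 2, reg.n_sites))
            batch = _simulate(reg, truth, coverage=1, seed=1000 + trial)
            patterns, _ = decode_well(batch, {reg.id: reg})
            assert patterns[reg.id].symbols == tuple(truth)

    def test_decode_run_full_inverse_with_report(self, panel5):
        payload = b"native DNA punch"
        layout = encode_payload(payload, panel5, "binary")
        cfg = RunConfig(coverage=3, err_rate=0.001, seed=5)
        batches = simulate_layout(layout, panel5, cfg)
        recovered, report = decode_run(batches, panel5, layout)
        assert recovered == payload
        assert set(report["wells"]) == set(layout.wells)
        assert all(s["kept"] > 0 for s in report["wells"].values())

    def test_wrong_design_forces_decoding_error(self, register10, panel5):
        """Reads simulated against one register cannot decode another."""
        batch = _simulate(register10, [1] * 10, coverage=2)
        other = panel5.registers[0]
        with pytest.raises(DecodingError):
            decode_well(batch, {other.id: other}, well="A1")

    def test_exhaustive_patterns_roundtrip_on_ten_site_register(self, register10):
        """Every one of the 1024 binary patterns survives write->read."""
        refs = {register10.id: register10.sequence}
        index = ReferenceIndex(refs)
        for bits in itertools.product([0, 1], repeat=10):
            fs = denature(apply_pattern(register10, _pattern(register10, bits)))
            batch = sim_reads(fs, refs, coverage=2, seed=hash(bits) % 2**31)
            patterns, _ = decode_well(
                batch, {register10.id: register10}, index=index
            )
            assert patterns[register10.id].symbols == bits
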