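"""Synthetic allele generator: planted truth, structural edits, I/O."""

import dataclasses

import pytest
from Bio.Seq import Seq
from hypothesis import given, settings
from hypothesis import strategies as st

from hicrepeats.constants import HET_E_CONSENSUS_AA, HYPERVARIABLE_POSITIONS
from hicrepeats.simulate import (
    MutationEvent,
    SimulationConfig,
    apply_unequal_crossover,
    build_variant_library,
    generate_allele,
    inject_disruption,
    read_truth_table,
    reverse_translate,
    simulate_cohort,
    write_simulation,
)


def translate(nt: str) -> str:
    return str(Seq(nt).translate())


class TestVariantLibrary:
    def test_single_entry_library_is_the_consensus(self):
        cfg = SimulationConfig(seed=1, variant_library_size=1)
        lib = build_variant_library(cfg)
        assert len(lib) == 1
        sig, nt = lib[0]
        assert translate(nt) == HET_E_CONSENSUS_AA
        assert sig == "GGSWDKA"

    def test_variant_alters_only_hypervariable_codons(self, library):
        for sig, nt in library:
            aa = translate(nt)
            for pos in range(1, 43):
                if pos in HYPERVARIABLE_POSITIONS:
                    continue
                assert aa[pos - 1] == HET_E_CONSENSUS_AA[pos - 1]

    def test_position39_substitution_changes_seventh_signature_char(self):
        # consensus has A at repeat position 39, the 7th signature slot
        mutated = list(HET_E_CONSENSUS_AA)
        mutated[38] = "V"
        from hicrepeats.catalog import extract_signature

        sig = extract_signature("".join(mutated))
        assert sig[:6] == "GGSWDK"
        assert sig[6] == "V"

    def test_signatures_pairwise_distinct(self, library):
        sigs = [s for s, _ in library]
        assert len(set(sigs)) == len(sigs)

    def test_deterministic_under_seed(self, sim_config, library):
        assert build_variant_library(sim_config) == library

    def test_alphabet_too_small_fails(self):
        cfg = SimulationConfig(
            seed=0, variant_library_size=3, hypervariable_alphabet="A"
        )
        with pytest.raises(ValueError, match="distinct signatures"):
            build_variant_library(cfg)


class TestGenerateAllele:
    def test_construction_arithmetic(self, clean_allele):
        assert len(clean_allele.full_sequence) == 2 * 500 + 11 * 126

    def test_empty_variant_list_gives_flanks_only(self, sim_config, library):
        allele = generate_allele(sim_config, [], "empty", library)
        assert allele.n_repeats == 0
        assert len(allele.full_sequence) == 1000

    def test_repeated_variant_gives_identical_signatures(self, sim_config, library):
        allele = generate_allele(sim_config, [1, 2, 3, 3, 4], "dup", library)
        sigs = allele.truth_signatures
        assert sigs[2] == sigs[3]

    def test_repeats_at_recorded_coordinates(self, clean_allele):
        full = clean_allele.full_sequence
        for (s, e), nt in zip(
            clean_allele.repeat_coordinates(), clean_allele.repeat_nt_seqs
        ):
            assert full[s:e] == nt

    def test_unknown_variant_id_rejected(self, sim_config, library):
        with pytest.raises(ValueError, match="unknown variant ID"):
            generate_allele(sim_config, [99], "bad", library)

    @given(rate=st.floats(min_value=0.0, max_value=0.02))
    @settings(max_examples=10, deadline=None)
    def test_identity_floor_without_background_noise(self, rate):
        # at rate 0 every repeat matches the consensus at >= 35/42 aa
        cfg = SimulationConfig(
            seed=3, variant_library_size=8, background_sub_rate=rate
        )
        lib = build_variant_library(cfg)
        allele = generate_allele(cfg, [1, 5, 8], "floor", lib)
        if rate == 0.0:
            for nt in allele.repeat_nt_seqs:
                aa = translate(nt)
                matches = sum(
                    a == b for a, b in zip(aa, HET_E_CONSENSUS_AA)
                )
                assert matches >= 35
        # background substitutions never create stops
        for nt in allele.repeat_nt_seqs:
            assert "*" not in translate(nt)


class TestUnequalCrossover:
    def test_duplication_inserts_tandem_copy(self, clean_allele):
        out = apply_unequal_crossover(clean_allele, 4, 1, "duplication")
        assert out.n_repeats == 12
        assert out.variant_ids[4] == out.variant_ids[5]
        assert out.repeat_nt_seqs[4] == out.repeat_nt_seqs[5]
        assert out.events[-1].kind == "duplication"

    def test_deletion_removes_block(self, clean_allele):
        out = apply_unequal_crossover(clean_allele, 3, 2, "deletion")
        assert out.n_repeats == 9
        expected = clean_allele.variant_ids[:3] + clean_allele.variant_ids[5:]
        assert out.variant_ids == expected

    def test_duplication_then_deletion_restores_barcode(self, clean_allele):
        dup = apply_unequal_crossover(clean_allele, 2, 3, "duplication")
        back = apply_unequal_crossover(dup, 2, 3, "deletion")
        assert back.variant_ids == clean_allele.variant_ids
        assert back.repeat_nt_seqs == clean_allele.repeat_nt_seqs

    def test_block_out_of_range(self, clean_allele):
        with pytest.raises(ValueError, match="out of range"):
            apply_unequal_crossover(clean_allele, 10, 2, "duplication")

    def test_input_not_mutated(self, clean_allele):
        before = list(clean_allele.variant_ids)
        apply_unequal_crossover(clean_allele, 0, 1, "deletion")
        assert clean_allele.variant_ids == before


class TestDisruptions:
    def test_stop_translates_to_stop_symbol(self, sim_config, clean_allele):
        out = inject_disruption(clean_allele, 5, "stop", sim_config)
        assert "*" in translate(out.repeat_nt_seqs[5])

    def test_stop_preserves_signature_codons(self, sim_config, clean_allele):
        out = inject_disruption(clean_allele, 5, "stop", sim_config)
        aa = translate(out.repeat_nt_seqs[5])
        for p in HYPERVARIABLE_POSITIONS:
            assert aa[p - 1] == translate(clean_allele.repeat_nt_seqs[5])[p - 1]

    def test_frameshift_removes_exactly_one_bp(self, sim_config, clean_allele):
        out = inject_disruption(clean_allele, 2, "frameshift", sim_config)
        assert len(out.full_sequence) == len(clean_allele.full_sequence) - 1

    def test_no_disruption_means_stop_free(self, clean_allele):
        for nt in clean_allele.repeat_nt_seqs:
            assert "*" not in translate(nt)

    def test_events_logged(self, sim_config, clean_allele):
        out = inject_disruption(clean_allele, 0, "stop", sim_config)
        assert out.events[-1] == MutationEvent("stop", 0, out.events[-1].detail)


class TestIO:
    def test_round_trip(self, tmp_path, sim_config, library):
        alleles = [
            generate_allele(sim_config, [1, 2, 3], "x1", library),
            generate_allele(sim_config, [4, 4, 5, 6], "x2", library),
        ]
        fasta, truth = tmp_path / "sim.fasta", tmp_path / "truth.tsv"
        write_simulation(alleles, fasta, truth)
        rows = read_truth_table(truth)
        assert [r["allele_id"] for r in rows] == ["x1", "x2"]
        assert rows[1]["variant_ids"] == [4, 4, 5, 6]
        headers = [
            line[1:].split()[0]
            for line in fasta.read_text().splitlines()
            if line.startswith(">")
        ]
        assert headers == ["x1", "x2"]

    def test_empty_cohort_valid_files(self, tmp_path):
        fasta, truth = tmp_path / "e.fasta", tmp_path / "e.tsv"
        write_simulation([], fasta, truth)
        assert fasta.read_text() == ""
        assert read_truth_table(truth) == []

    def test_byte_identical_outputs_under_same_seed(self, tmp_path):
        def run(sub):
            cfg = SimulationConfig(seed=11, variant_library_size=6)
            alleles = simulate_cohort(cfg, 4)
            d = tmp_path / sub
            d.mkdir()
            write_simulation(alleles, d / "s.fasta", d / "t.tsv")
            return (d / "s.fasta").read_bytes(), (d / "t.tsv").read_bytes()

        assert run("a") == run("b")


def test_config_invariants_enforced():
    with pytest.raises(ValueError):
        SimulationConfig(repeat_period_nt=125)
    with pytest.raises(ValueError):
        SimulationConfig(hypervariable_positions=(0, 11))
    with pytest.raises(ValueError):
        SimulationConfig(background_sub_rate=1.5)


def test_reverse_translation_is_lexicographic_first_codon():
    assert reverse_translate("M") == "ATG"
    assert reverse_translate("W") == "TGG"
    assert reverse_translate("G") == "GGA"
    assert translate(reverse_translate(HET_E_CONSENSUS_AA)) == HET_E_CONSENSUS_AA


def test_immutable_config_frozen(sim_config):
    with pytest.raises(dataclasses.FrozenInstanceError):
        sim_config.seed = 99
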