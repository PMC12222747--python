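"""Repeat detection: window scan, chaining, rescue, haplotype extraction."""

import numpy as np
import pytest
from Bio.Seq import Seq

from hicrepeats.constants import (
    HET_E_CONSENSUS_AA,
    HYPERVARIABLE_POSITIONS,
    REPEAT_PERIOD_NT,
)
from hicrepeats.detect import (
    DetectionParams,
    GeneSequence,
    detect_repeats,
    extract_haplotype,
    flag_disruptions,
    write_track_tsv,
)
from hicrepeats.simulate import (
    SimulationConfig,
    generate_allele,
    inject_disruption,
    reverse_translate,
    simulate_cohort,
)


def random_nt(seed: int, length: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list("ACGT"), size=length))


def brute_force_windows(nt: str, params: DetectionParams):
    """Independent oracle: enumerate every 42-aa window in every frame
    and filter by the non-hypervariable mismatch rule."""
    hv0 = {p - 1 for p in params.hypervariable_positions}
    L = len(params.consensus_aa)
    accepted = []
    for frame in range(3):
        sub = nt[frame:]
        sub = sub[: len(sub) - len(sub) % 3]
        aa = str(Seq(sub).translate())
        for i in range(len(aa) - L + 1):
            window = aa[i : i + L]
            mm = sum(
                1
                for k in range(L)
                if k not in hv0 and window[k] != params.consensus_aa[k]
            )
            if mm <= params.max_mismatch_nonhv:
                accepted.append((frame + 3 * i, mm, frame, window))
    return sorted(accepted)


class TestDetection:
    def test_planted_allele_fully_recovered(self, clean_allele):
        track = detect_repeats(GeneSequence("g", clean_allele.full_sequence))
        assert len(track.hits) == 11
        assert all(not h.flags for h in track.hits)
        planted_aa = [
            str(Seq(nt).translate()) for nt in clean_allele.repeat_nt_seqs
        ]
        assert [h.aa for h in track.hits] == planted_aa

    def test_printed_consensus_repeat_in_random_flanks(self):
        # the canonical 42-aa het-e repeat, reverse-translated and
        # embedded in 500 nt of random flank on each side
        insert = reverse_translate(HET_E_CONSENSUS_AA)
        gene = GeneSequence(
            "embedded", random_nt(5, 500) + insert + random_nt(6, 500)
        )
        track = detect_repeats(gene)
        assert len(track.hits) == 1
        hit = track.hits[0]
        assert hit.aa == HET_E_CONSENSUS_AA
        assert len(hit.aa) == 42
        assert hit.end - hit.start == REPEAT_PERIOD_NT == 126
        assert (hit.start, hit.end) == (500, 500 + 126)

    def test_random_sequence_yields_no_hits(self):
        gene = GeneSequence("rand", random_nt(3, 2000))
        track = detect_repeats(gene)
        assert track.hits == []
        # confirmed against the exhaustive window scan
        assert brute_force_windows(gene.nt, DetectionParams()) == []

    @pytest.mark.parametrize("n_repeats", [1, 3, 5])
    def test_pass1_matches_brute_force_oracle(self, sim_config, library, n_repeats):
        allele = generate_allele(
            sim_config, list(range(1, n_repeats + 1)), f"o{n_repeats}", library
        )
        gene = GeneSequence("o", allele.full_sequence)
        params = DetectionParams()
        oracle = brute_force_windows(gene.nt, params)
        track = detect_repeats(gene, params)
        # greedy chaining of the oracle's accepted windows
        chained = []
        cursor = 0
        for start, mm, frame, aa in oracle:
            if start >= cursor:
                chained.append((start, aa))
                cursor = start + REPEAT_PERIOD_NT
        assert [(h.start, h.aa) for h in track.hits] == chained

    def test_coordinate_round_trip(self, clean_allele):
        gene = GeneSequence("g", clean_allele.full_sequence)
        for hit in detect_repeats(gene).hits:
            assert gene.nt[hit.start : hit.end] == hit.nt

    def test_ordinals_strictly_increasing_and_nonoverlapping(self, clean_allele):
        track = detect_repeats(GeneSequence("g", clean_allele.full_sequence))
        for a, b in zip(track.hits, track.hits[1:]):
            assert a.ordinal + 1 == b.ordinal
            assert a.end <= b.start

    def test_recovery_rate_under_background_noise(self):
        # >= 99% of alleles recover the planted barcode length at
        # 0.01/site background substitution, over many seeds
        total = ok = 0
        for seed in range(10):
            cfg = SimulationConfig(
                seed=seed, variant_library_size=12, background_sub_rate=0.01
            )
            for allele in simulate_cohort(cfg, 10):
                track = detect_repeats(
                    GeneSequence(allele.allele_id, allele.full_sequence)
                )
                total += 1
                ok += len(track.barcode_hits()) == allele.n_repeats
        assert ok / total >= 0.99


class TestDisruptionFlags:
    def test_planted_stop_flagged_at_its_repeat(self, sim_config, clean_allele):
        disrupted = inject_disruption(clean_allele, 5, "stop", sim_config)
        track = detect_repeats(GeneSequence("g", disrupted.full_sequence))
        assert len(track.hits) == 11
        flagged = [h.ordinal for h in track.hits if "has_stop" in h.flags]
        assert flagged == [5]

    @pytest.mark.parametrize("index", [0, 3, 10])
    def test_planted_frameshift_rescued_once(self, sim_config, clean_allele, index):
        disrupted = inject_disruption(clean_allele, index, "frameshift", sim_config)
        track = detect_repeats(GeneSequence("g", disrupted.full_sequence))
        assert len(track.hits) == 11
        suspects = [h for h in track.hits if "frameshift_suspect" in h.flags]
        assert len(suspects) == 1
        # a boundary-adjacent deletion may manifest one unit downstream
        assert abs(suspects[0].ordinal - index) <= 1

    def test_clean_track_carries_no_flags(self, clean_allele):
        track = detect_repeats(GeneSequence("g", clean_allele.full_sequence))
        assert all(not h.flags for h in track.hits)

    def test_flag_disruptions_idempotent(self, sim_config, clean_allele):
        disrupted = inject_disruption(clean_allele, 2, "stop", sim_config)
        track = detect_repeats(GeneSequence("g", disrupted.full_sequence))
        again = flag_disruptions(flag_disruptions(track))
        assert [h.flags for h in again.hits] == [h.flags for h in track.hits]


class TestHaplotypeExtraction:
    def test_anchored_region_contains_all_repeats(self, clean_allele):
        full = clean_allele.full_sequence
        up, down = full[100:150], full[-150:-100]
        region = extract_haplotype(GeneSequence("asm", full), up, down)
        coords = clean_allele.repeat_coordinates()
        assert len(region.nt) == (len(full) - 100) - 100
        track = detect_repeats(region)
        assert len(track.hits) == len(coords)

    def test_absent_anchor_raises(self, clean_allele):
        with pytest.raises(ValueError, match="not found"):
            extract_haplotype(
                GeneSequence("asm", clean_allele.full_sequence),
                "T" * 30,
                clean_allele.full_sequence[-50:],
            )

    def test_inverted_anchors_raise(self, clean_allele):
        full = clean_allele.full_sequence
        with pytest.raises(ValueError, match="out of order"):
            extract_haplotype(GeneSequence("asm", full), full[-60:-20], full[:40])

    def test_adjacent_anchors_give_minimal_region(self):
        up, down = random_nt(8, 40), random_nt(9, 40)
        gene = GeneSequence("asm", random_nt(10, 200) + up + down + random_nt(11, 200))
        region = extract_haplotype(gene, up, down)
        assert region.nt == up + down

    def test_short_anchor_rejected(self, clean_allele):
        with pytest.raises(ValueError, match="shorter than 20"):
            extract_haplotype(
                GeneSequence("asm", clean_allele.full_sequence), "ACGT", "ACGT" * 6
            )


def test_track_tsv_uses_1based_inclusive_coordinates(tmp_path, clean_allele):
    track = detect_repeats(GeneSequence("g1", clean_allele.full_sequence))
    path = tmp_path / "track.tsv"
    write_track_tsv(track, path)
    lines = path.read_text().splitlines()
    first = lines[1].split("\t")
    assert first[0] == "g1"
    assert int(first[2]) == track.hits[0].start + 1
    assert int(first[3]) == track.hits[0].end


def test_invalid_sequences_rejected():
    with pytest.raises(ValueError):
        GeneSequence("x", "")
    with pytest.raises(ValueError):
        GeneSequence("x", "ACGU")
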