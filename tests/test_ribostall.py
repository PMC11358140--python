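import numpy as np
import pandas as pd
import pytest

from senestack import synthdata
from senestack.ribostall import (
    OffsetConfig,
    assign_sites,
    codon_region_profile,
    compare_conditions,
    site_pause_scores,
)
from senestack.transcripts import Transcriptome


def rpf_row(transcript, pos, count=1, length=30):
    return {"transcript": transcript, "five_prime_pos": pos,
            "read_length": length, "count": count}


@pytest.fixture(scope="module")
def toy_transcriptome():
    """Single CDS of 29 sense codons + stop with a known peptide, 30-nt UTRs.

    With edge_exclude=5 the eligible range is codons 5..24 (20 codons) and
    contains exactly two glycines, at codon indices 10 and 20.
    """
    aa_codon = {"G": "GGT", "A": "GCT", "L": "CTG", "S": "TCT"}
    body = ["A", "L", "S", "L", "A",            # 0-4
           "L", "A", "S", "L", "A",            # 5-9
           "G", "L", "A", "S", "L",            # 10-14
           "A", "S", "L", "A", "S",            # 15-19
           "G", "L", "A", "S", "L",            # 20-24
           "A", "S", "L", "A"]                 # 25-28
    codons = [aa_codon[a] for a in body]
    seq = "A" * 30 + "".join(codons) + "TAA" + "C" * 30
    return Transcriptome(sequences={"toy": seq}, cds={"toy": (30, 30 + 90)})


class TestOffsetConfig:
    def test_default_is_epa_9_12_15(self):
        cfg = OffsetConfig()
        assert (cfg.o_e, cfg.o_p, cfg.o_a) == (9, 12, 15)

    @pytest.mark.parametrize("offsets", [(9, 12, 14), (12, 9, 15), (9, 13, 17)])
    def test_invalid_spacing_rejected(self, offsets):
        with pytest.raises(ValueError):
            OffsetConfig(*offsets)


class TestAssignSites:
    def test_read_at_cds_start_hits_codon_5(self, toy_transcriptome):
        rpf = pd.DataFrame([rpf_row("toy", 30)])
        assigned, excluded = assign_sites(rpf, toy_transcriptome)
        assert excluded == 0
        row = assigned.iloc[0]
        assert (row.e_codon, row.p_codon, row.a_codon) == (3, 4, 5)

    def test_three_nt_shift_moves_sites_one_codon(self, toy_transcriptome):
        rpf = pd.DataFrame([rpf_row("toy", 30), rpf_row("toy", 27)])
        assigned, _ = assign_sites(rpf, toy_transcriptome)
        by_pos = assigned.set_index("five_prime_pos")
        assert by_pos.loc[27, "a_codon"] == by_pos.loc[30, "a_codon"] - 1

    def test_a_site_beyond_stop_excluded(self, toy_transcriptome):
        # A site would land at codon 31 > last codon index 29
        rpf = pd.DataFrame([rpf_row("toy", 30 + 90 - 12, count=3)])
        assigned, excluded = assign_sites(rpf, toy_transcriptome)
        assert len(assigned) == 0
        assert excluded == 3

    def test_out_of_frame_excluded(self, toy_transcriptome):
        rpf = pd.DataFrame([rpf_row("toy", 31, count=2)])
        _, excluded = assign_sites(rpf, toy_transcriptome)
        assert excluded == 2

    def test_unknown_transcript_errors(self, toy_transcriptome):
        rpf = pd.DataFrame([rpf_row("ghost", 30)])
        with pytest.raises(KeyError):
            assign_sites(rpf, toy_transcriptome)

    @pytest.mark.parametrize("offsets", [(0, 3, 6), (9, 12, 15), (12, 15, 18)])
    def test_reads_conserved_for_any_offsets(self, paused_rpf, paused_transcriptome, offsets):
        assigned, excluded = assign_sites(
            paused_rpf, paused_transcriptome, OffsetConfig(*offsets)
        )
        assert assigned["count"].sum() + excluded == paused_rpf["count"].sum()


class TestCodonRegionProfile:
    def test_axis_has_window_positions(self, paused_rpf, paused_transcriptome):
        profile = codon_region_profile(paused_rpf, paused_transcriptome, "W", window=61)
        assert len(profile.positions) == 61
        assert profile.positions[0] == -30 and profile.positions[-1] == 30

    def test_uniform_coverage_gives_flat_profile(self, toy_transcriptome):
        """Counts at every nt make each instance window exactly flat."""
        seq_len = len(toy_transcriptome.sequences["toy"])
        rpf = pd.DataFrame([rpf_row("toy", p, count=2) for p in range(seq_len)])
        profile = codon_region_profile(rpf, toy_transcriptome, "G", window=61)
        assert np.abs(profile.density - 1.0).max() < 0.05
        assert profile.n_instances == 2

    def test_window_mean_is_normalized(self, paused_rpf, paused_transcriptome):
        profile = codon_region_profile(paused_rpf, paused_transcriptome, "L", window=61)
        assert profile.density.mean() == pytest.approx(1.0, abs=1e-9)

    def test_pause_peak_sits_a_site_offset_upstream(self, paused_rpf, paused_transcriptome):
        profile = codon_region_profile(paused_rpf, paused_transcriptome, "W", window=61)
        assert profile.positions[np.argmax(profile.density)] == -15

    def test_even_window_rejected(self, paused_rpf, paused_transcriptome):
        with pytest.raises(ValueError, match="odd"):
            codon_region_profile(paused_rpf, paused_transcriptome, "W", window=60)

    def test_absent_anchor_errors(self, paused_rpf, paused_transcriptome):
        with pytest.raises(ValueError, match="anchor"):
            # TAG never occurs in the synthetic CDS (stop is always TAA)
            codon_region_profile(paused_rpf, paused_transcriptome, "TAG", window=61)
        with pytest.raises(ValueError, match="anchor"):
            codon_region_profile(
                paused_rpf.iloc[:0], paused_transcriptome, "W", window=61
            )


class TestSitePauseScores:
    def test_uniform_coverage_scores_near_one(self):
        tx = synthdata.make_transcriptome(n_transcripts=5, n_codons=200, seed=21)
        rpf = synthdata.simulate_rpf(tx, depth=1_000_000, seed=21)
        scores = site_pause_scores(rpf, tx, level="aa")
        assert np.abs(np.log2(scores["score"])).max() < 0.2

    def test_hand_enumerated_glycine_score(self, toy_transcriptome):
        """All 100 reads on the A-site glycine at codon 10: the eligible range
        holds 20 codons of which 2 are glycine, so expected = 100 * 2/20 = 10
        and the glycine A-site score is exactly 10."""
        rpf = pd.DataFrame([rpf_row("toy", 30 + 3 * 10 - 15, count=100)])
        scores = site_pause_scores(rpf, toy_transcriptome, level="aa")
        a_site = scores[scores["site"] == "A"].set_index("category")
        assert a_site.loc["G", "observed"] == 100
        assert a_site.loc["G", "expected"] == pytest.approx(10.0)
        assert a_site.loc["G", "score"] == pytest.approx(10.0)

    def test_programmed_proline_pause_recovered_at_a_site(self):
        tx = synthdata.make_transcriptome(
            n_transcripts=4, n_codons=150,
            pauses=[(f"tx{i:04d}", 50 + 7 * i, "P", 10.0) for i in range(4)],
            seed=22,
        )
        rpf = synthdata.simulate_rpf(tx, depth=200_000, seed=22)
        scores = site_pause_scores(rpf, tx, level="aa")
        a_site = scores[scores["site"] == "A"].set_index("category")["score"]
        assert a_site.idxmax() == "P"

    def test_tripeptide_level_uses_epa_triplet(self, toy_transcriptome):
        rpf = pd.DataFrame([rpf_row("toy", 30 + 3 * 10 - 15, count=10)])
        scores = site_pause_scores(rpf, toy_transcriptome, level="tripeptide")
        assert set(scores["site"]) == {"EPA"}
        top = scores.loc[scores["observed"].idxmax(), "category"]
        assert top == "LAG"  # codons 8, 9, 10 of the toy peptide


class TestCompareConditions:
    def test_identical_inputs_all_ratios_one(self, toy_transcriptome):
        rpf = pd.DataFrame([rpf_row("toy", 30 + 3 * c - 15, count=5) for c in range(5, 25)])
        scores = site_pause_scores(rpf, toy_transcriptome, level="aa")
        out = compare_conditions(scores, scores.copy())
        assert np.allclose(out["ratio"].dropna(), 1.0)

    def test_doubled_score_gives_ratio_two(self):
        a = pd.DataFrame({"site": ["A"], "category": ["P"], "observed": [20.0],
                          "expected": [10.0], "score": [2.0]})
        b = a.assign(score=[1.0])
        out = compare_conditions(a, b)
        assert out["ratio"].iloc[0] == pytest.approx(2.0)

    def test_mismatched_categories_error(self):
        a = pd.DataFrame({"site": ["A"], "category": ["P"], "observed": [1.0],
                          "expected": [1.0], "score": [1.0]})
        b = a.assign(category=["G"])
        with pytest.raises(ValueError, match="mismatched"):
            compare_conditions(a, b)

    def test_programmed_pause_tops_condition_ratio(self):
        """A pause present only in the 'treated' condition surfaces as the
        top per-amino-acid ratio."""
        hits = 0
        for rep in range(10):
            paused = synthdata.make_transcriptome(
                n_transcripts=3, n_codons=120,
                pauses=[("tx0000", 60, "G", 20.0)], seed=100 + rep,
            )
            # identical sequences, but the pause weight removed
            control = synthdata.SynthTranscriptome(
                sequences=paused.sequences, cds=paused.cds, pause_spec=[]
            )
            rpf_treated = synthdata.simulate_rpf(paused, depth=100_000, seed=200 + rep)
            rpf_control = synthdata.simulate_rpf(control, depth=100_000, seed=300 + rep)
            s_t = site_pause_scores(rpf_treated, paused, level="aa")
            s_c = site_pause_scores(rpf_control, control, level="aa")
            out = compare_conditions(s_t, s_c)
            a_site = out[out["site"] == "A"].set_index("category")["ratio"]
            hits += a_site.idxmax() == "G"
        assert hits == 10
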