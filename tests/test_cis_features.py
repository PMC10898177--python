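"""PWM scoring, branchpoint and PPT detection, GC, positions, architecture."""

from __future__ import annotations

import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cisplice.annotation_io import GeneModel, SequenceAccessor, TranscriptModel
from cisplice.cis_features import (
    Pwm,
    at_fraction,
    find_branchpoint,
    gc_fraction,
    gene_architecture,
    ppt_metrics,
    relative_position,
    representative_transcript,
    score_site,
    shipped_branch_pwm,
)

BASES = "ACGT"


# ---------------------------------------------------------------------------
# PWM training and scoring


def test_count_training_hand_arithmetic():
    # one position with counts A=3, C=1, pseudocount 1/base, uniform bg:
    # P(A) = (3+1)/(4+4) = 0.5 -> log2(0.5/0.25) = 1 bit
    pwm = Pwm.from_counts(np.array([[3, 1, 0, 0]]))
    assert pwm.log_odds[0, 0] == pytest.approx(1.0)
    assert pwm.log_odds[0, 1] == pytest.approx(0.0)  # (1+1)/8 = 0.25


def test_uniform_counts_give_zero_bits():
    pwm = Pwm.from_counts(np.full((3, 4), 5.0))
    assert np.allclose(pwm.log_odds, 0.0)


def test_identical_training_donors_score_consensus_with_shrinkage():
    n = 20
    pwm = Pwm.from_sequences(["CAGGTAAGT"] * n)
    # every position: P = (n+1)/(n+4); 9 positions of log2(P/0.25),
    # i.e. 18 bits minus the pseudocount shrinkage
    expected = 9 * math.log2(((n + 1) / (n + 4)) / 0.25)
    assert score_site(pwm, "CAGGTAAGT") == pytest.approx(expected)
    assert expected < 18.0


def test_scoring_matches_per_position_oracle_exhaustively():
    rng = np.random.default_rng(11)
    counts = rng.integers(0, 40, size=(4, 4))
    pwm = Pwm.from_counts(counts)
    lo = pwm.log_odds
    for window in product(BASES, repeat=4):
        oracle = sum(lo[i, BASES.index(b)] for i, b in enumerate(window))
        assert score_site(pwm, "".join(window)) == pytest.approx(oracle, abs=1e-12)


def test_uniform_pwm_scores_zero_everywhere():
    pwm = Pwm(np.full((5, 4), 0.25), np.full(4, 0.25))
    assert score_site(pwm, "ACGTA") == 0.0


def test_consensus_window_is_argmax():
    pwm = Pwm.from_sequences(["CAGGTAAGT"] * 10)
    best = score_site(pwm, "CAGGTAAGT")
    rng = np.random.default_rng(3)
    for _ in range(50):
        w = "".join(rng.choice(list(BASES), 9))
        assert score_site(pwm, w) <= best + 1e-12


def test_n_contributes_zero():
    pwm = Pwm.from_counts(np.array([[10, 0, 0, 0], [0, 10, 0, 0]]))
    assert score_site(pwm, "NN") == 0.0
    assert score_site(pwm, "AN") == pytest.approx(pwm.log_odds[0, 0])


def test_wrong_window_length_is_error():
    pwm = Pwm.from_counts(np.array([[1, 1, 1, 1]]))
    with pytest.raises(ValueError, match="length"):
        score_site(pwm, "ACG")


def test_pwm_tsv_round_trip(tmp_path):
    pwm = Pwm.from_sequences(["CAGGTAAGT"] * 7)
    p = tmp_path / "pwm.tsv"
    pwm.write_tsv(p)
    back = Pwm.read_tsv(p)
    assert np.allclose(back.probs, pwm.probs, atol=1e-6)


# ---------------------------------------------------------------------------
# branchpoint


def _intron_with_planted_bp(length, a_index, filler="G"):
    """An intron whose only branch-consensus heptamer has its A at a_index."""
    seq = [filler] * length
    seq[a_index - 5 : a_index + 2] = list("TACTAAC")
    return "".join(seq)


def test_branchpoint_distance_arithmetic():
    seq = _intron_with_planted_bp(40, 14)
    d, score = find_branchpoint(seq)
    assert d == 25  # 40 - (14 + 1)
    assert score > 0


def test_short_intron_has_missing_branchpoint():
    d, score = find_branchpoint("G" * 20)
    assert math.isnan(d) and math.isnan(score)


def test_branchpoint_window_excludes_near_acceptor_placements():
    # planted A only 10 nt from the 3' end: outside the 18-100 search window
    seq = _intron_with_planted_bp(60, 49)
    d, _ = find_branchpoint(seq)
    assert d != 10


def test_ties_resolve_to_three_prime_most_maximum():
    seq = list("G" * 80)
    for a_index in (30, 50):
        seq[a_index - 5 : a_index + 2] = list("TACTAAC")
    d, _ = find_branchpoint("".join(seq))
    assert d == 80 - 51  # the 3'-most of the two identical maxima


def _brute_force_bp(seq, pwm):
    L = len(seq)
    best = None
    for i in range(5, L - 1):
        d = L - (i + 1)
        if not (18 <= d <= 100) or i + 2 > L:
            continue
        window = seq[i - 5 : i + 2]
        if len(window) != 7:
            continue
        s = score_site(pwm, window)
        if best is None or s > best[1] or (s == best[1] and i > best[2]):
            best = (d, s, i)
    return (best[0], best[1]) if best else (math.nan, math.nan)


def test_branchpoint_matches_exhaustive_scan_on_random_introns():
    rng = np.random.default_rng(42)
    pwm = shipped_branch_pwm()
    for _ in range(200):
        L = int(rng.integers(25, 220))
        seq = "".join(rng.choice(list(BASES), L))
        assert find_branchpoint(seq, pwm) == pytest.approx(_brute_force_bp(seq, pwm))


# ---------------------------------------------------------------------------
# polypyrimidine tract


@pytest.mark.parametrize(
    "region, expected",
    [
        ("TTTTTT", (6, 6.0)),
        ("CCCC", (4, 2.0)),
        ("TTCGTT", (3, 2.5)),  # runs: TTC = 2.5 beats TT = 2.0
        ("GAGA", (0, 0.0)),
    ],
)
def test_ppt_runs(region, expected):
    # build an intron where seq[bp+1 : L-2] == region
    bp_index = 4
    seq = "G" * (bp_index + 1) + region + "AG"
    assert ppt_metrics(seq, bp_index) == expected


# ---------------------------------------------------------------------------
# GC content


@pytest.mark.parametrize(
    "seq, expected", [("ATGC", 0.5), ("GGCC", 1.0), ("AT", 0.0), ("ANGC", 2 / 3)]
)
def test_gc_fraction_examples(seq, expected):
    assert gc_fraction(seq) == pytest.approx(expected)


def test_all_n_sequence_is_missing():
    assert math.isnan(gc_fraction("NNN"))


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=1, max_size=100))
def test_gc_plus_at_is_one_and_revcomp_invariant(seq):
    assert gc_fraction(seq) + at_fraction(seq) == pytest.approx(1.0)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(seq))
    assert gc_fraction(rc) == pytest.approx(gc_fraction(seq))


# ---------------------------------------------------------------------------
# relative position and architecture


def _one_tx_gene(strand, exons, gene_id="g"):
    return GeneModel(gene_id, "c", strand, (TranscriptModel("t", tuple(exons)),))


def test_relative_position_plus_and_mirrored_minus():
    plus = _one_tx_gene("+", [(0, 300), (400, 1000)])
    minus = _one_tx_gene("-", [(0, 300), (400, 1000)])
    assert relative_position((100, 200), plus) == pytest.approx(0.15)
    assert relative_position((100, 200), minus) == pytest.approx(0.85)


def test_relative_position_midpoint_is_half_either_strand():
    for strand in "+-":
        g = _one_tx_gene(strand, [(0, 400), (600, 1000)])
        assert relative_position((450, 550), g) == pytest.approx(0.5)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.integers(0, 800), st.integers(1, 200))
def test_strand_mirror_sums_to_one(start, length):
    plus = _one_tx_gene("+", [(0, 1000)])
    minus = _one_tx_gene("-", [(0, 1000)])
    region = (start, min(start + length, 1000))
    assert relative_position(region, plus) + relative_position(region, minus) == pytest.approx(1.0)


def test_intronless_gene_architecture():
    arch = gene_architecture(_one_tx_gene("+", [(0, 500)]))
    assert arch.intronless and arch.n_introns == 0
    assert arch.mean_intron_length == 0.0 and arch.intron_exon_ratio == 0.0
    assert arch.gene_length == 500


def test_architecture_length_arithmetic():
    arch = gene_architecture(_one_tx_gene("+", [(0, 100), (200, 300)]))
    assert arch.intron_exon_ratio == pytest.approx(0.5)  # 100 intron / 200 exon
    assert arch.mean_intron_length == pytest.approx(100.0)


def test_representative_transcript_maximizes_exonic_content():
    g = GeneModel(
        "g", "c", "+",
        (
            TranscriptModel("b_long", ((0, 100), (200, 400))),  # 300 nt exonic
            TranscriptModel("a_short", ((0, 100),)),            # 100 nt
            TranscriptModel("c_equal", ((0, 300),)),            # 300 nt, later id
        ),
    )
    assert representative_transcript(g).transcript_id == "b_long"
    arch = gene_architecture(g)
    assert arch.mean_intron_length == pytest.approx(100.0)


def test_feature_extraction_does_not_mutate_gene_models(small_bundle):
    from cisplice import cis_features as cf
    from cisplice.event_catalog import build_catalog

    gene = small_bundle.genes[0]
    before = tuple(t.exons for t in gene.transcripts)
    cat = build_catalog([g for g in small_bundle.genes[:50]])
    donor, acceptor = cf.train_pwms(
        small_bundle.genes[:50], small_bundle.accessor(), cat, min_junctions=10
    )
    ev = next(e for e in cat.events if e.pattern == "EC")
    gmap = {g.gene_id: g for g in small_bundle.genes[:50]}
    cf.event_features(ev, gmap[ev.gene_id], small_bundle.accessor(), donor, acceptor)
    assert tuple(t.exons for t in gene.transcripts) == before
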