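import itertools
import math

import numpy as np
import pytest

from regboot.io_formats import GeneRecord, PWM
from regboot.motif_scan import (
    MotifHit,
    genes_with_feature,
    logodds_score,
    promoter_windows,
    reverse_complement,
    scan_promoters,
    score_distribution,
    score_threshold,
)
from conftest import make_informative_pwm


# ------------------------------------------------------------------- windows

def test_promoter_windows_follow_strand():
    genes = [
        GeneRecord("plus", "chr1", 5000, 7000, "+"),
        GeneRecord("minus", "chr1", 3000, 5000, "-"),
    ]
    wins = {w.gene_id: w for w in promoter_windows(genes, {"chr1": 100_000})}
    assert (wins["plus"].start, wins["plus"].end) == (4000, 5000)
    assert (wins["minus"].start, wins["minus"].end) == (5000, 6000)


def test_promoter_windows_truncate_and_skip_empty():
    genes = [
        GeneRecord("near_start", "chr1", 300, 600, "+"),
        GeneRecord("at_start", "chr1", 0, 100, "+"),
    ]
    with pytest.warns(UserWarning, match="at_start"):
        wins = promoter_windows(genes, {"chr1": 100_000})
    assert len(wins) == 1
    assert (wins[0].start, wins[0].end) == (0, 300)


def test_promoter_windows_require_known_chromosome():
    with pytest.raises(KeyError):
        promoter_windows([GeneRecord("g", "chrZ", 10, 20, "+")], {"chr1": 100})


# ------------------------------------------------------------------- scoring

def test_uniform_pwm_scores_zero_everywhere(uniform_pwm):
    for seq in ("ACGT", "TTTT", "GCGC"):
        assert logodds_score(uniform_pwm, seq) == pytest.approx(0.0)


def test_consensus_scores_at_the_maximum(acgt_pwm):
    consensus = acgt_pwm.consensus
    s_max = sum(
        math.log2(acgt_pwm.probs[i].max() / 0.25) for i in range(acgt_pwm.width)
    )
    assert logodds_score(acgt_pwm, consensus) == pytest.approx(s_max)
    # every other sequence scores strictly less
    assert logodds_score(acgt_pwm, "TTTT") < s_max


def test_logodds_matches_bruteforce_arithmetic():
    rng = np.random.default_rng(7)
    probs = rng.dirichlet(np.ones(4), size=6)
    bg = rng.dirichlet(np.ones(4) * 5)
    pwm = PWM(probs=probs, background=bg)
    seq = "".join(rng.choice(list("ACGT"), 6))
    expected = sum(
        math.log2(probs[i, "ACGT".index(b)] / bg["ACGT".index(b)])
        for i, b in enumerate(seq)
    )
    assert logodds_score(pwm, seq) == pytest.approx(expected, abs=1e-12)


def test_n_bases_score_the_position_minimum(acgt_pwm):
    per_pos_min = [
        math.log2(acgt_pwm.probs[0].min() / 0.25)
    ]
    expected = per_pos_min[0] + logodds_score(acgt_pwm, "A" + acgt_pwm.consensus[1:])
    # replacing position 0 of (A + consensus tail) with N swaps in the row min
    n_score = logodds_score(acgt_pwm, "N" + acgt_pwm.consensus[1:])
    a_contrib = math.log2(acgt_pwm.probs[0, 0] / 0.25)
    assert n_score == pytest.approx(expected - a_contrib)


def test_logodds_rejects_wrong_length(acgt_pwm):
    with pytest.raises(ValueError):
        logodds_score(acgt_pwm, "ACG")


# ------------------------------------------------- score distribution DP

def enumeration_distribution(pwm: PWM, grid: float):
    """Brute-force oracle: integer score PMF over all 4^w words."""
    dist = score_distribution(pwm, grid)
    pmf = {}
    for word in itertools.product(range(4), repeat=pwm.width):
        s = int(sum(dist.int_scores[i, b] for i, b in enumerate(word)))
        p = float(np.prod([pwm.background[b] for b in word]))
        pmf[s] = pmf.get(s, 0.0) + p
    return dist, pmf


@pytest.mark.parametrize("width", [2, 4, 6])
@pytest.mark.parametrize("bg", [None, (0.4, 0.1, 0.1, 0.4)])
def test_dp_matches_exhaustive_enumeration(width, bg):
    rng = np.random.default_rng(width)
    probs = rng.dirichlet(np.ones(4) * 0.7, size=width)
    pwm = PWM(probs=probs, background=np.array(bg) if bg else np.full(4, 0.25))
    dist, pmf = enumeration_distribution(pwm, grid=1e-3)
    for s, p in pmf.items():
        assert dist.probs[s - dist.min_int] == pytest.approx(p, abs=1e-12)
    assert dist.probs.sum() == pytest.approx(1.0, abs=1e-12)


def test_alpha_one_returns_minimum_achievable_score(acgt_pwm):
    thr, tail = score_threshold(acgt_pwm, alpha=1.0)
    dist = score_distribution(acgt_pwm, 1e-3)
    min_achievable = (dist.min_int + np.nonzero(dist.probs > 0)[0][0]) * dist.grid
    assert thr == pytest.approx(min_achievable)
    assert tail == pytest.approx(1.0)


def test_alpha_below_best_word_yields_no_hits(acgt_pwm):
    best_word_p = float(np.prod([0.25] * 4))  # most probable single word mass
    thr, tail = score_threshold(acgt_pwm, alpha=best_word_p / 10)
    assert tail == 0.0
    seqs = {"chr1": acgt_pwm.consensus * 50}
    genes = [GeneRecord("g", "chr1", 150, 190, "+")]
    wins = promoter_windows(genes, {"chr1": 200}, window_size=150)
    assert scan_promoters(wins, seqs, acgt_pwm, alpha=best_word_p / 10) == []


def test_threshold_monotone_in_alpha(acgt_pwm):
    alphas = [1e-4, 1e-2, 0.5, 1.0]
    thresholds = [score_threshold(acgt_pwm, a)[0] for a in alphas]
    assert thresholds == sorted(thresholds, reverse=True)


def test_score_threshold_rejects_bad_alpha(acgt_pwm):
    with pytest.raises(ValueError):
        score_threshold(acgt_pwm, 0.0)


# ------------------------------------------------------------------ scanning

def _toy_genome(window_seq: str):
    """One gene whose promoter window is exactly window_seq."""
    n = len(window_seq)
    genes = [GeneRecord("g1", "chr1", n, n + 100, "+")]
    seqs = {"chr1": window_seq + "G" * 100}
    sizes = {"chr1": n + 100}
    wins = promoter_windows(genes, sizes, window_size=n)
    return wins, seqs


def test_planted_consensus_recovered_at_exact_offset():
    pwm = make_informative_pwm("TGAATGAA")
    rng = np.random.default_rng(0)
    bgseq = "".join(rng.choice(list("ACGT"), 300))
    seq = bgseq[:100] + "TGAATGAA" + bgseq[108:300]
    wins, seqs = _toy_genome(seq)
    hits = scan_promoters(wins, seqs, pwm, alpha=1e-4)
    plus = [h for h in hits if h.strand == "+"]
    assert [h.offset for h in plus] == [100]


def test_planted_reverse_complement_hits_minus_strand():
    pwm = make_informative_pwm("TGAATGAA")
    rc = reverse_complement("TGAATGAA")
    rng = np.random.default_rng(1)
    bgseq = "".join(rng.choice(list("ACGT"), 300))
    seq = bgseq[:100] + rc + bgseq[108:300]
    wins, seqs = _toy_genome(seq)
    hits = scan_promoters(wins, seqs, pwm, alpha=1e-4)
    minus = [h for h in hits if h.strand == "-"]
    assert 100 in [h.offset for h in minus]
    best = max(hits, key=lambda h: h.score)
    assert (best.offset, best.strand) == (100, "-")


def test_strand_symmetry_of_scanning():
    """Scanning S with M equals scanning revcomp(S) with M, strands swapped
    and offsets mirrored."""
    pwm = make_informative_pwm("TGCA", certainty=0.9)
    rng = np.random.default_rng(2)
    seq = "".join(rng.choice(list("ACGT"), 200))
    wins, seqs = _toy_genome(seq)
    wins_rc, seqs_rc = _toy_genome(reverse_complement(seq))
    fwd = scan_promoters(wins, seqs, pwm, alpha=0.05)
    rev = scan_promoters(wins_rc, seqs_rc, pwm, alpha=0.05)
    w = pwm.width
    mirrored = sorted(
        (len(seq) - w - h.offset, "+-"[h.strand == "+"], round(h.score, 9)) for h in rev
    )
    original = sorted((h.offset, h.strand, round(h.score, 9)) for h in fwd)
    assert original == mirrored


def test_hit_sets_nest_with_alpha():
    pwm = make_informative_pwm("TGCAGT", certainty=0.8)
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGT"), 500))
    wins, seqs = _toy_genome(seq)
    small = {(h.offset, h.strand) for h in scan_promoters(wins, seqs, pwm, alpha=1e-3)}
    large = {(h.offset, h.strand) for h in scan_promoters(wins, seqs, pwm, alpha=1e-2)}
    assert small <= large


def test_uniform_pwm_alpha_half_hits_about_half_of_positions(uniform_pwm):
    # zero-information motif: every position scores 0, tail mass 1 <= 0.5 is
    # false, so threshold sits at the single achievable score with tail 1.0
    # only when alpha = 1; at alpha = 0.5 no score qualifies
    rng = np.random.default_rng(4)
    seq = "".join(rng.choice(list("ACGT"), 400))
    wins, seqs = _toy_genome(seq)
    all_hits = scan_promoters(wins, seqs, uniform_pwm, alpha=1.0)
    n_positions = (len(seq) - uniform_pwm.width + 1) * 2
    assert len(all_hits) == n_positions  # alpha=1 admits every position
    assert scan_promoters(wins, seqs, uniform_pwm, alpha=0.5) == []


def test_genes_with_feature_set_semantics():
    hits = [
        MotifHit("a", 1, "+", 1.0, 0.1),
        MotifHit("a", 5, "-", 1.0, 0.1),
        MotifHit("b", 2, "+", 1.0, 0.1),
    ]
    assert genes_with_feature(hits) == {"a", "b"}
    assert genes_with_feature([]) == set()


def test_genes_with_feature_matches_naive_grouping():
    rng = np.random.default_rng(5)
    hits = [
        MotifHit(f"g{rng.integers(0, 50)}", int(rng.integers(0, 100)), "+", 0.0, 0.5)
        for _ in range(1000)
    ]
    naive = set()
    for h in hits:
        naive.add(h.gene_id)
    assert genes_with_feature(hits) == naive
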