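"""PFM/PWM scoring, promoter scanning, exact E-values, TF networks."""

import numpy as np
import pytest

import _oracles as oracles
from cncnet.errors import DomainError
from cncnet.regulatory import (PFM, build_tf_lncrna_network,
                               build_ternary_network, pfm_log_odds,
                               revcomp_dna, scan_promoter, site_evalue,
                               tf_target_enrichment)
from cncnet.simulate import informative_pfm, random_seq


def _random_pfm(rng, width):
    counts = rng.integers(1, 50, size=(4, width)).astype(float)
    return PFM(f"TF_r{width}", counts)


def test_uniform_pfm_uniform_background_scores_zero():
    pwm = pfm_log_odds(PFM("U", np.full((4, 6), 10.0)))
    assert np.allclose(pwm.weights, 0.0)


def test_one_hot_limit_approaches_two_bits():
    counts = np.zeros((4, 4))
    counts[0] = 100.0  # all-A columns
    pwm = pfm_log_odds(PFM("H", counts, pseudocount=1e-9))
    assert pwm.weights[0].max() == pytest.approx(2.0, abs=1e-6)


def test_consensus_achieves_matrix_maximum():
    rng = np.random.default_rng(0)
    for width in (4, 6, 10):
        pfm = _random_pfm(rng, width)
        pwm = pfm_log_odds(pfm)
        cons_score = sum(pwm.qweights[:, i].max() for i in range(width))
        scores = oracles.scan_scores_oracle(pwm, pfm.consensus,
                                            both_strands=False)
        assert scores[(0, "+")] == cons_score


def test_pfm_validation():
    with pytest.raises(DomainError):
        PFM("X", np.full((4, 3), 1.0))  # too narrow
    with pytest.raises(DomainError):
        PFM("X", np.array([[1, -1, 1, 1]] * 4, float))
    bad = np.full((4, 5), 1.0)
    bad[:, 2] = 0.0
    with pytest.raises(DomainError):
        PFM("X", bad)


def test_scan_matches_per_position_oracle():
    rng = np.random.default_rng(1)
    for _ in range(50):
        width = int(rng.integers(4, 8))
        pfm = _random_pfm(rng, width)
        pwm = pfm_log_odds(pfm)
        seq = random_seq(rng, 40, "ACGT")
        expected = oracles.scan_scores_oracle(pwm, seq)
        got = {(s.offset, s.strand): int(round(s.score * pwm.scale))
               for s in scan_promoter(pwm, seq)}
        assert got == expected


def test_planted_consensus_is_top_hit():
    rng = np.random.default_rng(2)
    pfm = informative_pfm("T", random_seq(rng, 10, "ACGT"))
    pwm = pfm_log_odds(pfm)
    seq = random_seq(rng, 300, "ACGT")
    seq = seq[:100] + pfm.consensus + seq[110:]
    hits = scan_promoter(pwm, seq)
    best = max(hits, key=lambda h: h.score)
    assert (best.offset, best.strand) == (100, "+")
    assert best.score == pytest.approx(pwm.max_score)


def test_reverse_complement_scan_symmetry():
    rng = np.random.default_rng(3)
    pfm = _random_pfm(rng, 6)
    pwm = pfm_log_odds(pfm)
    seq = random_seq(rng, 60, "ACGT")
    fwd = {(s.offset, s.strand): s.score for s in scan_promoter(pwm, seq)}
    rc = {(s.offset, s.strand): s.score
          for s in scan_promoter(pwm, revcomp_dna(seq))}
    L, w = len(seq), pwm.width
    for (off, strand), score in fwd.items():
        flipped = (L - w - off, "-" if strand == "+" else "+")
        assert rc[flipped] == pytest.approx(score)


@pytest.mark.parametrize("width", [4, 6, 8])
def test_evalue_tail_matches_word_enumeration(width):
    rng = np.random.default_rng(width)
    pfm = _random_pfm(rng, width)
    pwm = pfm_log_odds(pfm)
    qmin = int(pwm.min_score * pwm.scale)
    qmax = int(pwm.max_score * pwm.scale)
    for qt in {qmin, qmax, (qmin + qmax) // 2,
               int(rng.integers(qmin, qmax + 1))}:
        expected = oracles.pwm_tail_enum(pwm, qt)
        got = site_evalue(qt / pwm.scale, pwm, n_positions_scanned=1)
        assert got == pytest.approx(expected, rel=1e-9, abs=1e-15)


def test_evalue_edge_thresholds():
    pwm = pfm_log_odds(informative_pfm("T", "ACGTAC"))
    n = 777
    assert site_evalue(pwm.max_score + 1.0, pwm, n_positions_scanned=n) == 0.0
    assert site_evalue(pwm.min_score, pwm, n_positions_scanned=n) == \
        pytest.approx(n)


def test_complete_bipartite_fixture_and_locality():
    rng = np.random.default_rng(5)
    pfms = [informative_pfm(f"TF_{i}", random_seq(rng, 14, "ACGT"))
            for i in range(3)]
    promoters = {}
    for j in range(5):
        seq = random_seq(rng, 400, "ACGT")
        for i, p in enumerate(pfms):
            off = 30 + 60 * i
            seq = seq[:off] + p.consensus + seq[off + 14:]
        promoters[f"L{j}"] = seq
    net = build_tf_lncrna_network(pfms, promoters, e_max=0.01)
    assert (net.n_tfs, net.n_lncrnas, net.n_edges) == (3, 5, 15)
    assert "3 TFs and 5 correlated lncRNAs" in net.summary
    # removing one TF's PFM removes exactly its edges
    net2 = build_tf_lncrna_network(pfms[1:], promoters, e_max=0.01)
    assert set(net2.edges) == {e for e in net.edges if e[0] != "TF_0"}


def test_tf_target_enrichment_exact_cases():
    overlap, p = tf_target_enrichment(list("abcde"), list("abcde"), 10)
    assert overlap == list("abcde")
    assert p == pytest.approx(1 / 252, rel=1e-12)
    _, p0 = tf_target_enrichment(list("abc"), list("xyz"), 20)
    assert p0 == 1.0
    with pytest.raises(DomainError):
        tf_target_enrichment(["a"], ["a"], 0)


class _Edge:
    def __init__(self, nc, cod, r, q):
        self.nc_id, self.coding_id, self.r, self.q = nc, cod, r, q


def _chain_fixture():
    universe = [f"g{i}" for i in range(50)]
    cnc = [_Edge("L1", g, 0.99, 1e-4) for g in universe[:10]]
    cnc += [_Edge("L2", universe[20], 0.95, 0.01)]
    tf_edges = [("TFA", "L1"), ("TFB", "L2")]
    targets = {"TFA": universe[:10] + universe[40:42],
               "TFB": universe[25:30]}
    return universe, cnc, tf_edges, targets


def test_ternary_planted_chain_recovered_exactly():
    universe, cnc, tf_edges, targets = _chain_fixture()
    net = build_ternary_network(cnc, tf_edges, targets, universe)
    assert net.triples == [("L1", "TFA", f"g{i}") for i in range(10)]
    assert (net.n_lncrnas, net.n_tfs, net.n_genes) == (1, 1, 10)


def test_ternary_conjunction_semantics():
    universe, cnc, tf_edges, targets = _chain_fixture()
    # deleting the CNC edges deletes the triples
    pruned = [e for e in cnc if e.coding_id != "g0"]
    net = build_ternary_network(pruned, tf_edges, targets, universe)
    assert ("L1", "TFA", "g0") not in net.triples
    # deleting the TF-lncRNA edge deletes every triple of that pair
    net2 = build_ternary_network(cnc, [("TFB", "L2")], targets, universe)
    assert net2.triples == []


def test_ternary_threshold_monotonicity():
    universe, cnc, tf_edges, targets = _chain_fixture()
    strict = build_ternary_network(cnc, tf_edges, targets, universe,
                                   r_min=0.95, q_max=1e-3)
    loose = build_ternary_network(cnc, tf_edges, targets, universe,
                                  r_min=0.9, q_max=0.05)
    assert set(strict.triples) <= set(loose.triples)
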