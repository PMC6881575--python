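"""Synthetic-data generator: planted structure, determinism, calibration."""

import numpy as np
import pytest

from cncnet.errors import ConfigurationError
from cncnet.genome import classify_all
from cncnet.regulatory import find_seed_sites, pfm_log_odds, scan_promoter
from cncnet.simulate import (SimConfig, SyntheticTruth, random_seq,
                             simulate_all, simulate_expression,
                             simulate_genome)

SMALL = dict(n_mrna=200, n_lncrna=40, n_circrna=20, frac_de=0.2,
             n_coexpr_pairs=4, n_terms=8, module_size=8)


def test_config_validation():
    with pytest.raises(ConfigurationError):
        SimConfig(n_per_group=1)
    with pytest.raises(ConfigurationError):
        SimConfig(frac_de=1.5)
    with pytest.raises(ConfigurationError):
        SimConfig(noise_sd=0.0)
    with pytest.raises(ConfigurationError):
        SimConfig.from_mapping({"not_a_field": 1})


def test_null_configuration_has_no_planted_structure():
    m, truth = simulate_expression(SimConfig(seed=1, frac_de=0.0, **{
        k: v for k, v in SMALL.items() if k != "frac_de"}))
    assert truth.de_ids_up == set() and truth.de_ids_down == set()
    assert truth.coexpr_pairs == set()
    # no group effect: log-ratios scatter around zero
    log_ratio = np.log2(m.group_values("case").mean(1)
                        / m.group_values("control").mean(1))
    assert abs(log_ratio.mean()) < 0.05


def test_zero_noise_limit_ratio_is_four():
    cfg = SimConfig(seed=2, noise_sd=1e-6, **SMALL)
    m, truth = simulate_expression(cfg)
    ratios = m.group_values("case").mean(1) / m.group_values("control").mean(1)
    ids = list(m.values.index)
    for pid in truth.de_ids_up:
        assert ratios[ids.index(pid)] == pytest.approx(4.0, rel=1e-3)
    for pid in truth.de_ids_down:
        assert ratios[ids.index(pid)] == pytest.approx(0.25, rel=1e-3)


def test_all_values_positive_and_groups_labeled(small_bundle):
    m = small_bundle.matrix
    assert (m.values.to_numpy() > 0).all()
    assert sorted(m.groups.unique()) == ["case", "control"]
    assert len(m.samples_in("control")) == len(m.samples_in("case")) == 3


def test_determinism_identical_outputs():
    a = simulate_all(SimConfig(seed=9, **SMALL))
    b = simulate_all(SimConfig(seed=9, **SMALL))
    assert a.matrix.values.equals(b.matrix.values)
    assert a.truth.to_jsonable() == b.truth.to_jsonable()
    assert a.sequences.mrna_utr == b.sequences.mrna_utr
    assert a.promoters == b.promoters
    assert [p.counts.tolist() for p in a.pfms] == \
        [p.counts.tolist() for p in b.pfms]
    c = simulate_all(SimConfig(seed=10, **SMALL))
    assert not a.matrix.values.equals(c.matrix.values)


def test_truth_referential_integrity(small_bundle):
    tr = small_bundle.truth
    probe_ids = set(small_bundle.matrix.values.index)
    assert (tr.de_ids_up | tr.de_ids_down) <= probe_ids
    for nc, cod, sign in tr.coexpr_pairs:
        assert {nc, cod} <= probe_ids and sign in ("positive", "negative")
    record_ids = {r.id for r in small_bundle.transcripts}
    assert probe_ids == record_ids
    for l, g, d in tr.cis_pairs:
        assert 0 <= d < 300_000 and {l, g} <= record_ids


def test_genome_exemplars_cover_all_six_categories(small_bundle):
    tr = small_bundle.truth
    planted = set().union(*tr.category_by_lncrna.values())
    assert planted == {"exon_overlapping", "intron_overlapping",
                       "natural_antisense", "intron_antisense",
                       "bidirectional", "intergenic"}
    # the multi-label crossover exemplar carries two labels
    assert any(len(v) == 2 for v in tr.category_by_lncrna.values())


def test_genome_truth_matches_classifier(small_bundle):
    lncs = [r for r in small_bundle.transcripts if r.rna_type == "lncRNA"]
    coding = [r for r in small_bundle.transcripts if r.rna_type == "mRNA"]
    summary = classify_all(lncs, coding)
    by_id = {c.lncrna_id: set(c.labels) for c in summary.calls}
    for lnc_id, labels in small_bundle.truth.category_by_lncrna.items():
        assert by_id[lnc_id] == labels


def test_cis_window_plants(small_bundle):
    tr = small_bundle.truth
    assert any(d == 295_000 for (_, _, d) in tr.cis_pairs)
    assert any(d == 305_000 for (_, _, d) in tr.noncis_pairs)


def test_genome_too_small_raises():
    with pytest.raises(ConfigurationError):
        simulate_genome(SimConfig(seed=1, genome_length_bp=100_000,
                                  n_chromosomes=1, **SMALL))


def test_sequences_alphabets(small_bundle):
    seqs = small_bundle.sequences
    rna = set("ACGU")
    for d in (seqs.mrna_utr, seqs.lncrna, seqs.circrna, seqs.mirna):
        assert all(set(s) <= rna for s in d.values())
    assert all(set(s) <= set("ACGT")
               for s in small_bundle.promoters.values())


def test_planted_seed_sites_recovered(small_bundle):
    seqs = small_bundle.sequences
    for (mir, tid, off, stype) in small_bundle.truth.seed_sites:
        if tid in seqs.lncrna:
            seq, circ = seqs.lncrna[tid], False
        elif tid in seqs.circrna:
            seq, circ = seqs.circrna[tid], True
        else:
            seq, circ = seqs.mrna_utr[tid], False
        found = {(s.offset, s.site_type)
                 for s in find_seed_sites(seqs.mirna[mir], seq, circ)}
        assert (off, stype) in found


def test_cerna_module_has_junction_site(small_bundle):
    tr = small_bundle.truth
    circ = tr.cerna_module["circrna"]
    L = len(small_bundle.sequences.circrna[circ])
    (site,) = [(o, t) for (m, h, o, t) in tr.seed_sites if h == circ]
    assert site[0] + 7 > L  # straddles the back-splice junction


def test_planted_motifs_score_maximal(small_bundle):
    by_name = {p.tf_name: p for p in small_bundle.pfms}
    for (tf, lnc, off, strand) in small_bundle.truth.motif_sites:
        pwm = pfm_log_odds(by_name[tf])
        hits = scan_promoter(pwm, small_bundle.promoters[lnc])
        best = max(hits, key=lambda h: h.score)
        assert (best.offset, best.strand) == (off, strand)
        assert best.score == pytest.approx(pwm.max_score)


def test_planted_term_is_overrepresented(small_bundle):
    tr = small_bundle.truth
    table = small_bundle.term_table
    members = set(table[table.term_id == tr.enriched_term].gene_id)
    de = tr.de_ids_up | tr.de_ids_down
    assert len(members & de) >= 10  # most of the planted term's genes are DE


def test_spurious_8mer_rate_matches_uniform_model():
    """Background 8mer count per sequence ~ (L-7) / 4^8 under the uniform
    base model (checked over 100 seeds x 50 sequences)."""
    L = 500
    count, n_seq = 0, 0
    for seed in range(100):
        rng = np.random.default_rng([11, seed])
        mir = random_seq(rng, 22)
        for _ in range(50):
            s = random_seq(rng, L)
            count += sum(1 for x in find_seed_sites(mir, s)
                         if x.site_type == "8mer")
            n_seq += 1
    expected = (L - 7) * 0.25 ** 8 * n_seq
    assert abs(count - expected) <= 3.5 * np.sqrt(expected)


def test_truth_json_roundtrip(small_bundle):
    tr = small_bundle.truth
    back = SyntheticTruth.from_jsonable(tr.to_jsonable())
    assert back.to_jsonable() == tr.to_jsonable()
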