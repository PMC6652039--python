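"""Similarity coefficients, consensus screening, clustering (against a
hand-rolled agglomerative oracle), representatives and composition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenostack.screening import (
    ScreeningHit,
    cluster_hits,
    composition_summary,
    dice,
    nearest_active,
    screen,
    select_representatives,
    tanimoto,
)
from phenostack.synthetic_data import generate_screening_library


def _vec(bits, n=8):
    v = np.zeros(n, dtype=int)
    v[list(bits)] = 1
    return v


class TestSimilarity:
    def test_tanimoto_known_values(self):
        assert tanimoto(_vec({1, 2, 3}), _vec({1, 2, 3})) == 1.0
        assert tanimoto(_vec({0, 1}), _vec({2, 3})) == 0.0
        assert tanimoto(_vec({1, 2, 3}), _vec({2, 3, 4})) == 0.5
        assert tanimoto(_vec(set()), _vec(set())) == 1.0

    def test_dice_known_values(self):
        assert dice(_vec({1, 2, 3}), _vec({1, 2, 3})) == 1.0
        assert dice(_vec({0, 1}), _vec({2, 3})) == 0.0
        assert dice(_vec({1, 2, 3}), _vec({2, 3, 4})) == pytest.approx(4 / 6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            tanimoto(np.zeros(4), np.zeros(5))
        with pytest.raises(ValueError):
            dice(np.zeros(4), np.zeros(5))

    @given(st.lists(st.booleans(), min_size=1, max_size=24), st.data())
    @settings(derandomize=True, max_examples=100)
    def test_dice_dominates_tanimoto(self, a_bits, data):
        b_bits = data.draw(st.lists(st.booleans(), min_size=len(a_bits),
                                    max_size=len(a_bits)))
        a, b = np.array(a_bits, int), np.array(b_bits, int)
        t, d = tanimoto(a, b), dice(a, b)
        assert d >= t - 1e-12
        inter = np.logical_and(a, b).sum()
        if np.array_equal(a, b) or inter == 0:
            assert d == pytest.approx(t)
        elif t < 1.0:
            assert d > t


class TestScreen:
    def test_consensus_is_intersection_and_bounded(self, perfect_signal_models):
        m_nin, m_nhn, nin_cfg, nhn_cfg = perfect_signal_models
        lib, _ = generate_screening_library(nin_cfg, nhn_cfg,
                                            n_compounds=120, seed=7)
        hits = screen(lib, m_nin, m_nhn)
        n_nin = sum(h.predicted_nin for h in hits)
        n_nhn = sum(h.predicted_nhn for h in hits)
        n_cons = sum(h.consensus for h in hits)
        assert n_cons <= min(n_nin, n_nhn)
        for h in hits:
            assert h.consensus == bool(h.predicted_nin and h.predicted_nhn)

    def test_order_invariance(self, perfect_signal_models):
        m_nin, m_nhn, nin_cfg, nhn_cfg = perfect_signal_models
        lib, _ = generate_screening_library(nin_cfg, nhn_cfg,
                                            n_compounds=60, seed=9)
        h1 = {h.compound_id: h.est_p_good_nin for h in screen(lib, m_nin, m_nhn)}
        h2 = {h.compound_id: h.est_p_good_nin
              for h in screen(list(reversed(lib)), m_nin, m_nhn)}
        assert h1 == h2

    def test_dice_reported_against_nearest_training_active(self,
                                                           perfect_signal_models):
        m_nin, m_nhn, nin_cfg, nhn_cfg = perfect_signal_models
        lib, _ = generate_screening_library(nin_cfg, nhn_cfg,
                                            n_compounds=30, seed=11)
        hits = screen(lib, m_nin, m_nhn)
        actives = {r.id: r for r in (m_nin.training_actives
                                     + m_nhn.training_actives)}.values()
        for h, rec in zip(hits, lib):
            best, best_id = nearest_active(rec.fingerprint, list(actives))
            assert h.dice_to_nearest_active == pytest.approx(best)
            assert h.nearest_active_id == best_id


def _mk_hits(fps, ests=None):
    hits = []
    for i, fp in enumerate(fps):
        e = 0.5 if ests is None else ests[i]
        hits.append(ScreeningHit(
            compound_id=f"h{i:02d}", herb=None, est_p_good_nin=e,
            est_p_good_nhn=e, predicted_nin=1, predicted_nhn=1,
            consensus=True))
    return hits


def _brute_force_average_linkage(fps, k):
    """O(n^3) agglomerative clustering on jaccard distance."""
    def jac(a, b):
        union = np.logical_or(a, b).sum()
        return 0.0 if union == 0 else 1 - np.logical_and(a, b).sum() / union

    clusters = [[i] for i in range(len(fps))]
    while len(clusters) > k:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean([jac(fps[a], fps[b])
                             for a in clusters[i] for b in clusters[j]])
                if best is None or d < best[0]:
                    best = (d, i, j)
        _, i, j = best
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return clusters


class TestClusterHits:
    def test_two_planted_chemotypes_recovered_exactly(self):
        rng = np.random.default_rng(4)
        fps, truth = [], []
        for i in range(20):
            fp = (rng.random(64) < 0.03).astype(int)
            if i < 10:
                fp[0:8] = 1
                truth.append(0)
            else:
                fp[32:40] = 1
                truth.append(1)
            fps.append(fp)
        hits = _mk_hits(fps)
        assignment = cluster_hits(hits, {h.compound_id: fp
                                         for h, fp in zip(hits, fps)}, k=2)
        labels = [assignment[f"h{i:02d}"] for i in range(20)]
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_k_equal_n_gives_singletons(self):
        fps = [_vec({i}, 8) for i in range(4)]
        hits = _mk_hits(fps)
        assignment = cluster_hits(hits, {h.compound_id: fp
                                         for h, fp in zip(hits, fps)}, k=4)
        assert sorted(assignment.values()) == [1, 2, 3, 4]

    def test_partition_into_exactly_k(self):
        rng = np.random.default_rng(8)
        fps = [(rng.random(32) < 0.3).astype(int) for _ in range(12)]
        hits = _mk_hits(fps)
        cluster_hits(hits, {h.compound_id: fp for h, fp in zip(hits, fps)}, 3)
        assert len({h.cluster_id for h in hits}) == 3
        assert all(h.cluster_id is not None for h in hits)

    def test_fewer_hits_than_k_rejected(self):
        fps = [_vec({0}), _vec({1})]
        hits = _mk_hits(fps)
        with pytest.raises(ValueError):
            cluster_hits(hits, {h.compound_id: fp
                                for h, fp in zip(hits, fps)}, k=3)

    def test_matches_brute_force_agglomeration(self):
        rng = np.random.default_rng(21)
        fps = [(rng.random(40) < 0.25).astype(int) for _ in range(9)]
        hits = _mk_hits(fps)
        assignment = cluster_hits(hits, {h.compound_id: fp
                                         for h, fp in zip(hits, fps)}, k=3)
        oracle = _brute_force_average_linkage(fps, 3)
        oracle_sets = {frozenset(f"h{i:02d}" for i in c) for c in oracle}
        mine = {}
        for cid, cl in assignment.items():
            mine.setdefault(cl, set()).add(cid)
        assert {frozenset(s) for s in mine.values()} == oracle_sets


class TestRepresentatives:
    def test_counts_and_dominance(self):
        rng = np.random.default_rng(3)
        fps = [(rng.random(32) < 0.3).astype(int) for _ in range(10)]
        ests = list(rng.random(10))
        ests[4] = 1.0   # dominant in whatever cluster it lands
        hits = _mk_hits(fps, ests)
        cluster_hits(hits, {h.compound_id: fp for h, fp in zip(hits, fps)}, 5)
        reps = select_representatives(hits, n_per_cluster=1)
        assert len(reps) == 5
        assert "h04" in reps

    def test_matches_per_cluster_argmax(self):
        rng = np.random.default_rng(13)
        fps = [(rng.random(32) < 0.3).astype(int) for _ in range(12)]
        ests = list(rng.random(12))
        hits = _mk_hits(fps, ests)
        cluster_hits(hits, {h.compound_id: fp for h, fp in zip(hits, fps)}, 4)
        reps = select_representatives(hits, n_per_cluster=1)
        by_cluster = {}
        for h in hits:
            cur = by_cluster.get(h.cluster_id)
            if cur is None or (h.est_p_good_nin + h.est_p_good_nhn >
                               cur.est_p_good_nin + cur.est_p_good_nhn):
                by_cluster[h.cluster_id] = h
        assert sorted(reps) == sorted(h.compound_id
                                      for h in by_cluster.values())

    def test_unclustered_hits_rejected(self):
        hits = _mk_hits([_vec({0}), _vec({1})])
        with pytest.raises(ValueError, match="clustered"):
            select_representatives(hits)


class TestComposition:
    def test_single_herb_all_consensus(self):
        hits = _mk_hits([_vec({0})] * 3)
        for h in hits:
            h.herb = "renshen"
        df = composition_summary(hits)
        assert df.loc["renshen", "frac_both"] == 1.0

    def test_fractions_sum_to_one_and_match_tally(self):
        rng = np.random.default_rng(6)
        hits = []
        herbs = ["a", "b", "c"]
        for i in range(60):
            pn, ph = int(rng.random() < 0.5), int(rng.random() < 0.5)
            hits.append(ScreeningHit(
                compound_id=f"x{i}", herb=herbs[i % 3],
                est_p_good_nin=0.5, est_p_good_nhn=0.5,
                predicted_nin=pn, predicted_nhn=ph,
                consensus=bool(pn and ph)))
        df = composition_summary(hits)
        frac_cols = [c for c in df.columns if c.startswith("frac_")]
        np.testing.assert_allclose(df[frac_cols].sum(axis=1), 1.0)
        # brute-force tally for one herb/category
        n_both_a = sum(1 for h in hits
                       if h.herb == "a" and h.predicted_nin and h.predicted_nhn)
        assert df.loc["a", "both"] == n_both_a

    def test_untagged_compounds_grouped(self):
        hits = _mk_hits([_vec({0})])
        df = composition_summary(hits)
        assert "untagged" in df.index
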