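import numpy as np
import pytest

from phosflow.psea import (
    RankedSites,
    ZeroOverlapError,
    enrichment_score,
    psea,
    psea_row_null,
    rank_sites,
    ranked_from_scores,
)
from phosflow.simulate import SimConfig, simulate_kinase_scores


def ks_running_sum_oracle(site_ids, member_set, weight, scores):
    """Independent step-by-step running-sum computation."""
    hits = [s in member_set for s in site_ids]
    nh = sum(hits)
    L = len(site_ids)
    hit_weights = [abs(sc) ** weight for sc, h in zip(scores, hits) if h]
    total = sum(hit_weights)
    running, value, hi = [], 0.0, 0
    for s, sc, h in zip(site_ids, scores, hits):
        if h:
            value += (abs(sc) ** weight / total) if total > 0 else 1.0 / nh
            hi += 1
        else:
            value -= 1.0 / (L - nh)
        running.append(value)
    es = max(running, key=abs)
    return es, running


class TestRankSites:
    def test_median_over_redundant_peptides(self):
        ranked = rank_sites(
            {"p1": 1.0, "p2": 2.0, "p3": 3.0, "q1": -1.0, "q2": 0.0},
            {"p1": "A:S1", "p2": "A:S1", "p3": "A:S1",
             "q1": "B:S2", "q2": "B:S2"})
        # site A median 2, site B median -0.5 -> A ranks first
        assert list(ranked.site_ids) == ["A:S1", "B:S2"]

    def test_all_equal_scores_lexicographic(self):
        ranked = rank_sites({"a": 1.0, "b": 1.0, "c": 1.0},
                            {"a": "Z:S1", "b": "A:S1", "c": "M:S1"})
        assert list(ranked.site_ids) == ["A:S1", "M:S1", "Z:S1"]
        np.testing.assert_array_equal(ranked.scores, 0.0)

    def test_zscore_properties(self, rng):
        values = {f"p{i}": float(v)
                  for i, v in enumerate(rng.normal(0, 2, 100))}
        site_map = {f"p{i}": f"G{i}:S1" for i in range(100)}
        ranked = rank_sites(values, site_map)
        assert ranked.scores.mean() == pytest.approx(0.0, abs=1e-12)
        assert ranked.scores.std() == pytest.approx(1.0, abs=1e-12)


class TestEnrichmentScore:
    def test_unweighted_hand_example(self):
        ranked = RankedSites(np.array(["a", "b", "c"], dtype=object),
                             np.array([1.0, 0.0, -1.0]))
        es, running = enrichment_score(ranked, {"a"}, weight=0.0)
        np.testing.assert_allclose(running, [1.0, 0.5, 0.0])
        assert es == 1.0

    def test_full_list_membership_gives_one(self):
        ranked = ranked_from_scores({f"s{i}": float(i) for i in range(10)})
        es, _ = enrichment_score(ranked, set(ranked.site_ids))
        assert es == pytest.approx(1.0)

    def test_zero_overlap_raises(self):
        ranked = ranked_from_scores({"a": 1.0, "b": -1.0, "c": 0.5})
        with pytest.raises(ZeroOverlapError):
            enrichment_score(ranked, {"zzz"})

    def test_matches_oracle_and_bounded(self, rng):
        for _ in range(200):
            L = int(rng.integers(5, 40))
            scores = np.sort(rng.normal(0, 1, L))[::-1]
            ids = np.array([f"s{i}" for i in range(L)], dtype=object)
            ranked = RankedSites(ids, scores)
            members = set(rng.choice(ids, size=int(rng.integers(1, L)),
                                     replace=False))
            for weight in (0.0, 0.75):
                es, running = enrichment_score(ranked, members, weight)
                oes, orun = ks_running_sum_oracle(ids, members, weight,
                                                 scores)
                assert es == pytest.approx(oes, abs=1e-12)
                np.testing.assert_allclose(running, orun, atol=1e-12)
                assert abs(es) <= 1.0 + 1e-12

    def test_score_negation_flips_es(self, rng):
        scores = np.sort(rng.normal(0, 1, 30))[::-1]
        ids = np.array([f"s{i}" for i in range(30)], dtype=object)
        members = set(rng.choice(ids, 8, replace=False))
        es, _ = enrichment_score(RankedSites(ids, scores), members)
        neg = RankedSites(ids[::-1], -scores[::-1])
        es_neg, _ = enrichment_score(neg, members)
        assert es_neg == pytest.approx(-es, abs=1e-12)


class TestPsea:
    def test_small_set_excluded_with_reason(self):
        scores, sets, _ = simulate_kinase_scores(
            SimConfig(seed=1, kinase_plant=(19, 1.0)))
        ranked = ranked_from_scores(scores)
        results, excluded = psea(ranked, {"SMALL":
                                          sets["PLANTED_KINASE"]},
                                 nperm=10, min_size=20, seed=0)
        assert excluded["SMALL"] == "below minimum overlap"
        assert results == []

    def test_planted_activation_detected(self):
        scores, sets, ledger = simulate_kinase_scores(SimConfig(seed=6))
        ranked = ranked_from_scores(scores)
        results, _ = psea(ranked, sets, nperm=1000, seed=0)
        planted = {r.set_name: r for r in results}["PLANTED_KINASE"]
        assert planted.nes > 0
        assert planted.p_value <= 0.05
        # planted set ranks first by NES
        assert max(results, key=lambda r: r.nes).set_name \
            == "PLANTED_KINASE"

    def test_negative_shift_gives_negative_nes(self):
        scores, sets, _ = simulate_kinase_scores(
            SimConfig(seed=6, kinase_plant=(40, -1.5)))
        ranked = ranked_from_scores(scores)
        results, _ = psea(ranked, sets, nperm=200, seed=0)
        planted = {r.set_name: r for r in results}["PLANTED_KINASE"]
        assert planted.nes < 0

    def test_p_value_bounds_and_reproducibility(self):
        scores, sets, _ = simulate_kinase_scores(SimConfig(seed=9))
        ranked = ranked_from_scores(scores)
        r1, _ = psea(ranked, sets, nperm=100, seed=42)
        r2, _ = psea(ranked, sets, nperm=100, seed=42)
        for a, b in zip(r1, r2):
            assert (a.es, a.nes, a.p_value, a.q_value) \
                == (b.es, b.nes, b.p_value, b.q_value)
            assert 1 / 101 <= a.p_value <= 1.0
            assert 0.0 <= a.q_value <= 1.0

    def test_nperm_validated(self):
        ranked = ranked_from_scores({f"s{i}": float(i) for i in range(30)})
        with pytest.raises(ValueError, match="nperm"):
            psea(ranked, {"K": frozenset(ranked.site_ids[:25])}, nperm=0)

    def test_row_null_mode_agrees_on_direction(self):
        scores, sets, _ = simulate_kinase_scores(SimConfig(seed=13))
        peptide_fc = {f"pep{i}": v for i, (s, v) in
                      enumerate(sorted(scores.items()))}
        site_map = {f"pep{i}": s for i, (s, v) in
                    enumerate(sorted(scores.items()))}
        results, _ = psea_row_null(peptide_fc, site_map, sets, nperm=100,
                                   seed=0)
        planted = {r.set_name: r for r in results}["PLANTED_KINASE"]
        assert planted.nes > 0 and planted.p_value <= 0.05
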