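"""Pairwise similarity: coverage x identity scores against a DP oracle."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from pellicle.similarity import (AlignParams, SimilarityError, align_proteins,
                                 best_hit, cluster_similarity, local_score)
from pellicle.synthetic_data import diverge_protein

from _oracles import sw_score

AAS = "ACDEFGHIKLMNPQRSTVWY"


def _random_protein(rng, n):
    return "".join(rng.choice(AAS) for _ in range(n))


def test_identical_sequences_score_100():
    seq = _random_protein(random.Random(0), 50)
    res = align_proteins(seq, seq)
    assert res.pid == 100.0
    assert res.qcov == 100.0
    assert res.score == 100.0
    assert res.identities == 50


def test_unalignable_pair_scores_zero():
    res = align_proteins("AAAA", "WWWW")
    assert res.score == 0.0
    assert res.identities == 0


def test_empty_or_invalid_sequences_rejected():
    with pytest.raises(SimilarityError):
        align_proteins("", "MKV")
    with pytest.raises(SimilarityError):
        align_proteins("MKV", "MK1V")


def test_optimal_score_matches_dp_oracle():
    """50 random pairs (lengths <= 40): implementation == quadratic DP."""
    rng = random.Random(1234)
    for _ in range(50):
        a = _random_protein(rng, rng.randint(10, 40))
        b = _random_protein(rng, rng.randint(10, 40))
        assert local_score(a, b) == sw_score(a, b)


def test_identity_counts_on_unambiguous_constructions():
    # a unique exact substring alignment: identities are forced
    core = "WWCHHMYFW"
    res = align_proteins(core, "AAAA" + core + "SSS")
    assert res.identities == len(core)
    assert res.qcov == 100.0


class TestBestHit:
    def test_exact_copy_beats_diverged_copy(self):
        seq = _random_protein(random.Random(2), 80)
        div = diverge_protein(seq, 60, seed=3)
        res = best_hit(seq, {"exact": seq, "diverged": div})
        assert res.subject_id == "exact"
        assert res.score == 100.0

    def test_all_zero_subjects_returns_zero_not_error(self):
        res = best_hit("AAAAAAA", {"w1": "WWWWWWW", "w2": "WWWWWWW"})
        assert res.score == 0.0

    def test_best_matches_exhaustive_per_pair_maximum(self):
        rng = random.Random(7)
        seq = _random_protein(rng, 120)
        subjects = {
            f"id{ident}": diverge_protein(seq, ident, seed=ident)
            for ident in range(10, 100, 10)
        }
        res = best_hit(seq, subjects)
        one_by_one = {
            sid: align_proteins(seq, s, subject_id=sid).score
            for sid, s in subjects.items()
        }
        assert res.score == max(one_by_one.values())
        assert res.subject_id == max(one_by_one, key=one_by_one.get)

    def test_empty_subject_list_rejected(self):
        with pytest.raises(SimilarityError):
            best_hit("MKV", {})


class TestClusterSimilarity:
    def test_identical_sets_shuffled_order(self):
        rng = random.Random(9)
        genes = {f"g{i}": _random_protein(rng, 60 + i) for i in range(5)}
        shuffled = dict(reversed(list(genes.items())))
        sim = cluster_similarity(genes, shuffled)
        assert sim.mean_best_hit_score == 100.0
        assert sim.reciprocal_fraction == 1.0

    def test_disjoint_unrelated_sets_near_zero(self):
        rng = random.Random(10)
        a = {f"a{i}": _random_protein(rng, 100) for i in range(4)}
        b = {f"b{i}": _random_protein(rng, 100) for i in range(4)}
        sim = cluster_similarity(a, b)
        assert sim.mean_best_hit_score < 10.0

    def test_weighted_mean_matches_hand_computation(self):
        rng = random.Random(11)
        a = {f"g{i}": _random_protein(rng, 80 + 10 * i) for i in range(4)}
        b = dict(a)
        b["g2"] = _random_protein(rng, 100)  # one gene replaced, known length
        sim = cluster_similarity(a, b)
        per_gene = {
            gid: max(align_proteins(seq, s).score for s in b.values())
            for gid, seq in a.items()
        }
        expected = (sum(len(a[g]) * per_gene[g] for g in a)
                    / sum(len(s) for s in a.values()))
        assert sim.mean_best_hit_score == pytest.approx(expected)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.text(alphabet=AAS, min_size=1, max_size=60))
def test_self_score_is_always_100(seq):
    assert align_proteins(seq, seq).score == pytest.approx(100.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.text(alphabet=AAS, min_size=5, max_size=50),
       st.text(alphabet=AAS, min_size=5, max_size=50))
def test_score_bounded_by_pid_and_qcov(a, b):
    res = align_proteins(a, b)
    assert 0.0 <= res.score <= min(res.pid, res.qcov) + 1e-9
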