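"""Genotype criteria, label minting, and the single-edit semantics."""

import copy

import pytest

from pellicle.genotyper import (GenotypeDB, GenotypeError, GenotypeProfile,
                                assign_cwps_genotype, assign_eps_genotype,
                                default_cwps_db, int_to_roman, mint_label,
                                roman_to_int)
from pellicle.locus_finder import find_locus
from pellicle.role_inference import assign_roles, psp_gene_calls
from pellicle.similarity import best_hit
from pellicle.synthetic_data import (StrainSpec, diverge_protein,
                                     generate_strain)


@pytest.fixture(scope="module")
def typed_f(refdb, align_params):
    spec = StrainSpec(strain_id="GT1", cwps_template="F", eps_template=None, seed=41)
    genome, _ = generate_strain(spec)
    locus = find_locus(genome, "cwps")[0]
    return assign_roles(locus, refdb, params=align_params)


@pytest.fixture()
def db_with_f(typed_f, align_params):
    """Profile db where the F-like locus has minted profile 'E' (first novel
    label after the historical A-D)."""
    db = default_cwps_db()
    call = assign_cwps_genotype(typed_f, db, params=align_params)
    assert call.is_novel
    return db, call.label


class TestMintLabel:
    def test_continues_letter_series(self):
        assert mint_label(default_cwps_db(), "cwps") == "E"

    def test_empty_dbs(self):
        assert mint_label(GenotypeDB(), "cwps") == "A"
        assert mint_label(GenotypeDB(), "eps") == "I"

    def test_roman_successor(self):
        db = GenotypeDB(profiles=[GenotypeProfile(int_to_roman(i), "eps")
                                  for i in range(1, 12)])
        assert mint_label(db, "eps") == "XII"

    @pytest.mark.parametrize("n", [1, 4, 9, 11, 14, 40, 1987])
    def test_roman_round_trip(self, n):
        assert roman_to_int(int_to_roman(n)) == n

    def test_letters_past_z(self):
        db = GenotypeDB(profiles=[GenotypeProfile("Z", "cwps")])
        assert mint_label(db, "cwps") == "AA"


class TestCwpsCriteria:
    def test_identity_match(self, typed_f, db_with_f, align_params):
        db, label = db_with_f
        call = assign_cwps_genotype(typed_f, db, params=align_params)
        assert not call.is_novel
        assert call.matched_profile == label
        assert call.mean_similarity == pytest.approx(100.0)
        assert label not in call.criteria_fired

    def test_flippase_deletion_fires_criterion_ii(self, typed_f, db_with_f, align_params):
        db, label = db_with_f
        edited = copy.deepcopy(typed_f)
        edited.roles = [c for c in edited.roles if c.role != "flippase"]
        edited.region.genes = [c.gene for c in edited.roles]
        call = assign_cwps_genotype(edited, db, params=align_params, mint=False)
        assert call.is_novel
        assert "ii" in call.criteria_fired[label]
        # every profile is rejected by at least one criterion
        assert all(call.criteria_fired[p.label] for p in db.profiles)

    def test_two_diverged_psp_genes_fire_criterion_iii(self, typed_f, db_with_f, align_params):
        db, label = db_with_f
        profile = next(p for p in db.profiles if p.label == label)
        edited = copy.deepcopy(typed_f)
        for call in psp_gene_calls(edited)[:2]:
            call.gene.protein = diverge_protein(call.gene.protein, 12, seed=77)
            # post-hoc verification that the edit really crosses the boundary
            hit = best_hit(call.gene.protein, profile.psp_exemplars, align_params)
            assert hit.score < 30.0
        out = assign_cwps_genotype(edited, db, params=align_params, mint=False)
        assert out.is_novel
        assert "iii" in out.criteria_fired[label]

    def test_one_diverged_psp_gene_does_not(self, typed_f, db_with_f, align_params):
        db, label = db_with_f
        edited = copy.deepcopy(typed_f)
        call = psp_gene_calls(edited)[0]
        call.gene.protein = diverge_protein(call.gene.protein, 12, seed=78)
        out = assign_cwps_genotype(edited, db, params=align_params, mint=False)
        assert not out.is_novel
        assert out.matched_profile == label

    def test_threshold_monotonicity(self, typed_f, db_with_f, align_params):
        """Lowering the criterion-iii threshold never breaks a match."""
        db, label = db_with_f
        for threshold in (30.0, 20.0, 10.0, 1.0):
            call = assign_cwps_genotype(typed_f, db, sim_threshold=threshold,
                                        params=align_params, mint=False)
            assert not call.is_novel

    def test_missing_role_calls_rejected(self):
        class NoRoles:
            roles = []
        with pytest.raises(GenotypeError):
            assign_cwps_genotype(NoRoles(), default_cwps_db())


@pytest.fixture(scope="module")
def typed_eps(refdb, align_params):
    spec = StrainSpec(strain_id="GE1", cwps_template=None, eps_template="VI",
                      seed=43, implant_island=False)
    genome, _ = generate_strain(spec)
    locus = find_locus(genome, "eps")[0]
    return assign_roles(locus, refdb, params=align_params)


class TestEpsGenotyping:
    def test_identity_match(self, typed_eps, align_params):
        db = GenotypeDB(next_label_rule="roman")
        first = assign_eps_genotype(typed_eps, db, params=align_params)
        assert first.is_novel and first.label == "I"
        again = assign_eps_genotype(typed_eps, db, params=align_params)
        assert not again.is_novel
        assert again.matched_profile == "I"

    def test_pathway_mismatch_forces_novel(self, typed_eps, align_params):
        db = GenotypeDB(next_label_rule="roman")
        assign_eps_genotype(typed_eps, db, params=align_params)
        mismatched = copy.deepcopy(typed_eps)
        mismatched.pathway_class = "abc_transporter"
        call = assign_eps_genotype(mismatched, db, params=align_params, mint=False)
        assert call.is_novel
        assert "pathway" in call.criteria_fired["I"]
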