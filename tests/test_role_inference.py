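"""Per-gene role assignment, eps pathway classing, positional rules."""

import copy
import random

import pytest

from pellicle.genome_io import Contig, GeneFeature, Genome
from pellicle.locus_finder import LocusRegion, find_locus
from pellicle.role_inference import (RoleCall, TypedLocus, assign_roles,
                                     classify_eps_pathway,
                                     positional_disambiguation)
from pellicle.synthetic_data import StrainSpec, generate_strain

from conftest import random_protein
from test_topology import k_helix_protein


def _locus_of(genes):
    return LocusRegion(genome_id="g", kind="cwps",
                       fragments=[("c1", genes[0].start, genes[-1].end)],
                       genes=genes)


def _gene(tag, product, protein, start):
    return GeneFeature(contig_id="c1", start=start, end=start + 3 * (len(protein) + 1) - 1,
                       strand="+", locus_tag=tag, product=product, protein=protein)


def test_keyword_route(refdb, align_params):
    rng = random.Random(0)
    gene = _gene("kw1", "dTDP-glucose 4,6-dehydratase", random_protein(rng, 120), 10)
    typed = assign_roles(_locus_of([gene]), refdb, params=align_params)
    # the random protein has no similarity hit; the keyword decides
    assert typed.roles[0].role == "precursor_rmlB"
    assert typed.roles[0].evidence in ("keyword", "similarity")


def test_hypothetical_13tmh_protein_called_flippase(refdb, align_params):
    gene = _gene("hy1", "hypothetical protein", k_helix_protein(13), 10)
    typed = assign_roles(_locus_of([gene]), refdb, params=align_params)
    call = typed.roles[0]
    assert call.role == "flippase"
    assert call.evidence == "topology"
    assert call.score is None


def test_role_recovery_on_diverged_implants(refdb, align_params):
    """Implants diverged to 60% identity: >= 95% of roles recovered."""
    spec = StrainSpec(strain_id="DIV1", cwps_template="F", eps_template=None,
                      divergence_identity=60.0, seed=31)
    genome, truth = generate_strain(spec)
    locus = find_locus(genome, "cwps")[0]
    typed = assign_roles(locus, refdb, params=align_params)
    truth_roles = truth.cwps.roles
    scored = [(c.role, truth_roles[c.gene.locus_tag]) for c in typed.roles
              if c.gene.locus_tag in truth_roles]
    recovered = sum(1 for got, want in scored if got == want)
    assert recovered / len(scored) >= 0.95
    # transposase implants always recovered via the keyword rule
    for call in typed.roles:
        if truth_roles.get(call.gene.locus_tag) == "transposase":
            assert call.role == "transposase"


def test_determinism(f_strain, refdb, align_params):
    genome, _ = f_strain
    locus = find_locus(genome, "cwps")[0]
    v1 = assign_roles(locus, refdb, params=align_params).role_vector()
    v2 = assign_roles(locus, refdb, params=align_params).role_vector()
    assert v1 == v2


class TestEpsPathway:
    def _typed(self, roles):
        rng = random.Random(4)
        genes = [_gene(f"t{i}", "x", random_protein(rng, 60), 10 + 400 * i)
                 for i in range(len(roles))]
        region = LocusRegion(genome_id="g", kind="eps",
                             fragments=[("c1", genes[0].start, genes[-1].end)],
                             genes=genes)
        return TypedLocus(region=region, roles=[
            RoleCall(gene=g, role=r, evidence="keyword")
            for g, r in zip(genes, roles)
        ])

    def test_wzx_wzy(self):
        typed = self._typed(["flippase", "polymerase", "regulator"])
        assert classify_eps_pathway(typed) == "wzx_wzy"

    def test_abc_transporter(self):
        typed = self._typed(["abc_transporter", "glycosyltransferase"])
        assert classify_eps_pathway(typed) == "abc_transporter"

    def test_undetermined(self):
        typed = self._typed(["glycosyltransferase"] * 3)
        assert classify_eps_pathway(typed) == "undetermined"


class TestPositionalDisambiguation:
    def _typed_with(self, entries):
        genes = []
        calls = []
        for i, (product, role, evidence) in enumerate(entries):
            g = _gene(f"p{i}", product, k_helix_protein(11), 10 + 2000 * i)
            genes.append(g)
            calls.append(RoleCall(gene=g, role=role, evidence=evidence))
        region = _locus_of(genes)
        return TypedLocus(region=region, roles=calls)

    def test_adjacent_to_copolymerase_becomes_polymerase(self):
        typed = self._typed_with([
            ("DUF2142 domain-containing glycosyltransferase", "glycosyltransferase", "keyword"),
            ("bactoprenol glycosyltransferase", "copolymerase", "similarity"),
        ])
        out = positional_disambiguation(typed)
        assert out.roles[0].role == "polymerase"
        assert "ambiguous_ycaA_like" in out.roles[0].note

    def test_isolated_duf2142_becomes_psp_transferase(self):
        typed = self._typed_with([
            ("DUF2142 domain-containing protein", "polymerase", "topology"),
            ("glycosyltransferase", "glycosyltransferase", "keyword"),
        ])
        out = positional_disambiguation(typed)
        assert out.roles[0].role == "psp_transferase"

    def test_no_duf2142_unchanged(self):
        typed = self._typed_with([
            ("glycosyltransferase", "glycosyltransferase", "keyword"),
            ("NAD-dependent epimerase", "modification_epimerase", "keyword"),
        ])
        before = typed.role_vector()
        assert positional_disambiguation(copy.deepcopy(typed)).role_vector() == before
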