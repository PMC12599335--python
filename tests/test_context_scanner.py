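"""Flank MGE census, island heuristic and split-locus merging."""

import pytest

from pellicle.context_scanner import detect_split_locus, scan_context
from pellicle.genome_io import Contig, Genome
from pellicle.locus_finder import find_locus
from pellicle.synthetic_data import StrainSpec, generate_strain


def test_housekeeping_flanks_are_quiet(f_strain_exact):
    genome, _ = f_strain_exact
    locus = find_locus(genome, "cwps")[0]
    report = scan_context(genome, locus)
    assert report.total_up + report.total_down <= 1
    assert not report.island_flag
    assert report.island_span_estimate is None
    assert report.replicon == "chromosome"


@pytest.fixture(scope="module")
def island_strain():
    spec = StrainSpec(strain_id="ISL1", cwps_template=None,
                      eps_template="IX", implant_island=True, seed=51)
    return generate_strain(spec)


class TestIsland:
    def test_island_flagged_with_dense_flanks(self, island_strain):
        genome, _ = island_strain
        locus = find_locus(genome, "eps")[0]
        report = scan_context(genome, locus)
        assert report.island_flag
        assert report.total_up >= 8
        assert report.mge_hits_up["transposase"] >= 1
        assert report.mge_hits_up["conjugal"] >= 1

    def test_span_estimate_within_20_percent(self, island_strain):
        genome, truth = island_strain
        locus = find_locus(genome, "eps")[0]
        report = scan_context(genome, locus)
        true_span = truth.island_span[1] - truth.island_span[0]
        assert 45_000 <= true_span <= 56_000
        assert report.island_span_estimate == pytest.approx(true_span, rel=0.2)

    def test_ice_components_without_orit_flagged(self, island_strain):
        genome, _ = island_strain
        locus = find_locus(genome, "eps")[0]
        report = scan_context(genome, locus)
        assert not report.orit_found
        assert report.ice_without_orit


def test_plasmid_replicon_forces_island_flag(f_strain_exact):
    genome, _ = f_strain_exact
    locus = find_locus(genome, "cwps")[0]
    plasmid = Genome(
        id=genome.id + "_p", species=genome.species,
        contigs=[Contig(id=c.id, length=c.length, topology=c.topology,
                        replicon_class="plasmid", sequence=c.sequence)
                 for c in genome.contigs],
        features=genome.features,
    )
    report = scan_context(plasmid, locus)
    assert report.replicon == "plasmid"
    assert report.island_flag


class TestSplitMerging:
    def test_generator_split_is_merged(self, refdb, align_params):
        from pellicle.locus_finder import FinderParams
        spec = StrainSpec(strain_id="SPL2", cwps_template="F", eps_template=None,
                          split_cwps=True, seed=53)
        genome, truth = generate_strain(spec)
        ref_map = {f"{p.role}|{p.name}": p.sequence for p in refdb
                   if p.kind in ("cwps", "any")}
        regions = find_locus(genome, "cwps", FinderParams(align=align_params),
                             refdb=ref_map)
        merged = detect_split_locus(regions, genome)
        assert len(merged) == 1
        assert len(merged[0].fragments) == 2
        report = scan_context(genome, merged[0])
        assert report.split_locus

    def test_merging_symmetric_in_order(self, refdb, align_params):
        from pellicle.locus_finder import FinderParams
        spec = StrainSpec(strain_id="SPL3", cwps_template="F", eps_template=None,
                          split_cwps=True, seed=54)
        genome, _ = generate_strain(spec)
        ref_map = {f"{p.role}|{p.name}": p.sequence for p in refdb
                   if p.kind in ("cwps", "any")}
        regions = find_locus(genome, "cwps", FinderParams(align=align_params),
                             refdb=ref_map)
        a = detect_split_locus(regions, genome)
        b = detect_split_locus(list(reversed(regions)), genome)
        assert len(a) == len(b) == 1
        assert sorted(a[0].fragments) == sorted(b[0].fragments)

    def test_two_complete_loci_not_merged(self, refdb, align_params):
        """Two genomes' worth of complete loci on one contig stay separate."""
        spec1 = StrainSpec(strain_id="TWIN", cwps_template="F", eps_template=None,
                           transposase_insertions=0, seed=55)
        genome, _ = generate_strain(spec1)
        regions = find_locus(genome, "cwps")
        doubled = regions + [
            type(regions[0])(genome_id="other", kind="cwps",
                             fragments=regions[0].fragments,
                             genes=regions[0].genes,
                             anchor_hits=regions[0].anchor_hits)
        ]
        merged = detect_split_locus(doubled, genome)
        assert len(merged) == 2

    def test_single_region_unchanged(self, f_strain_exact):
        genome, _ = f_strain_exact
        regions = find_locus(genome, "cwps")
        assert detect_split_locus(regions, genome) == regions
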