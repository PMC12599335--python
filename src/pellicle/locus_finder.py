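"""Detection of cwps and eps loci from annotated genomes.

Loci are found by anchoring on conserved marker genes — the dTDP-rhamnose
precursor pathway (rmlA-D), the rhamnosyltransferases (rgpA/B/E/F) and the
rgpCD ABC transporter for cwps; the conserved epsRXABCD / epsL / orfY
vocabulary for eps — and growing a region from each anchor over adjacent
genes that match the polysaccharide vocabulary or are annotated as
hypothetical, stopping after ``stop_after`` consecutive non-matching genes.
Transposases count as matching: they occur inside real loci.

A locus split across distant chromosomal sites (transposase-mediated) is
represented as one region with multiple fragments; fragment lengths and the
locus total use the end - start convention of the strain table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from . import vocab as _vocab
from .genome_io import GeneFeature, Genome
from .similarity import AlignParams, best_hit

CWPS_LENGTH_RANGE = (18445, 30217)   # advisory, observed cwps extremes
CWPS_GENE_RANGE = (16, 28)           # advisory, observed cwps gene counts
EPS_LENGTH_RANGE = (11000, 23300)    # advisory, typical eps cluster sizes
EPS_GENE_RANGE = (8, 30)


class LocusError(ValueError):
    pass


@dataclass
class FinderParams:
    stop_after: int = 2
    min_anchor_genes: int = 1
    use_similarity_fallback: bool = True
    fallback_threshold: float = 40.0
    fallback_min_genes: int = 2   # similarity hits needed to seed an anchor-less fragment
    align: AlignParams = field(default_factory=AlignParams)
    vocab_path: Optional[str] = None


@dataclass
class LocusRegion:
    genome_id: str
    kind: str  # cwps | eps
    fragments: list[tuple[str, int, int]]  # (contig_id, start, end)
    genes: list[GeneFeature]
    anchor_hits: list[tuple[str, str]] = field(default_factory=list)  # (locus_tag, marker role)

    @property
    def total_length(self) -> int:
        return sum(end - start for _, start, end in self.fragments)

    @property
    def gene_count(self) -> int:
        return len(self.genes)

    @property
    def split(self) -> bool:
        return len(self.fragments) > 1


@dataclass
class LocusQC:
    total_length: int
    gene_count: int
    length_in_expected_range: bool
    gene_count_in_expected_range: bool


def _gene_matches(gene: GeneFeature, kind: str, entries) -> bool:
    if _vocab.is_hypothetical(gene.product):
        return True
    return bool(_vocab.match_roles(gene.product, kind, entries))


def _anchor_role(gene: GeneFeature, kind: str, entries) -> Optional[str]:
    for e in _vocab.match_roles(gene.product, kind, entries):
        if e.anchor:
            return e.role
    return None


def find_locus(genome: Genome, kind: str,
               params: FinderParams | None = None,
               refdb=None) -> list[LocusRegion]:
    """Detect loci of one kind; returns one region per contiguous cluster.

    ``refdb`` (role-labelled exemplar proteins, mapping id->sequence) enables
    a similarity fallback that seeds regions where product strings are
    uninformative; it is only consulted when keyword anchoring finds nothing.
    """
    params = params or FinderParams()
    if kind not in ("cwps", "eps"):
        raise LocusError(f"unknown locus kind {kind!r}")
    entries = _vocab.role_vocabulary(params.vocab_path)
    regions: list[LocusRegion] = []
    for contig in genome.contigs:
        genes = [f for f in genome.sorted_features() if f.contig_id == contig.id]
        if not genes:
            continue
        anchors = {}
        for idx, g in enumerate(genes):
            role = _anchor_role(g, kind, entries)
            if role:
                anchors[idx] = role
        claimed: set[int] = set()
        if params.use_similarity_fallback and refdb:
            # similarity fallback: a transposase-split locus leaves an
            # anchor-less fragment whose products are uninformative for
            # seeding; genes matching the kind's reference exemplars seed it
            anchored_span: set[int] = set()
            for seed in anchors:
                anchored_span.update(range(max(0, seed - 40), min(len(genes), seed + 40)))
            sim_hits: dict[int, str] = {}
            for idx, g in enumerate(genes):
                if idx in anchored_span or not g.protein:
                    continue
                roles = {e.call_role for e in _vocab.match_roles(g.product, kind, entries)}
                if not roles or roles == {"transposase"}:
                    continue
                hit = best_hit(g.protein, refdb, params.align, query_id=g.locus_tag)
                if hit.score >= params.fallback_threshold:
                    sim_hits[idx] = f"similarity:{hit.subject_id}"
            # keep runs of >= fallback_min_genes hits within stop_after reach
            run: list[int] = []
            runs: list[list[int]] = []
            for idx in sorted(sim_hits):
                if run and idx - run[-1] > params.stop_after + 1:
                    runs.append(run)
                    run = []
                run.append(idx)
            if run:
                runs.append(run)
            for r in runs:
                if len(r) >= params.fallback_min_genes:
                    for idx in r:
                        anchors[idx] = sim_hits[idx]
        if not anchors:
            continue
        for seed in sorted(anchors):
            if seed in claimed:
                continue
            lo = hi = seed
            # grow left
            miss = 0
            i = seed - 1
            while i >= 0 and miss < params.stop_after:
                if _gene_matches(genes[i], kind, entries):
                    lo = i
                    miss = 0
                else:
                    miss += 1
                i -= 1
            # grow right
            miss = 0
            i = seed + 1
            while i < len(genes) and miss < params.stop_after:
                if _gene_matches(genes[i], kind, entries):
                    hi = i
                    miss = 0
                else:
                    miss += 1
                i += 1
            claimed.update(range(lo, hi + 1))
            region_genes = genes[lo : hi + 1]
            hits = [
                (g.locus_tag, anchors[j])
                for j, g in zip(range(lo, hi + 1), region_genes)
                if j in anchors
            ]
            regions.append(
                LocusRegion(
                    genome_id=genome.id, kind=kind,
                    fragments=[(contig.id, region_genes[0].start, region_genes[-1].end)],
                    genes=region_genes, anchor_hits=hits,
                )
            )
    # merge overlapping regions on the same contig
    merged: list[LocusRegion] = []
    for region in sorted(regions, key=lambda r: (r.fragments[0][0], r.fragments[0][1])):
        if merged:
            prev = merged[-1]
            pc, ps, pe = prev.fragments[0]
            rc, rs, re_ = region.fragments[0]
            if pc == rc and rs <= pe:
                tags = {g.locus_tag for g in prev.genes}
                prev.genes.extend(g for g in region.genes if g.locus_tag not in tags)
                prev.genes.sort(key=GeneFeature.sort_key)
                prev.fragments = [(pc, prev.genes[0].start, prev.genes[-1].end)]
                prev.anchor_hits.extend(
                    h for h in region.anchor_hits if h not in prev.anchor_hits
                )
                continue
        merged.append(region)
    # drop seedless leftovers below the anchor floor
    return [r for r in merged if len(r.anchor_hits) >= params.min_anchor_genes]


def partition_cwps(typed) -> Optional[int]:
    """Index of the first priming-glycosyltransferase role call.

    Genes before it form the rhamnan-encoding region, genes from it onward
    the PSP-encoding region.  Returns None (caller flags the locus
    non-canonical, the E/G-like organization) when no priming GT exists.
    """
    if not typed.roles:
        raise LocusError("cannot partition an empty locus")
    for idx, call in enumerate(typed.roles):
        if call.role == "priming_gt":
            return idx
    return None


def qc_locus(locus: LocusRegion) -> LocusQC:
    """Advisory size/gene-count QC; never rejects a locus."""
    lo, hi = CWPS_LENGTH_RANGE if locus.kind == "cwps" else EPS_LENGTH_RANGE
    glo, ghi = CWPS_GENE_RANGE if locus.kind == "cwps" else EPS_GENE_RANGE
    return LocusQC(
        total_length=locus.total_length,
        gene_count=locus.gene_count,
        length_in_expected_range=lo <= locus.total_length <= hi,
        gene_count_in_expected_range=glo <= locus.gene_count <= ghi,
    )
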