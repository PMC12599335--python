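"""Genomic context of polysaccharide loci: MGE census, island and ICE flags.

The mobile-genetic-element census is a keyword model over flanking product
annotations (transposases, integrases, phage genes, relaxases, T4SS/T4CP and
conjugal transfer proteins, phage-defense and immunity genes).  A locus is
flagged as sitting in a genomic island when either flank is MGE-dense (>= 3
hits per 10 genes by default) or the locus lies on a plasmid replicon.  The
island span estimate extends from the locus edges over contiguous MGE-rich
annotation; it is a heuristic estimate, not a curated boundary.

An ICE lacking an origin of transfer — relaxase, T4SS and T4CP present but
no oriT — is flagged as non-self-transmissible.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from . import vocab as _vocab
from .genome_io import GeneFeature, Genome
from .locus_finder import FinderParams, LocusRegion

MGE_CATEGORIES = (
    "transposase", "integrase", "phage", "relaxase", "t4ss", "t4cp",
    "conjugal", "defense", "amr",
)

_ORIT_RE = re.compile(r"\boriT\b|origin of transfer|mobilization nic", re.IGNORECASE)


@dataclass
class ContextParams:
    flank: int = 30000
    min_hits: int = 3          # island rule: >= min_hits per window_genes genes
    window_genes: int = 10
    island_gap: int = 2        # tolerated consecutive non-MGE genes when spanning
    mge_vocab_path: Optional[str] = None


@dataclass
class MobilityReport:
    upstream_window: tuple[int, int]
    downstream_window: tuple[int, int]
    mge_hits_up: dict[str, int]
    mge_hits_down: dict[str, int]
    island_flag: bool
    island_span_estimate: Optional[int]
    split_locus: bool
    replicon: str
    orit_found: bool
    ice_without_orit: bool = False
    notes: list[str] = field(default_factory=list)

    @property
    def total_up(self) -> int:
        return sum(self.mge_hits_up.values())

    @property
    def total_down(self) -> int:
        return sum(self.mge_hits_down.values())


def _census(genes: list[GeneFeature], vocab) -> dict[str, int]:
    counts = {c: 0 for c in MGE_CATEGORIES}
    for g in genes:
        for cat in _vocab.mge_categories(g.product, vocab):
            counts[cat] += 1
    return counts


def _is_mge(gene: GeneFeature, vocab) -> bool:
    return bool(_vocab.mge_categories(gene.product, vocab)) or \
        _vocab.is_hypothetical(gene.product)


def scan_context(genome: Genome, locus: LocusRegion,
                 params: ContextParams | None = None) -> MobilityReport:
    """Characterize the regions flanking a locus.  Pure given its inputs."""
    params = params or ContextParams()
    vocab = _vocab.mge_vocabulary(params.mge_vocab_path)
    contig_id, lstart, lend = max(
        locus.fragments, key=lambda f: sum(1 for g in locus.genes if g.contig_id == f[0])
    )
    contig = genome.contig(contig_id)
    notes: list[str] = []
    up = (max(1, lstart - params.flank), lstart - 1)
    down = (lend + 1, min(contig.length, lend + params.flank))
    if up[0] == 1 and lstart - params.flank < 1:
        notes.append("upstream flank clamped at contig edge")
    if down[1] == contig.length and lend + params.flank > contig.length:
        notes.append("downstream flank clamped at contig edge")

    locus_tags = {g.locus_tag for g in locus.genes}
    contig_genes = [g for g in genome.sorted_features() if g.contig_id == contig_id]
    up_genes = [g for g in contig_genes
                if g.locus_tag not in locus_tags and g.end >= up[0] and g.start <= up[1]]
    down_genes = [g for g in contig_genes
                  if g.locus_tag not in locus_tags and g.end >= down[0] and g.start <= down[1]]
    hits_up = _census(up_genes, vocab)
    hits_down = _census(down_genes, vocab)

    def dense(hits: dict[str, int], genes: list[GeneFeature]) -> bool:
        total = sum(hits.values())
        if not genes:
            return False
        return total >= params.min_hits and \
            total / len(genes) >= params.min_hits / params.window_genes

    replicon = contig.replicon_class
    island = dense(hits_up, up_genes) or dense(hits_down, down_genes) or replicon == "plasmid"

    span_estimate = None
    if island:
        idx_of = {g.locus_tag: i for i, g in enumerate(contig_genes)}
        in_locus = [i for i, g in enumerate(contig_genes) if g.locus_tag in locus_tags]
        lo = min(in_locus) if in_locus else 0
        hi = max(in_locus) if in_locus else len(contig_genes) - 1
        miss = 0
        i = lo - 1
        while i >= 0 and miss <= params.island_gap:
            if _is_mge(contig_genes[i], vocab):
                lo = i
                miss = 0
            else:
                miss += 1
            i -= 1
        miss = 0
        i = hi + 1
        while i < len(contig_genes) and miss <= params.island_gap:
            if _is_mge(contig_genes[i], vocab):
                hi = i
                miss = 0
            else:
                miss += 1
            i += 1
        span_estimate = contig_genes[hi].end - contig_genes[lo].start

    all_flank = up_genes + down_genes
    orit = any(_ORIT_RE.search(g.product) for g in all_flank)
    have = {cat for cat, n in _census(all_flank, vocab).items() if n > 0}
    ice_wo_orit = {"relaxase", "t4ss", "t4cp"} <= have and not orit
    if ice_wo_orit:
        notes.append("ICE components (relaxase+T4SS+T4CP) without an oriT: "
                     "likely not self-transmissible")

    return MobilityReport(
        upstream_window=up, downstream_window=down,
        mge_hits_up=hits_up, mge_hits_down=hits_down,
        island_flag=island, island_span_estimate=span_estimate,
        split_locus=locus.split, replicon=replicon,
        orit_found=orit, ice_without_orit=ice_wo_orit, notes=notes,
    )


CANONICAL_CWPS_ROLES = (
    "precursor_rmlA", "precursor_rmlB", "precursor_rmlC", "precursor_rmlD",
    "rhamnosyltransferase", "abc_transporter", "priming_gt", "flippase",
    "polymerase", "copolymerase", "glycosyltransferase",
)
CANONICAL_EPS_ROLES = (
    "regulator", "flippase", "polymerase", "glycosyltransferase",
    "abc_transporter", "modification_acetylase", "modification_epimerase",
)


@dataclass
class SplitParams:
    max_breakpoint_offset: int = 3   # transposase within this many genes of a fragment edge
    min_vocab_genes: int = 2
    min_union_roles: int = 6         # complementarity: union covers this many canonical roles
    vocab_path: Optional[str] = None


def _matched_roles(region: LocusRegion, vocab_path=None) -> set[str]:
    entries = _vocab.role_vocabulary(vocab_path)
    roles = set()
    for g in region.genes:
        for e in _vocab.match_roles(g.product, region.kind, entries):
            roles.add(e.call_role)
    return roles


def _edge_transposase(region: LocusRegion, genome: Genome, offset: int) -> bool:
    contig_id = region.fragments[0][0]
    genes = [g for g in genome.sorted_features() if g.contig_id == contig_id]
    tags = [g.locus_tag for g in genes]
    first = tags.index(region.genes[0].locus_tag)
    last = tags.index(region.genes[-1].locus_tag)
    window = genes[max(0, first - offset): first + offset + 1] + \
        genes[max(0, last - offset): last + offset + 1]
    return any("transposase" in _vocab.mge_categories(g.product) for g in window)


def detect_split_locus(regions: list[LocusRegion], genome: Genome,
                       params: SplitParams | None = None) -> list[LocusRegion]:
    """Merge fragments of one transposase-split locus into a 2-fragment region.

    Two same-kind regions merge iff both carry at least ``min_vocab_genes``
    locus-vocabulary genes, at least one has a transposase within
    ``max_breakpoint_offset`` genes of an edge, and their matched role sets
    are complementary (union >= ``min_union_roles`` canonical roles).
    Symmetric in fragment order; with > 2 candidates the best-supported pair
    is merged and the rest reported unchanged.
    """
    params = params or SplitParams()
    if len(regions) < 2:
        return list(regions)
    kinds = {r.kind for r in regions}
    if len(kinds) != 1:
        raise ValueError("detect_split_locus expects regions of one kind")
    canonical = CANONICAL_CWPS_ROLES if regions[0].kind == "cwps" else CANONICAL_EPS_ROLES

    def vocab_gene_count(region: LocusRegion) -> int:
        entries = _vocab.role_vocabulary(params.vocab_path)
        return sum(
            1 for g in region.genes
            if _vocab.match_roles(g.product, region.kind, entries)
        )

    candidates = []
    for i in range(len(regions)):
        for j in range(i + 1, len(regions)):
            a, b = regions[i], regions[j]
            if vocab_gene_count(a) < params.min_vocab_genes or \
                    vocab_gene_count(b) < params.min_vocab_genes:
                continue
            if not (_edge_transposase(a, genome, params.max_breakpoint_offset) or
                    _edge_transposase(b, genome, params.max_breakpoint_offset)):
                continue
            roles_a = _matched_roles(a, params.vocab_path) & set(canonical)
            roles_b = _matched_roles(b, params.vocab_path) & set(canonical)
            union = roles_a | roles_b
            if len(union) < params.min_union_roles:
                continue
            # complementarity: two complete loci (near-identical role sets)
            # are not fragments of one split locus
            overlap = len(roles_a & roles_b) / max(1, min(len(roles_a), len(roles_b)))
            if overlap > 0.5:
                continue
            candidates.append((len(union), vocab_gene_count(a) + vocab_gene_count(b), i, j))
    if not candidates:
        return list(regions)
    _, _, i, j = max(candidates, key=lambda t: (t[0], t[1], -t[2], -t[3]))
    a, b = regions[i], regions[j]
    first, second = sorted([a, b], key=lambda r: (r.fragments[0][0], r.fragments[0][1]))
    merged = LocusRegion(
        genome_id=first.genome_id, kind=first.kind,
        fragments=first.fragments + second.fragments,
        genes=first.genes + second.genes,
        anchor_hits=first.anchor_hits + second.anchor_hits,
    )
    out = [merged] + [r for k, r in enumerate(regions) if k not in (i, j)]
    if len(regions) > 2:
        pass  # remaining fragments reported unchanged
    return out
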