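"""Per-gene functional role assignment for detected loci.

Rule precedence mirrors the inference order used when typing these clusters
by hand: sequence similarity against role-labelled exemplar proteins first,
then annotation keywords, then membrane topology as the fallback of last
resort.  A combined-score threshold of 40 on the similarity route is loose
enough to carry cross-genotype identifications (e.g. a 56.3% similarity
still identifies a glycosyltransferase family member) while rejecting
spurious local hits.

DUF2142-containing genes are genuinely ambiguous between the polymerase and
the PSP-to-rhamnan transferase function; ``positional_disambiguation``
resolves keyword/topology-derived calls by gene context (adjacent to a
co-polymerase at the 3'-end -> polymerase; isolated with no co-polymerase in
the locus -> PSP transferase) and tags them ``ambiguous_ycaA_like``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

from . import vocab as _vocab
from .genome_io import GeneFeature
from .locus_finder import LocusRegion, partition_cwps
from .similarity import AlignParams, best_hit
from .topology import TMHProfile, classify_topology, predict_tmh

ROLES = (
    "precursor_rmlA", "precursor_rmlB", "precursor_rmlC", "precursor_rmlD",
    "rhamnosyltransferase", "abc_transporter", "priming_gt", "membrane_anchor",
    "flippase", "polymerase", "copolymerase", "psp_transferase",
    "glycosyltransferase", "modification_acetylase", "modification_epimerase",
    "modification_dehydratase", "modification_oxidoreductase",
    "modification_other", "regulator", "transposase", "unknown",
)

RHAMNAN_CORE_ROLES = {
    "precursor_rmlA", "precursor_rmlB", "precursor_rmlC", "precursor_rmlD",
    "rhamnosyltransferase", "abc_transporter",
}

_TOPOLOGY_ROLE = {
    "flippase_like": "flippase",
    "polymerase_like": "polymerase",
    "copolymerase_like": "copolymerase",
}


class RoleError(ValueError):
    pass


@dataclass
class RefProtein:
    role: str
    name: str
    sequence: str
    kind: str = "any"  # cwps | eps | any


@dataclass
class RoleCall:
    gene: GeneFeature
    role: str
    evidence: str  # similarity | keyword | topology
    score: Optional[float] = None
    note: str = ""


@dataclass
class TypedLocus:
    region: LocusRegion
    roles: list[RoleCall]
    partition: Optional[int] = None
    organization: str = "canonical_rhamnan_psp"
    pathway_class: Optional[str] = None  # eps only

    @property
    def kind(self) -> str:
        return self.region.kind

    def has_role(self, role: str) -> bool:
        return any(c.role == role for c in self.roles)

    def role_vector(self) -> list[str]:
        return [c.role for c in self.roles]


def read_refdb_fasta(path) -> list[RefProtein]:
    """Load a user-supplied exemplar FASTA with headers ``role|name|kind``
    (kind optional, defaults to 'any')."""
    from Bio import SeqIO

    refs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        parts = rec.id.split("|")
        if len(parts) < 2:
            raise RoleError(f"refdb header {rec.id!r}: expected role|name[|kind]")
        refs.append(RefProtein(role=parts[0], name=parts[1],
                               kind=parts[2] if len(parts) > 2 else "any",
                               sequence=str(rec.seq)))
    return refs


def write_refdb_fasta(refs: list[RefProtein], path) -> None:
    with open(path, "w") as fh:
        for p in refs:
            fh.write(f">{p.role}|{p.name}|{p.kind}\n{p.sequence}\n")


def _domain_hints(gene: GeneFeature, domain_table=None) -> set[str]:
    hints = set()
    for token in ("DUF2142", "ALG6", "ALG8", "PMT", "O-Mannosyltransferase"):
        if token.lower() in gene.product.lower():
            hints.add(token.upper())
    if domain_table and gene.locus_tag in domain_table:
        hints.update(d.upper() for d in domain_table[gene.locus_tag].domains)
    return hints


def assign_roles(locus: LocusRegion, refdb: list[RefProtein],
                 topo: Mapping[str, TMHProfile] | None = None,
                 params: AlignParams | None = None,
                 role_sim_threshold: float = 40.0,
                 domain_table=None,
                 vocab_path=None) -> TypedLocus:
    """Assign exactly one role per gene; first matching rule wins.

    ``topo`` optionally supplies precomputed TMH profiles keyed by locus_tag
    (they are predicted on demand otherwise).
    """
    if not locus.genes:
        raise RoleError("empty locus")
    if not refdb:
        raise RoleError("empty reference exemplar set")
    params = params or AlignParams()
    entries = _vocab.role_vocabulary(vocab_path)
    exemplars = {
        f"{p.role}|{p.name}": p.sequence
        for p in refdb
        if p.kind in (locus.kind, "any")
    }
    calls: list[RoleCall] = []
    for gene in locus.genes:
        call: Optional[RoleCall] = None
        if gene.protein and exemplars:
            hit = best_hit(gene.protein, exemplars, params, query_id=gene.locus_tag)
            if hit.score >= role_sim_threshold:
                call = RoleCall(
                    gene=gene, role=hit.subject_id.split("|", 1)[0],
                    evidence="similarity", score=hit.score,
                )
        if call is None:
            role = _vocab.first_role(gene.product, locus.kind, entries)
            if role:
                call = RoleCall(gene=gene, role=role, evidence="keyword")
        if call is None and gene.protein:
            profile = (topo or {}).get(gene.locus_tag) or predict_tmh(gene.protein)
            topo_class = classify_topology(profile, _domain_hints(gene, domain_table))
            mapped = _TOPOLOGY_ROLE.get(topo_class.label)
            if mapped:
                call = RoleCall(gene=gene, role=mapped, evidence="topology",
                                note=topo_class.evidence)
        if call is None:
            call = RoleCall(gene=gene, role="unknown", evidence="keyword")
        calls.append(call)

    typed = TypedLocus(region=locus, roles=calls)
    typed = positional_disambiguation(typed, domain_table=domain_table)
    typed.partition = partition_cwps(typed)
    has_pol = typed.has_role("polymerase")
    has_cop = typed.has_role("copolymerase")
    has_priming = typed.has_role("priming_gt")
    if typed.partition is None and not has_priming:
        typed.organization = "non_canonical"
    elif has_priming and not has_pol and not has_cop:
        typed.organization = "oligomeric"
    else:
        typed.organization = "canonical_rhamnan_psp"
    if locus.kind == "eps":
        typed.pathway_class = classify_eps_pathway(typed)
    return typed


def positional_disambiguation(typed: TypedLocus, domain_table=None) -> TypedLocus:
    """Resolve DUF2142 polymerase-vs-PSP-transferase ambiguity by context.

    Only keyword/topology-derived calls are adjusted; a similarity call to a
    role-labelled exemplar is taken at face value.
    """
    cop_indices = [i for i, c in enumerate(typed.roles) if c.role == "copolymerase"]
    for i, call in enumerate(typed.roles):
        if call.evidence == "similarity":
            continue
        hints = _domain_hints(call.gene, domain_table)
        duf = any("DUF2142" in h for h in hints)
        if not duf and call.role != "polymerase":
            continue
        if cop_indices:
            if any(abs(i - j) == 1 for j in cop_indices):
                typed.roles[i] = replace(call, role="polymerase",
                                         note="ambiguous_ycaA_like; adjacent to copolymerase")
        elif duf:
            typed.roles[i] = replace(call, role="psp_transferase",
                                     note="ambiguous_ycaA_like; no copolymerase in locus")
    return typed


def classify_eps_pathway(typed: TypedLocus) -> str:
    """Wzx/Wzy vs ABC-transporter pathway call for an eps locus."""
    if typed.kind != "eps":
        raise RoleError("pathway classification applies to eps loci only")
    has_flip = typed.has_role("flippase")
    has_pol = typed.has_role("polymerase")
    has_abc = typed.has_role("abc_transporter")
    if has_flip and has_pol:
        return "wzx_wzy"
    if has_abc and not has_flip and not has_pol:
        return "abc_transporter"
    return "undetermined"


def psp_gene_calls(typed: TypedLocus) -> list[RoleCall]:
    """PSP-encoding genes used for genotype criterion evaluation.

    For a partitioned (canonical) locus: every gene from the priming GT
    onward; for a non-canonical locus: every gene outside the rhamnan core.
    The flippase, polymerase, co-polymerase — and mobile/regulatory genes —
    are excluded in both cases.
    """
    excluded = {"flippase", "polymerase", "copolymerase", "transposase", "regulator"}
    if typed.partition is not None:
        pool = typed.roles[typed.partition:]
    else:
        pool = [c for c in typed.roles if c.role not in RHAMNAN_CORE_ROLES]
    return [c for c in pool if c.role not in excluded and c.gene.protein]
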