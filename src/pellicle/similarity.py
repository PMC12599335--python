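"""Pairwise protein similarity as coverage x identity.

Similarity between gene products is expressed as the product of query cover
and percent identity (both 0-100), the combined score used throughout the
typing rules.  Alignments are Smith-Waterman local alignments (BLOSUM62,
BLAST-style affine gaps: a gap of length L costs open + L*extend), computed
with Bio.Align.PairwiseAligner.

Direction matters: qcov (and hence score) is computed on the query, which in
the typing pipeline is always the candidate gene, while the subject is the
reference exemplar.  pid is symmetric for identical sequence pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .genome_io import PROTEIN_ALPHABET


class SimilarityError(ValueError):
    pass


@dataclass(frozen=True)
class AlignParams:
    matrix: str = "BLOSUM62"
    gap_open: int = 11      # BLAST convention: gap of length L costs open + L*extend
    gap_extend: int = 1
    prescreen_min_shared: float = 0.0  # 3-mer containment below which score is taken as 0


DEFAULT_PARAMS = AlignParams()


@dataclass
class AlignmentResult:
    query_id: str
    subject_id: str
    identities: int
    aligned_query_span: int
    query_length: int
    subject_length: int
    pid: float
    qcov: float
    score: float

    @classmethod
    def zero(cls, query_id: str, subject_id: str, qlen: int, slen: int) -> "AlignmentResult":
        return cls(query_id, subject_id, 0, 0, qlen, slen, 0.0, 0.0, 0.0)


@dataclass
class ClusterSimilarity:
    mean_best_hit_score: float
    per_gene_best: dict[str, tuple[str, float]]
    reciprocal_fraction: float


@lru_cache(maxsize=8)
def _aligner(matrix: str, gap_open: int, gap_extend: int) -> PairwiseAligner:
    al = PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load(matrix)
    al.mode = "local"
    # PairwiseAligner charges open_gap_score for the first gapped position,
    # so BLAST's open+L*extend maps to open_gap_score = -(open+extend).
    al.open_gap_score = -(gap_open + gap_extend)
    al.extend_gap_score = -gap_extend
    return al


def _check_protein(seq: str, name: str) -> str:
    if not seq:
        raise SimilarityError(f"{name}: empty sequence")
    seq = seq.upper()
    bad = set(seq) - PROTEIN_ALPHABET
    if bad:
        raise SimilarityError(f"{name}: non-amino-acid symbols {sorted(bad)}")
    return seq


def kmer_containment(a: str, b: str, k: int = 3) -> float:
    """Shared k-mer fraction, normalised by the smaller k-mer set."""
    if len(a) < k or len(b) < k:
        return 1.0
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    return len(ka & kb) / min(len(ka), len(kb))


def local_score(query: str, subject: str, params: AlignParams = DEFAULT_PARAMS) -> float:
    """Optimal Smith-Waterman score (0 when no positive-scoring alignment)."""
    al = _aligner(params.matrix, params.gap_open, params.gap_extend)
    return max(0.0, float(al.score(query, subject)))


def align_proteins(query: str, subject: str,
                   params: AlignParams = DEFAULT_PARAMS,
                   query_id: str = "query", subject_id: str = "subject") -> AlignmentResult:
    """Local alignment with pid, qcov and the combined score.

    pid = 100 * identities / alignment columns (gaps included);
    qcov = 100 * aligned query span / query length;
    score = pid * qcov / 100.
    """
    query = _check_protein(query, "query")
    subject = _check_protein(subject, "subject")
    al = _aligner(params.matrix, params.gap_open, params.gap_extend)
    raw = float(al.score(query, subject))
    if raw <= 0:
        return AlignmentResult.zero(query_id, subject_id, len(query), len(subject))
    aln = al.align(query, subject)[0]
    counts = aln.counts()
    identities = int(counts.identities)
    columns = int(aln.length)
    q_segments = aln.aligned[0]
    q_start = int(q_segments[0][0])
    q_end = int(q_segments[-1][1])
    span = q_end - q_start
    pid = 100.0 * identities / columns if columns else 0.0
    qcov = 100.0 * span / len(query)
    return AlignmentResult(
        query_id=query_id, subject_id=subject_id,
        identities=identities, aligned_query_span=span,
        query_length=len(query), subject_length=len(subject),
        pid=pid, qcov=qcov, score=pid * qcov / 100.0,
    )


def _as_subject_map(subjects) -> dict[str, str]:
    if isinstance(subjects, Mapping):
        return dict(subjects)
    return {f"s{i}": s for i, s in enumerate(subjects)}


def best_hit(query: str, subjects, params: AlignParams = DEFAULT_PARAMS,
             query_id: str = "query") -> AlignmentResult:
    """Best-scoring subject for a query.

    Ties are broken by higher pid, then lexicographic subject id.  Subjects
    failing the 3-mer prescreen (params.prescreen_min_shared > 0) are treated
    as score 0 without running the DP.  A best hit of score 0 is returned,
    not raised.
    """
    submap = _as_subject_map(subjects)
    if not submap:
        raise SimilarityError("empty subject list")
    query = _check_protein(query, "query")
    raw_scores: dict[str, float] = {}
    for sid, sseq in submap.items():
        if params.prescreen_min_shared > 0 and \
                kmer_containment(query, sseq) < params.prescreen_min_shared:
            raw_scores[sid] = 0.0
        else:
            raw_scores[sid] = local_score(query, sseq, params)
    top_raw = max(raw_scores.values())
    if top_raw <= 0:
        sid = min(submap)
        return AlignmentResult.zero(query_id, sid, len(query), len(submap[sid]))
    # full alignment only for subjects sharing the top raw score
    candidates = [sid for sid, sc in raw_scores.items() if sc == top_raw]
    results = [
        align_proteins(query, submap[sid], params, query_id=query_id, subject_id=sid)
        for sid in sorted(candidates)
    ]
    return min(results, key=lambda r: (-r.score, -r.pid, r.subject_id))


def cluster_similarity(genes_a, genes_b,
                       params: AlignParams = DEFAULT_PARAMS) -> ClusterSimilarity:
    """Gene-set similarity A -> B.

    Per-gene best hits are computed A->B; the summary is the length-weighted
    mean of best-hit scores (weights = query lengths), so gene order is
    irrelevant.  reciprocal_fraction is the fraction of A genes that are also
    the best B->A partner of their own best hit.
    """
    amap = _as_subject_map(genes_a)
    bmap = _as_subject_map(genes_b)
    if not amap or not bmap:
        raise SimilarityError("empty gene set")
    per_gene: dict[str, tuple[str, float]] = {}
    total_w = 0.0
    acc = 0.0
    for aid in sorted(amap):
        hit = best_hit(amap[aid], bmap, params, query_id=aid)
        per_gene[aid] = (hit.subject_id, hit.score)
        w = len(amap[aid])
        acc += w * hit.score
        total_w += w
    n_recip = 0
    for aid, (bid, score) in per_gene.items():
        if score <= 0:
            continue
        back = best_hit(bmap[bid], amap, params, query_id=bid)
        if back.subject_id == aid:
            n_recip += 1
    return ClusterSimilarity(
        mean_best_hit_score=acc / total_w,
        per_gene_best=per_gene,
        reciprocal_fraction=n_recip / len(amap),
    )
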