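"""Genotype assignment for cwps and eps loci.

A cwps genotype is defined by three criteria evaluated against each known
profile: (i) presence/absence of the polymerase and co-polymerase, (ii)
presence/absence of the flippase, and (iii) two or more PSP-encoding genes
(excluding flippase/polymerase/co-polymerase) sharing < 30% amino-acid
similarity — coverage x identity — with the profile's exemplars.  A locus
matches a profile iff no criterion fires; otherwise a novel letter label is
minted, continuing the established A..D series at E.

eps genotypes have no published numeric rule; the stand-in implemented here
matches a locus to a profile when the variable region (genes after the
conserved proximal eps block) reaches a mean best-hit score >= 80 and the
export pathway class (Wzx/Wzy vs ABC transporter) is identical.  Novel eps
labels continue the roman-numeral series.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from .role_inference import TypedLocus, psp_gene_calls
from .similarity import AlignParams, ClusterSimilarity, best_hit, cluster_similarity

_EPS_CONSERVED_PREFIX = re.compile(
    r"\beps[RXABCDE]\b|transcriptional regulator|tyrosine-protein kinase|"
    r"protein-tyrosine phosphatase|capsular polysaccharide biosynthesis protein|"
    r"polysaccharide biosynthesis initiation",
    re.IGNORECASE,
)


class GenotypeError(ValueError):
    pass


@dataclass
class GenotypeProfile:
    label: str
    kind: str  # cwps | eps
    has_polymerase: bool = False
    has_copolymerase: bool = False
    has_flippase: bool = False
    psp_exemplars: dict[str, str] = field(default_factory=dict)  # name -> protein
    pathway_class: Optional[str] = None  # eps only


@dataclass
class GenotypeCall:
    label: str
    is_novel: bool
    matched_profile: Optional[str] = None
    criteria_fired: dict[str, frozenset] = field(default_factory=dict)  # per rejected profile
    mean_similarity: float = 0.0
    warning: str = ""


@dataclass
class GenotypeDB:
    profiles: list[GenotypeProfile] = field(default_factory=list)
    next_label_rule: str = "letters"  # letters (cwps) | roman (eps)

    def __post_init__(self) -> None:
        labels = [p.label for p in self.profiles]
        if len(labels) != len(set(labels)):
            raise GenotypeError("duplicate profile labels")

    def labels(self) -> list[str]:
        return [p.label for p in self.profiles]

    def add(self, profile: GenotypeProfile) -> None:
        if profile.label in self.labels():
            raise GenotypeError(f"duplicate label {profile.label}")
        self.profiles.append(profile)


def default_cwps_db() -> GenotypeDB:
    """Historical cwps profiles A-D, flag-level only.

    Without exemplar proteins criterion iii always fires against them, so
    every observed locus mints a novel label starting at E — matching how
    the established nomenclature was extended.  Exemplars may be supplied by
    the user to enable full A-D matching.
    """
    return GenotypeDB(
        profiles=[
            GenotypeProfile("A", "cwps", has_polymerase=False, has_copolymerase=False, has_flippase=True),
            GenotypeProfile("B", "cwps", has_polymerase=False, has_copolymerase=False, has_flippase=True),
            GenotypeProfile("C", "cwps", has_polymerase=True, has_copolymerase=True, has_flippase=True),
            GenotypeProfile("D", "cwps", has_polymerase=True, has_copolymerase=True, has_flippase=True),
        ],
        next_label_rule="letters",
    )


_ROMAN = [
    (1000, "M"), (900, "CM"), (500, "D"), (400, "CD"), (100, "C"), (90, "XC"),
    (50, "L"), (40, "XL"), (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
]


def int_to_roman(n: int) -> str:
    if n < 1:
        raise GenotypeError("roman numerals start at 1")
    out = []
    for value, sym in _ROMAN:
        while n >= value:
            out.append(sym)
            n -= value
    return "".join(out)


def roman_to_int(s: str) -> int:
    values = {"I": 1, "V": 5, "X": 10, "L": 50, "C": 100, "D": 500, "M": 1000}
    total = 0
    prev = 0
    for c in reversed(s.upper()):
        v = values[c]
        total = total - v if v < prev else total + v
        prev = max(prev, v)
    return total


def _letter_index(label: str) -> int:
    # A=1 .. Z=26, AA=27 ...
    n = 0
    for c in label.upper():
        n = n * 26 + (ord(c) - 64)
    return n


def _index_letter(n: int) -> str:
    out = []
    while n:
        n, rem = divmod(n - 1, 26)
        out.append(chr(65 + rem))
    return "".join(reversed(out))


def mint_label(db: GenotypeDB, kind: str) -> str:
    """Next unused label: letters continue past the maximum (A..Z, AA..);
    eps labels are successive roman numerals."""
    if kind == "cwps":
        existing = [_letter_index(l) for l in db.labels() if re.fullmatch(r"[A-Z]+", l)]
        return _index_letter(max(existing, default=0) + 1)
    existing = [roman_to_int(l) for l in db.labels() if re.fullmatch(r"[IVXLCDM]+", l)]
    return int_to_roman(max(existing, default=0) + 1)


def _locus_flags(typed: TypedLocus) -> tuple[bool, bool, bool]:
    return (
        typed.has_role("polymerase"),
        typed.has_role("copolymerase"),
        typed.has_role("flippase"),
    )


def assign_cwps_genotype(typed: TypedLocus, db: GenotypeDB,
                         sim_threshold: float = 30.0,
                         params: AlignParams | None = None,
                         mint: bool = True) -> GenotypeCall:
    """Classify a cwps locus against the profile database.

    Criterion iii is asymmetric: it counts genes of the query locus lacking
    any exemplar hit >= threshold in the profile.  Among matching profiles,
    the highest length-weighted mean exemplar similarity wins (db order
    breaks ties).  With no match a novel profile is minted from this locus
    and appended to the db (unless ``mint`` is False).
    """
    if not typed.roles:
        raise GenotypeError("locus has no role calls")
    params = params or AlignParams()
    has_pol, has_cop, has_flip = _locus_flags(typed)
    psp = psp_gene_calls(typed)
    psp_seqs = {c.gene.locus_tag: c.gene.protein for c in psp}

    criteria_fired: dict[str, frozenset] = {}
    matches: list[tuple[float, int, GenotypeProfile]] = []
    for order, profile in enumerate(p for p in db.profiles if p.kind == "cwps"):
        fired = set()
        if (profile.has_polymerase, profile.has_copolymerase) != (has_pol, has_cop):
            fired.add("i")
        if profile.has_flippase != has_flip:
            fired.add("ii")
        below = 0
        mean = 0.0
        if psp_seqs:
            total_w = sum(len(s) for s in psp_seqs.values())
            acc = 0.0
            for tag, seq in psp_seqs.items():
                if profile.psp_exemplars:
                    hit = best_hit(seq, profile.psp_exemplars, params, query_id=tag)
                    score = hit.score
                else:
                    score = 0.0
                if score < sim_threshold:
                    below += 1
                acc += len(seq) * score
            mean = acc / total_w if total_w else 0.0
        if below >= 2:
            fired.add("iii")
        if fired:
            criteria_fired[profile.label] = frozenset(fired)
        else:
            matches.append((mean, order, profile))

    if matches:
        mean, _, profile = min(matches, key=lambda t: (-t[0], t[1]))
        return GenotypeCall(
            label=profile.label, is_novel=False, matched_profile=profile.label,
            criteria_fired=criteria_fired, mean_similarity=mean,
        )
    label = mint_label(db, "cwps")
    if mint:
        db.add(GenotypeProfile(
            label=label, kind="cwps",
            has_polymerase=has_pol, has_copolymerase=has_cop, has_flippase=has_flip,
            psp_exemplars=dict(psp_seqs),
        ))
    return GenotypeCall(label=label, is_novel=True, criteria_fired=criteria_fired)


def eps_variable_region(typed: TypedLocus) -> dict[str, str]:
    """Genes after the conserved proximal eps block (epsRXABCD / epsABC)."""
    genes = [c.gene for c in typed.roles]
    idx = 0
    while idx < len(genes) and _EPS_CONSERVED_PREFIX.search(genes[idx].product):
        idx += 1
    return {g.locus_tag: g.protein for g in genes[idx:] if g.protein}


def assign_eps_genotype(typed: TypedLocus, db: GenotypeDB,
                        match_threshold: float = 80.0,
                        params: AlignParams | None = None,
                        mint: bool = True) -> GenotypeCall:
    """Classify an eps locus by variable-region similarity + pathway class."""
    if typed.kind != "eps":
        raise GenotypeError("assign_eps_genotype expects an eps locus")
    params = params or AlignParams()
    variable = eps_variable_region(typed)
    if not variable:
        return GenotypeCall(label="undetermined", is_novel=False,
                            warning="no variable-region genes")
    best: Optional[tuple[float, int, GenotypeProfile]] = None
    criteria: dict[str, frozenset] = {}
    for order, profile in enumerate(p for p in db.profiles if p.kind == "eps"):
        if not profile.psp_exemplars:
            criteria[profile.label] = frozenset({"similarity"})
            continue
        sim = cluster_similarity(variable, profile.psp_exemplars, params)
        rejected = set()
        if sim.mean_best_hit_score < match_threshold:
            rejected.add("similarity")
        if profile.pathway_class != typed.pathway_class:
            rejected.add("pathway")
        if rejected:
            criteria[profile.label] = frozenset(rejected)
        elif best is None or sim.mean_best_hit_score > best[0]:
            best = (sim.mean_best_hit_score, order, profile)
    if best is not None:
        mean, _, profile = best
        return GenotypeCall(label=profile.label, is_novel=False,
                            matched_profile=profile.label,
                            criteria_fired=criteria, mean_similarity=mean)
    label = mint_label(db, "eps")
    if mint:
        db.add(GenotypeProfile(
            label=label, kind="eps",
            has_polymerase=typed.has_role("polymerase"),
            has_copolymerase=typed.has_role("copolymerase"),
            has_flippase=typed.has_role("flippase"),
            psp_exemplars=dict(variable),
            pathway_class=typed.pathway_class,
        ))
    return GenotypeCall(label=label, is_novel=True, criteria_fired=criteria)
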