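"""Synthetic annotated genomes with implanted polysaccharide loci.

The generator emits Bakta-style annotated chromosomes carrying implantable
cwps and eps loci with controlled protein divergence, transposase
insertions (including transposase-mediated locus splitting) and MGE-rich
island flanks, together with a machine-readable truth table, so every
pipeline stage is testable without downloads.

Template proteins are synthetic: composition-biased random sequences with
role-appropriate membrane architectures (13-TMH flippases, 11-TMH DUF2142
polymerases, signal-peptide + large-loop co-polymerases), so both the
similarity and the topology inference routes are exercised.  The template
library covers the eight observed cwps organizations (E-L) and the eleven
eps organizations (I-XI); rhamnan-core and conserved-eps proteins are shared
across templates, variable-region proteins are template-specific.

Default study conditions: per-strain cwps implant divergence targets 88%
identity to the template (within-genotype pairwise identity then stays
comfortably above 70%), eps implants 98% (same-genotype eps clusters in the
emulated starter-culture strains are near-identical), islands span 45-55 kb
around the eps locus, and the default 28-strain cohort mirrors the observed
composition: 21 species-1 strains (19 F-like, one E-like, one G-like; two
with a split cwps locus) and 7 species-2 strains (H, I, G, E, J, K, L-like),
with eps templates on 25 of the 28.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from Bio.Align import substitution_matrices

from .genome_io import Contig, GeneFeature, Genome

TEMPLATE_SEED = 977151  # fixed: the template library is part of the package

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_POLAR = "DEKRSTNQGPHAY"
_HYDRO = "LIVFAM"
_HYDRO_W = np.array([0.30, 0.22, 0.20, 0.12, 0.10, 0.06])

# deterministic codon back-translation (one codon per amino acid, table 11)
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT", "X": "NNN", "*": "TAA",
}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SyntheticError(ValueError):
    pass


def _rng_for(*key) -> np.random.Generator:
    crc = zlib.crc32("|".join(str(k) for k in key).encode())
    return np.random.default_rng(np.random.SeedSequence([TEMPLATE_SEED, crc]))


def _soluble(length: int, rng: np.random.Generator) -> str:
    aas = np.array(list(AA20))
    w = np.ones(20)
    for i, c in enumerate(AA20):  # bias toward polar composition
        if c in _POLAR:
            w[i] = 2.0
    w /= w.sum()
    body = "".join(rng.choice(aas, size=length - 1, p=w))
    return "M" + body


def _membrane(n_helix: int, rng: np.random.Generator,
              tail: int = 25, loop: int = 18, helix: int = 21) -> str:
    polar = np.array(list(_POLAR))
    hydro = np.array(list(_HYDRO))
    parts = ["M" + "".join(rng.choice(polar, size=tail - 1))]
    for i in range(n_helix):
        parts.append("".join(rng.choice(hydro, size=helix, p=_HYDRO_W)))
        parts.append("".join(rng.choice(polar, size=loop if i < n_helix - 1 else tail)))
    return "".join(parts)


def _copolymerase(rng: np.random.Generator, loop: int = 190) -> str:
    polar = np.array(list(_POLAR))
    hydro = np.array(list(_HYDRO))
    return ("MKR" + "".join(rng.choice(hydro, size=9, p=_HYDRO_W)) + "AQA"
            + "".join(rng.choice(polar, size=loop))
            + "".join(rng.choice(hydro, size=21, p=_HYDRO_W)) + "KK")


@dataclass(frozen=True)
class TemplateGene:
    name: str        # protein identity key; shared names = shared proteins
    product: str
    role: str
    build: tuple     # ("sol", length) | ("mem", n_helix) | ("cop",)


_PROTEIN_CACHE: dict[str, str] = {}


def template_protein(gene: TemplateGene) -> str:
    if gene.name not in _PROTEIN_CACHE:
        rng = _rng_for("protein", gene.name)
        kind = gene.build[0]
        if kind == "sol":
            seq = _soluble(gene.build[1], rng)
        elif kind == "mem":
            seq = _membrane(gene.build[1], rng)
        elif kind == "cop":
            seq = _copolymerase(rng)
        else:
            raise SyntheticError(f"unknown builder {kind}")
        _PROTEIN_CACHE[gene.name] = seq
    return _PROTEIN_CACHE[gene.name]


def _g(name, product, role, build) -> TemplateGene:
    return TemplateGene(name, product, role, build)


# --- cwps template library -------------------------------------------------

_RML_CORE = [
    _g("rmlA", "glucose-1-phosphate thymidylyltransferase RmlA", "precursor_rmlA", ("sol", 290)),
    _g("rmlB", "dTDP-glucose 4,6-dehydratase RmlB", "precursor_rmlB", ("sol", 330)),
    _g("rmlC", "dTDP-4-dehydrorhamnose 3,5-epimerase RmlC", "precursor_rmlC", ("sol", 190)),
    _g("rmlD", "dTDP-4-dehydrorhamnose reductase RmlD", "precursor_rmlD", ("sol", 280)),
    _g("rgpA", "rhamnosyltransferase RgpA", "rhamnosyltransferase", ("sol", 380)),
    _g("rgpB", "rhamnosyltransferase RgpB", "rhamnosyltransferase", ("sol", 390)),
]
_RGP_ABC = [
    _g("rgpC", "polysaccharide ABC transporter ATP-binding protein RgpC", "abc_transporter", ("sol", 250)),
    _g("rgpD", "polysaccharide ABC transporter permease RgpD", "abc_transporter", ("mem", 6)),
]
_WPS_AB = [
    _g("wpsA", "priming glycosyltransferase WpsA", "priming_gt", ("sol", 225)),
    _g("wpsB", "polysaccharide biosynthesis membrane protein WpsB", "membrane_anchor", ("mem", 2)),
]
_TNP = _g("tnp", "IS30 family transposase", "transposase", ("sol", 270))


def _gts(prefix: str, lengths: list[int]) -> list[TemplateGene]:
    return [
        _g(f"{prefix}{i+1}", "glycosyltransferase", "glycosyltransferase", ("sol", n))
        for i, n in enumerate(lengths)
    ]


CWPS_TEMPLATES: dict[str, list[TemplateGene]] = {
    "E": _RML_CORE + [
        _g("rgpE_E", "rhamnosyltransferase RgpE", "rhamnosyltransferase", ("sol", 360)),
        _g("taldh_E", "dTDP-6-deoxy-L-talose 4-dehydrogenase", "modification_oxidoreductase", ("sol", 300)),
        _g("acet_E", "acetyltransferase OafA superfamily protein", "modification_acetylase", ("mem", 10)),
        _g("sulf_E", "sulfatase-like hydrolase/transferase", "modification_other", ("mem", 11)),
        *_gts("gtE", [330]),
        _g("ycaA_E", "DUF2142 domain-containing protein", "polymerase", ("mem", 11)),
        _g("cop_E", "bactoprenol glycosyltransferase", "copolymerase", ("cop",)),
    ] + _RGP_ABC + [_TNP],
    "F": _RML_CORE + _RGP_ABC + _WPS_AB + [
        *_gts("gtF", [320, 350, 300]),
        _g("acet_F", "O-acetyltransferase OafA family protein", "modification_acetylase", ("mem", 10)),
        _g("epim_F", "NAD-dependent epimerase", "modification_epimerase", ("sol", 310)),
        _g("wpsG_F", "polysaccharide flippase WpsG", "flippase", ("mem", 13)),
        _g("pol_F", "DUF2142 domain-containing glycosyltransferase", "polymerase", ("mem", 11)),
        _g("cop_F", "bactoprenol glycosyltransferase", "copolymerase", ("cop",)),
        _g("wpsJ_F", "DUF2142 domain-containing protein", "psp_transferase", ("mem", 11)),
        _TNP,
    ],
    "G": _RML_CORE + [
        *_gts("gtG", [340, 310, 290]),
        _g("epim_G", "NAD-dependent epimerase", "modification_epimerase", ("sol", 320)),
        _g("ycaA_G", "DUF2142 domain-containing protein", "polymerase", ("mem", 11)),
        _g("cop_G", "bactoprenol glycosyltransferase", "copolymerase", ("cop",)),
    ] + _RGP_ABC,
    "H": _RML_CORE + _RGP_ABC + _WPS_AB + [
        *_gts("gtH", [310, 340, 295, 325]),
        _g("dehy_H", "polysaccharide biosynthesis dehydratase", "modification_dehydratase", ("sol", 330)),
        _g("wpsG_H", "polysaccharide flippase WpsG", "flippase", ("mem", 13)),
        _g("pol_H", "DUF2142 domain-containing glycosyltransferase", "polymerase", ("mem", 11)),
        _g("cop_H", "bactoprenol glycosyltransferase", "copolymerase", ("cop",)),
        _g("wpsJ_H", "DUF2142 domain-containing protein", "psp_transferase", ("mem", 11)),
    ],
    "I": _RML_CORE + _RGP_ABC + _WPS_AB + [
        *_gts("gtI", [305, 335, 315, 345, 290]),
        _g("epim_I", "NAD-dependent epimerase", "modification_epimerase", ("sol", 315)),
        _g("wpsG_I", "polysaccharide flippase WpsG", "flippase", ("mem", 13)),
        _g("pol_I", "DUF2142 domain-containing glycosyltransferase", "polymerase", ("mem", 11)),
        _g("cop_I", "bactoprenol glycosyltransferase", "copolymerase", ("cop",)),
        _g("wpsJ_I", "DUF2142 domain-containing protein", "psp_transferase", ("mem", 11)),
    ],
    "J": _RML_CORE + _RGP_ABC + _WPS_AB + [
        *_gts("gtJ", [325, 300, 340]),
        _g("acet_J", "O-acetyltransferase", "modification_acetylase", ("sol", 280)),
        _g("wpsG_J", "polysaccharide flippase WpsG", "flippase", ("mem", 13)),
    ],
    "K": _RML_CORE + _RGP_ABC + _WPS_AB + [
        *_gts("gtK", [300, 330, 310, 345, 295, 320]),
        _g("epim_K", "NAD-dependent epimerase", "modification_epimerase", ("sol", 305)),
        _g("acet_K", "O-acetyltransferase", "modification_acetylase", ("sol", 285)),
        _g("mut_K", "phosphoglucosamine mutase", "modification_other", ("sol", 340)),
        _g("wpsG_K", "polysaccharide flippase WpsG", "flippase", ("mem", 13)),
        _g("wpsI_K", "DUF2142 domain-containing glycosyltransferase", "polymerase", ("mem", 11)),
        _g("wpsH_K", "bactoprenol glycosyltransferase", "copolymerase", ("cop",)),
        _g("wpsJ_K", "DUF2142 domain-containing protein", "psp_transferase", ("mem", 11)),
    ],
    "L": _RML_CORE + _RGP_ABC + _WPS_AB + [
        *_gts("gtL", [315, 290, 335, 305, 350]),
        _g("oxi_L", "UDP-glucose 6-dehydrogenase", "modification_oxidoreductase", ("sol", 390)),
        _g("acet_L", "O-acetyltransferase", "modification_acetylase", ("sol", 290)),
        _g("wpsG_L", "polysaccharide flippase WpsG", "flippase", ("mem", 13)),
        _g("ycaA_L", "DUF2142 domain-containing protein", "polymerase", ("mem", 11)),
        _g("cop_L", "bactoprenol glycosyltransferase", "copolymerase", ("cop",)),
    ],
}

# --- eps template library --------------------------------------------------

_EPS_RX = [
    _g("epsR", "transcriptional regulator EpsR", "regulator", ("sol", 120)),
    _g("epsX", "EpsX protein", "regulator", ("sol", 160)),
]
_EPS_ABC_BLOCK = [
    _g("epsA", "capsular polysaccharide biosynthesis protein EpsA", "regulator", ("mem", 2)),
    _g("epsB", "tyrosine-protein kinase EpsB", "regulator", ("sol", 230)),
    _g("epsC", "protein-tyrosine phosphatase EpsC", "regulator", ("sol", 250)),
]
_EPS_D = [_g("epsD", "capsular polysaccharide biosynthesis protein EpsD", "regulator", ("sol", 230))]
_EPS_TERM = [
    _g("epsL", "EpsL protein", "regulator", ("sol", 200)),
    _g("orfY", "polysaccharide biosynthesis modulator OrfY", "regulator", ("sol", 150)),
]


def _eps_variable(label: str, n_gt: int, mods: list[TemplateGene],
                  wzx_product: str, wzy_product: str) -> list[TemplateGene]:
    lengths = [290 + 17 * ((i * 7 + sum(ord(c) for c in label)) % 6) for i in range(n_gt)]
    return (
        _gts(f"gt{label}e", lengths) + mods + [
            _g(f"wzx_{label}", wzx_product, "flippase", ("mem", 13)),
            _g(f"wzy_{label}", wzy_product, "polymerase", ("mem", 11)),
        ]
    )


_WZX_NAMED = "polysaccharide flippase Wzx"
_WZX_ANON = "polysaccharide biosynthesis protein"
_WZY_NAMED = "oligosaccharide repeat unit polymerase Wzy"
_WZY_ANON = "hypothetical protein"

EPS_TEMPLATES: dict[str, list[TemplateGene]] = {
    "I": _EPS_RX + _EPS_ABC_BLOCK + _EPS_D + _eps_variable(
        "I", 4, [_g("epimIe", "NAD-dependent epimerase", "modification_epimerase", ("sol", 300))],
        _WZX_NAMED, _WZY_ANON) + _EPS_TERM,
    "II": _EPS_ABC_BLOCK + _eps_variable(
        "II", 5, [_g("acetIIe", "O-acetyltransferase", "modification_acetylase", ("sol", 270))],
        _WZX_NAMED, _WZY_ANON) + _EPS_TERM,
    "III": _EPS_RX + _EPS_ABC_BLOCK + _EPS_D + _eps_variable(
        "III", 8, [_g("phosIIIe", "putative phosphotransferase", "modification_other", ("sol", 260))],
        _WZX_ANON, _WZY_ANON) + _EPS_TERM,
    "IV": _EPS_RX + _EPS_ABC_BLOCK + _EPS_D + _eps_variable(
        "IV", 5, [_g("dehyIVe", "polysaccharide biosynthesis dehydratase", "modification_dehydratase", ("sol", 310))],
        _WZX_NAMED, _WZY_ANON) + _EPS_TERM,
    "V": _EPS_RX + _EPS_ABC_BLOCK + _EPS_D + _eps_variable(
        "V", 4, [_g("epimVe", "UDP-glucose 4-epimerase", "modification_epimerase", ("sol", 295))],
        _WZX_ANON, _WZY_NAMED) + _EPS_TERM,
    "VI": _EPS_ABC_BLOCK + _eps_variable(
        "VI", 4, [
            _g("acetVIe", "O-acetyltransferase", "modification_acetylase", ("sol", 280)),
            _g("dehyVIe", "polysaccharide biosynthesis dehydratase", "modification_dehydratase", ("sol", 320)),
            _g("epimVIe", "NAD-dependent epimerase", "modification_epimerase", ("sol", 305)),
        ], _WZX_ANON, _WZY_ANON) + _EPS_TERM,
    "VII": _EPS_ABC_BLOCK + _eps_variable(
        "VII", 4, [_g("mutVIIe", "phosphoglucomutase", "modification_other", ("sol", 330))],
        _WZX_ANON, _WZY_NAMED) + _EPS_TERM,
    "VIII": _EPS_ABC_BLOCK + _eps_variable(
        "VIII", 5, [_g("acetVIIIe", "O-acetyltransferase", "modification_acetylase", ("sol", 265))],
        _WZX_ANON, _WZY_ANON) + _EPS_TERM,
    "IX": _EPS_RX + _EPS_ABC_BLOCK + _EPS_D + _eps_variable(
        "IX", 6, [_g("epimIXe", "NAD-dependent epimerase", "modification_epimerase", ("sol", 310))],
        _WZX_ANON, _WZY_ANON) + _EPS_TERM,
    "X": _gts("gtXe", [310, 290, 335, 300, 320, 295, 340]) + [
        _g("kpsT_X", "capsular polysaccharide transport ATP-binding protein KpsT", "abc_transporter", ("sol", 230)),
        _g("kpsM_X", "capsular polysaccharide transport permease KpsM", "abc_transporter", ("mem", 6)),
        _g("oxi_Xe", "UDP-glucose 6-dehydrogenase", "modification_oxidoreductase", ("sol", 380)),
    ] + _EPS_TERM,
    "XI": _gts("gtXIe", [305, 325, 295, 315, 300, 330]) + [
        _g("kpsT_XI", "capsular polysaccharide transport ATP-binding protein KpsT", "abc_transporter", ("sol", 235)),
        _g("kpsM_XI", "capsular polysaccharide transport permease KpsM", "abc_transporter", ("mem", 6)),
        _g("acet_XIe", "O-acetyltransferase", "modification_acetylase", ("sol", 275)),
    ] + _EPS_TERM,
}

_FILLER_PRODUCTS = [
    "30S ribosomal protein S4", "50S ribosomal protein L2",
    "translation elongation factor Tu", "chaperonin GroEL",
    "co-chaperonin GroES", "septation ring formation regulator EzrA",
    "N-acetylmuramoyl-L-alanine amidase", "DUF4649 domain-containing protein",
    "ribose-phosphate pyrophosphokinase", "glutamyl aminopeptidase",
    "CHAP domain-containing protein", "DNA gyrase subunit A",
    "phosphoenolpyruvate carboxykinase", "preprotein translocase subunit SecY",
]

_ISLAND_PRODUCTS = [
    "phage portal protein", "phage terminase large subunit",
    "site-specific integrase", "phage antirepressor protein",
    "IS30 family transposase", "relaxase MobA",
    "type IV secretion system protein VirB4", "type IV coupling protein",
    "conjugal transfer protein TraE", "abortive infection protein AbiV",
    "enterocin A immunity protein", "phage tail protein",
]


# --- divergence ------------------------------------------------------------

_BLOSUM = substitution_matrices.load("BLOSUM62")
_SUB_CHOICES: dict[str, tuple[np.ndarray, np.ndarray]] = {}


def _substitution_dist(aa: str) -> tuple[np.ndarray, np.ndarray]:
    if aa not in _SUB_CHOICES:
        others = [c for c in AA20 if c != aa]
        scores = np.array([float(_BLOSUM[aa, o]) for o in others])
        w = np.exp(scores / 2.0)
        _SUB_CHOICES[aa] = (np.array(others), w / w.sum())
    return _SUB_CHOICES[aa]


def diverge_protein(seq: str, target_identity: float, seed: int,
                    indel_rate: float = 0.0) -> str:
    """Diverge a protein to a target ungapped identity (BLOSUM-weighted
    substitutions at sampled positions; deterministic per seed)."""
    if len(seq) < 30:
        raise SyntheticError("sequence too short to diverge (< 30 residues)")
    if not (0 < target_identity <= 100):
        raise SyntheticError("target identity must be in (0, 100]")
    if target_identity == 100:
        return seq
    rng = np.random.default_rng(seed)
    n_sub = int(round(len(seq) * (1 - target_identity / 100.0)))
    positions = rng.choice(len(seq), size=n_sub, replace=False)
    out = list(seq)
    for pos in sorted(positions):
        aa = out[pos]
        if aa not in AA20:
            continue
        choices, weights = _substitution_dist(aa)
        out[pos] = str(rng.choice(choices, p=weights))
    if indel_rate > 0:
        kept = [c for c in out if rng.random() > indel_rate]
        out = kept or out
    return "".join(out)


# --- genome assembly -------------------------------------------------------

@dataclass
class StrainSpec:
    strain_id: str
    species_label: str = "Synthetic species 1"
    cwps_template: Optional[str] = None
    eps_template: Optional[str] = None
    divergence_identity: float = 88.0
    eps_divergence_identity: float = 98.0
    split_cwps: bool = False
    implant_island: bool = True
    transposase_insertions: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.divergence_identity <= 100):
            raise SyntheticError("divergence_identity must be in (0, 100]")
        if self.split_cwps and not self.cwps_template:
            raise SyntheticError("split_cwps requires a cwps template")
        if self.cwps_template and self.cwps_template not in CWPS_TEMPLATES:
            raise SyntheticError(f"unknown cwps template {self.cwps_template}")
        if self.eps_template and self.eps_template not in EPS_TEMPLATES:
            raise SyntheticError(f"unknown eps template {self.eps_template}")


@dataclass
class LocusTruth:
    label: str
    fragments: list[tuple[int, int]]
    locus_tags: list[str]
    roles: dict[str, str]


@dataclass
class StrainTruth:
    strain_id: str
    species: str
    cwps: Optional[LocusTruth] = None
    eps: Optional[LocusTruth] = None
    island_span: Optional[tuple[int, int]] = None
    split_breakpoints: list[int] = field(default_factory=list)


@dataclass
class Truth:
    strains: dict[str, StrainTruth] = field(default_factory=dict)


@dataclass
class _PendingGene:
    product: str
    protein: str
    role: Optional[str] = None
    tag_group: Optional[str] = None  # cwps0, cwps1, eps, island


class _GenomeBuilder:
    def __init__(self, strain_id: str, rng: np.random.Generator):
        self.strain_id = strain_id
        self.rng = rng
        self.seq_parts: list[str] = []
        self.pos = 0  # current length
        self.features: list[GeneFeature] = []
        self.counter = 0
        self.group_tags: dict[str, list[str]] = {}
        self.roles: dict[str, str] = {}

    def spacer(self, length: int | None = None) -> None:
        n = int(length if length is not None else self.rng.integers(90, 150))
        self.seq_parts.append("".join(self.rng.choice(list("ACGT"), size=n)))
        self.pos += n

    def add_gene(self, gene: _PendingGene, strand: str = "+") -> GeneFeature:
        self.counter += 1
        tag = f"{self.strain_id}_{self.counter:05d}"
        coding = "".join(_CODON[c] for c in gene.protein) + "TAA"
        if strand == "-":
            coding = coding.translate(_COMPLEMENT)[::-1]
        start = self.pos + 1
        self.seq_parts.append(coding)
        self.pos += len(coding)
        feat = GeneFeature(
            contig_id=f"{self.strain_id}_chr", start=start, end=self.pos,
            strand=strand, locus_tag=tag, product=gene.product,
            protein=gene.protein,
        )
        self.features.append(feat)
        if gene.tag_group:
            self.group_tags.setdefault(gene.tag_group, []).append(tag)
        if gene.role:
            self.roles[tag] = gene.role
        self.spacer()
        return feat

    def finish(self, species: str) -> Genome:
        seq = "".join(self.seq_parts)
        contig = Contig(
            id=f"{self.strain_id}_chr", length=len(seq), topology="circular",
            replicon_class="chromosome", sequence=seq,
        )
        return Genome(id=self.strain_id, species=species,
                      contigs=[contig], features=self.features)


def _filler_gene(rng: np.random.Generator) -> _PendingGene:
    product = _FILLER_PRODUCTS[int(rng.integers(len(_FILLER_PRODUCTS)))]
    length = int(rng.integers(160, 340))
    aas = np.array(list(AA20))
    return _PendingGene(product=product, protein="M" + "".join(rng.choice(aas, size=length - 1)))


def _island_gene(rng: np.random.Generator, product: str) -> _PendingGene:
    length = int(rng.integers(200, 380))
    aas = np.array(list(AA20))
    return _PendingGene(product=product, tag_group="island",
                        protein="M" + "".join(rng.choice(aas, size=length - 1)))


def _implant_genes(template: list[TemplateGene], identity: float,
                   rng: np.random.Generator, tag_group: str) -> list[_PendingGene]:
    out = []
    for gene in template:
        prot = template_protein(gene)
        if identity < 100:
            prot = diverge_protein(prot, identity, int(rng.integers(2**31)))
        out.append(_PendingGene(product=gene.product, protein=prot,
                                role=gene.role, tag_group=tag_group))
    return out


def generate_strain(spec: StrainSpec) -> tuple[Genome, StrainTruth]:
    """Emit one annotated chromosome plus its truth record."""
    rng = np.random.default_rng(spec.seed)
    b = _GenomeBuilder(spec.strain_id, rng)
    truth = StrainTruth(strain_id=spec.strain_id, species=spec.species_label)

    def fillers(n: int) -> None:
        for _ in range(n):
            strand = "-" if rng.random() < 0.3 else "+"
            b.add_gene(_filler_gene(rng), strand=strand)

    b.spacer(400)
    fillers(12)

    # --- eps locus inside an MGE island ---
    if spec.eps_template:
        eps_genes = _implant_genes(EPS_TEMPLATES[spec.eps_template],
                                   spec.eps_divergence_identity, rng, "eps")
        eps_bp = sum(3 * (len(g.protein) + 1) + 120 for g in eps_genes)
        island_first = island_last = None
        if spec.implant_island:
            target_total = int(rng.integers(45000, 55001))
            up_bp = int(0.6 * max(0, target_total - eps_bp))
            down_bp = max(0, target_total - eps_bp) - up_bp
            made = 0
            i = 0
            while made < up_bp:
                # keep transposases away from the locus-facing edge
                prod = _ISLAND_PRODUCTS[i % len(_ISLAND_PRODUCTS)]
                if made + 1500 >= up_bp and "transposase" in prod.lower():
                    prod = "phage portal protein"
                g = b.add_gene(_island_gene(rng, prod))
                island_first = island_first or g
                made += g.end - g.start + 1 + 120
                i += 1
        for g in eps_genes:
            b.add_gene(g)
        if spec.implant_island:
            made = 0
            i = 1  # start off-phase so the first downstream gene is not a transposase
            while made < down_bp:
                prod = _ISLAND_PRODUCTS[i % len(_ISLAND_PRODUCTS)]
                if made == 0 and "transposase" in prod.lower():
                    prod = "phage tail protein"
                g = b.add_gene(_island_gene(rng, prod))
                island_last = g
                made += g.end - g.start + 1 + 120
                i += 1
            if island_first and island_last:
                truth.island_span = (island_first.start, island_last.end)
        eps_tags = b.group_tags.get("eps", [])
        eps_feats = [f for f in b.features if f.locus_tag in set(eps_tags)]
        truth.eps = LocusTruth(
            label=spec.eps_template,
            fragments=[(eps_feats[0].start, eps_feats[-1].end)],
            locus_tags=eps_tags,
            roles={t: b.roles[t] for t in eps_tags},
        )

    fillers(15)

    # --- cwps locus (possibly split) ---
    if spec.cwps_template:
        template = list(CWPS_TEMPLATES[spec.cwps_template])
        genes = _implant_genes(template, spec.divergence_identity, rng, "cwps0")
        for _ in range(spec.transposase_insertions):
            pos = int(rng.integers(1, len(genes)))
            tnp = _implant_genes([_TNP], spec.divergence_identity, rng, "cwps0")[0]
            genes.insert(pos, tnp)
        if spec.split_cwps:
            roles = [g.role for g in genes]
            if "priming_gt" in roles:
                cut = roles.index("priming_gt") + 2
            else:
                cut = len(genes) // 2
            cut = min(max(cut, 2), len(genes) - 2)
            frag1, frag2 = genes[:cut], genes[cut:]
            tnp_a = _implant_genes([_TNP], 100, rng, "cwps0")[0]
            tnp_b = _implant_genes([_TNP], 100, rng, "cwps1")[0]
            for g in frag2:
                g.tag_group = "cwps1"
            for g in frag1 + [tnp_a]:
                b.add_gene(g)
            breakpoint_a = b.pos
            fillers(120)  # >= 100 kb between the two fragments
            breakpoint_b = b.pos
            for g in [tnp_b] + frag2:
                b.add_gene(g)
            truth.split_breakpoints = [breakpoint_a, breakpoint_b]
        else:
            for g in genes:
                b.add_gene(g)
        tags0 = b.group_tags.get("cwps0", [])
        tags1 = b.group_tags.get("cwps1", [])
        feats = {f.locus_tag: f for f in b.features}
        fragments = []
        for tags in (tags0, tags1):
            if tags:
                fragments.append((feats[tags[0]].start, feats[tags[-1]].end))
        all_tags = tags0 + tags1
        truth.cwps = LocusTruth(
            label=spec.cwps_template, fragments=fragments, locus_tags=all_tags,
            roles={t: b.roles[t] for t in all_tags if t in b.roles},
        )

    fillers(12)
    b.spacer(400)
    genome = b.finish(spec.species_label)
    return genome, truth


# Default 28-strain cohort composition (species, strain id, cwps, eps, split)
DEFAULT_COHORT = [
    ("Synthetic species 1", "S1_01", "E", "V", False),
    ("Synthetic species 1", "S1_02", "F", "I", False),
    ("Synthetic species 1", "S1_03", "F", "VI", False),
    ("Synthetic species 1", "S1_04", "F", "I", False),
    ("Synthetic species 1", "S1_05", "F", "I", False),
    ("Synthetic species 1", "S1_06", "F", "IV", False),
    ("Synthetic species 1", "S1_07", "F", "VI", False),
    ("Synthetic species 1", "S1_08", "F", "I", False),
    ("Synthetic species 1", "S1_09", "F", "I", False),
    ("Synthetic species 1", "S1_10", "F", None, False),
    ("Synthetic species 1", "S1_11", "F", "VI", False),
    ("Synthetic species 1", "S1_12", "F", "I", False),
    ("Synthetic species 1", "S1_13", "F", "VI", False),
    ("Synthetic species 1", "S1_14", "F", "VI", False),
    ("Synthetic species 1", "S1_15", "F", "I", False),
    ("Synthetic species 1", "S1_16", "F", "III", False),
    ("Synthetic species 1", "S1_17", "F", "IV", False),
    ("Synthetic species 1", "S1_18", "F", "VII", True),
    ("Synthetic species 1", "S1_19", "F", "VI", False),
    ("Synthetic species 1", "S1_20", "G", "II", False),
    ("Synthetic species 1", "S1_21", "F", "VII", True),
    ("Synthetic species 2", "S2_01", "H", "VIII", False),
    ("Synthetic species 2", "S2_02", "I", "IX", False),
    ("Synthetic species 2", "S2_03", "G", "X", False),
    ("Synthetic species 2", "S2_04", "E", None, False),
    ("Synthetic species 2", "S2_05", "J", "XI", False),
    ("Synthetic species 2", "S2_06", "K", "XI", False),
    ("Synthetic species 2", "S2_07", "L", None, False),
]


def generate_cohort(n_strains: int | None = None, composition=None,
                    seed: int = 0) -> tuple[list[tuple[Genome, StrainSpec]], Truth]:
    """Generate a cohort of strains (default: the 28-strain composition
    mirroring the observed genotype distribution)."""
    composition = composition if composition is not None else DEFAULT_COHORT
    if n_strains is not None:
        composition = composition[:n_strains]
    if n_strains is not None and len(composition) != n_strains:
        raise SyntheticError("composition does not cover n_strains")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(composition))
    out = []
    truth = Truth()
    for (species, sid, cwps, eps, split), child in zip(composition, children):
        spec = StrainSpec(
            strain_id=sid, species_label=species,
            cwps_template=cwps, eps_template=eps, split_cwps=split,
            transposase_insertions=1 if cwps == "F" else 0,
            seed=int(child.generate_state(1)[0] % (2**31)),
        )
        genome, struth = generate_strain(spec)
        truth.strains[sid] = struth
        out.append((genome, spec))
    return out, truth


def build_refdb():
    """Role-labelled exemplar proteins from the template library.

    This is the packaged reference set used by role inference; users can
    substitute their own via role_inference.read_refdb_fasta.
    """
    from .role_inference import RefProtein

    refs: list[RefProtein] = []
    seen: set[str] = set()
    for kind, templates in (("cwps", CWPS_TEMPLATES), ("eps", EPS_TEMPLATES)):
        for label, genes in templates.items():
            for gene in genes:
                if gene.name in seen:
                    continue
                seen.add(gene.name)
                refs.append(RefProtein(role=gene.role, name=gene.name,
                                       sequence=template_protein(gene), kind=kind))
    return refs
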