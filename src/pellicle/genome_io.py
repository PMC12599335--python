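"""Reading and writing annotated genomes, plus the packaged strain table.

Genomes come in as Bakta-style annotated GenBank flat files or as GFF3 with a
companion FASTA.  All coordinates are stored 1-based inclusive (GenBank
convention).  Reported cluster lengths throughout the package follow the
``end - start`` convention of the packaged strain table (NOT ``end - start +
1``): the printed lengths in that table obey it exactly (e.g. 201332 - 182887
= 18445).
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")

TABLE1_SHA256 = "110f14a2d24ed2c09a41f4e4c851b23a8aae2f2ffb6f84671bae2f4bd3aad7a7"


class GenomeError(ValueError):
    """Invalid genome content (invariant violation)."""


class ParseError(ValueError):
    """Malformed input file."""


class UnsupportedFeatureError(ValueError):
    """Feature the reader does not support (e.g. origin-spanning CDS)."""


class CorruptedFixtureError(RuntimeError):
    """The packaged strain table does not match its recorded checksum."""


@dataclass
class Contig:
    id: str
    length: int
    topology: Literal["circular", "linear"] = "linear"
    replicon_class: Literal["chromosome", "plasmid", "unknown"] = "unknown"
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if self.length < 1:
            raise GenomeError(f"contig {self.id}: length must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise GenomeError(
                f"contig {self.id}: sequence length {len(self.sequence)} "
                f"!= declared length {self.length}"
            )


@dataclass
class GeneFeature:
    """One annotated CDS.

    ``start``/``end`` are 1-based inclusive; ``strand`` is ``+`` or ``-``.
    ``protein`` may contain X (ambiguous) and ``*`` (internal stop; flagged as
    a pseudogene candidate, not an error).
    """

    contig_id: str
    start: int
    end: int
    strand: Literal["+", "-"]
    locus_tag: str
    product: str = "hypothetical protein"
    gene_name: Optional[str] = None
    protein: Optional[str] = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise GenomeError(
                f"{self.locus_tag}: bad coordinates {self.start}..{self.end}"
            )
        if self.strand not in "+-":
            raise GenomeError(f"{self.locus_tag}: strand must be + or -")
        if self.protein:
            bad = set(self.protein) - PROTEIN_ALPHABET
            if bad:
                raise GenomeError(
                    f"{self.locus_tag}: non-amino-acid symbols {sorted(bad)}"
                )

    @property
    def has_internal_stop(self) -> bool:
        return bool(self.protein) and "*" in self.protein.rstrip("*")

    def sort_key(self) -> tuple:
        return (self.contig_id, self.start)


@dataclass
class Genome:
    id: str
    species: str = ""
    contigs: list[Contig] = field(default_factory=list)
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        contig_ids = {c.id for c in self.contigs}
        tags: set[str] = set()
        for f in self.features:
            if f.contig_id not in contig_ids:
                raise GenomeError(f"{f.locus_tag}: unknown contig {f.contig_id}")
            if f.locus_tag in tags:
                raise GenomeError(f"duplicate locus_tag {f.locus_tag}")
            tags.add(f.locus_tag)
        by_id = {c.id: c for c in self.contigs}
        for f in self.features:
            if f.end > by_id[f.contig_id].length:
                raise GenomeError(
                    f"{f.locus_tag}: end {f.end} beyond contig "
                    f"{f.contig_id} length {by_id[f.contig_id].length}"
                )

    def contig(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(contig_id)

    def sorted_features(self) -> list[GeneFeature]:
        return sorted(self.features, key=GeneFeature.sort_key)


@dataclass
class StrainRecord:
    """One strain of the packaged in-study table (cluster coordinates as
    printed; lengths follow the end - start convention)."""

    species: str
    strain: str
    cwps_genotype: str
    cwps_fragments: list[tuple[int, int]]
    eps_genotype: Optional[str] = None
    eps_fragments: list[tuple[int, int]] = field(default_factory=list)
    printed_lengths: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.eps_genotype is None) != (not self.eps_fragments):
            raise GenomeError(
                f"{self.strain}: eps genotype and fragments must be both "
                "present or both absent"
            )

    @property
    def cwps_length(self) -> int:
        return sum(e - s for s, e in self.cwps_fragments)

    @property
    def eps_length(self) -> Optional[int]:
        if not self.eps_fragments:
            return None
        return sum(e - s for s, e in self.eps_fragments)


def _translate_span(contig_seq: str, start: int, end: int, strand: str) -> str:
    """Translate a CDS span with the bacterial code (table 11).

    Ambiguous codons yield X; internal stops are kept as ``*``.  The trailing
    stop, if present, is stripped.
    """
    nt = Seq(contig_seq[start - 1 : end])
    if strand == "-":
        nt = nt.reverse_complement()
    aa = str(nt.translate(table=11))
    return aa[:-1] if aa.endswith("*") else aa


def _replicon_class(record: SeqRecord) -> str:
    text = " ".join(
        [record.description or ""]
        + [
            " ".join(f.qualifiers.get("plasmid", []) + f.qualifiers.get("organelle", []))
            for f in record.features
            if f.type == "source"
        ]
    ).lower()
    if "plasmid" in text:
        return "plasmid"
    if "chromosome" in text:
        return "chromosome"
    return "unknown"


def _genome_from_records(genome_id: str, records: list[SeqRecord], species: str = "") -> Genome:
    contigs: list[Contig] = []
    features: list[GeneFeature] = []
    counter = 0
    for rec in records:
        topology = rec.annotations.get("topology", "linear")
        contig = Contig(
            id=rec.id,
            length=len(rec.seq),
            topology="circular" if topology == "circular" else "linear",
            replicon_class=_replicon_class(rec),
            sequence=str(rec.seq) if len(rec.seq) and set(str(rec.seq)) != {"N"} else None,
        )
        contigs.append(contig)
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            if len(feat.location.parts) > 1:
                raise UnsupportedFeatureError(
                    f"{rec.id}: compound/origin-spanning CDS at "
                    f"{feat.location} is not supported"
                )
            start = int(feat.location.start) + 1
            end = int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
            counter += 1
            tag = feat.qualifiers.get("locus_tag", [f"{genome_id}_{counter:05d}"])[0]
            product = feat.qualifiers.get("product", ["hypothetical protein"])[0]
            gene = feat.qualifiers.get("gene", [None])[0]
            protein = feat.qualifiers.get("translation", [None])[0]
            if protein is None and contig.sequence is not None:
                protein = _translate_span(contig.sequence, start, end, strand)
            features.append(
                GeneFeature(
                    contig_id=rec.id,
                    start=start,
                    end=end,
                    strand=strand,
                    locus_tag=tag,
                    product=product,
                    gene_name=gene,
                    protein=protein,
                )
            )
        if not species:
            species = rec.annotations.get("organism", "") or species
    return Genome(id=genome_id, species=species, contigs=contigs, features=features)


def _read_gff3_fasta(gff_path: Path, fasta_path: Path) -> Genome:
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not seqs:
        raise ParseError(f"{fasta_path}: no FASTA records")
    contigs = [Contig(id=k, length=len(v), sequence=v) for k, v in seqs.items()]
    features: list[GeneFeature] = []
    counter = 0
    with open(gff_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ParseError(f"{gff_path}:{lineno}: expected 9 columns")
            seqid, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            if ftype != "CDS":
                continue
            if seqid not in seqs:
                raise ParseError(f"{gff_path}:{lineno}: unknown contig {seqid}")
            attr = {}
            for kv in attrs.split(";"):
                if "=" in kv:
                    k, v = kv.split("=", 1)
                    attr[k] = v
            counter += 1
            start_i, end_i = int(start), int(end)
            strand_s = "-" if strand == "-" else "+"
            protein = attr.get("translation")
            if protein is None:
                protein = _translate_span(seqs[seqid], start_i, end_i, strand_s)
            features.append(
                GeneFeature(
                    contig_id=seqid,
                    start=start_i,
                    end=end_i,
                    strand=strand_s,
                    locus_tag=attr.get("locus_tag", attr.get("ID", f"gene_{counter:05d}")),
                    product=attr.get("product", "hypothetical protein"),
                    gene_name=attr.get("gene"),
                    protein=protein,
                )
            )
    return Genome(id=gff_path.stem, contigs=contigs, features=features)


def read_annotated_genome(path: str | Path, format: str = "genbank",
                          fasta: str | Path | None = None) -> Genome:
    """Read an annotated genome.

    ``format`` is ``genbank`` or ``gff3+fasta``; for the latter, ``fasta``
    names the companion sequence file (defaults to ``path`` with a ``.fasta``
    suffix).  CDS features lacking a stored translation are translated from
    the nucleotide span with the bacterial genetic code.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "genbank":
        try:
            records = list(SeqIO.parse(str(path), "genbank"))
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
        if not records:
            raise ParseError(f"{path}: no GenBank records")
        return _genome_from_records(path.stem, records)
    if format == "gff3+fasta":
        fasta_path = Path(fasta) if fasta else path.with_suffix(".fasta")
        if not fasta_path.exists():
            raise FileNotFoundError(fasta_path)
        return _read_gff3_fasta(path, fasta_path)
    raise ValueError(f"unknown format {format!r}")


def _genome_to_records(genome: Genome) -> list[SeqRecord]:
    records = []
    feats_by_contig: dict[str, list[GeneFeature]] = {}
    for f in genome.sorted_features():
        feats_by_contig.setdefault(f.contig_id, []).append(f)
    for contig in genome.contigs:
        seq = Seq(contig.sequence) if contig.sequence else Seq("N" * contig.length)
        rec = SeqRecord(seq, id=contig.id, name=contig.id[:16], description=genome.species or contig.id)
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = contig.topology
        rec.annotations["date"] = "01-JAN-1980"  # fixed for byte-identical output
        if genome.species:
            rec.annotations["organism"] = genome.species
        src = SeqFeature(FeatureLocation(0, contig.length), type="source")
        if contig.replicon_class == "plasmid":
            src.qualifiers["plasmid"] = [contig.id]
        elif contig.replicon_class == "chromosome":
            src.qualifiers["chromosome"] = [contig.id]
        rec.features.append(src)
        for f in feats_by_contig.get(contig.id, []):
            loc = FeatureLocation(f.start - 1, f.end, strand=-1 if f.strand == "-" else 1)
            feat = SeqFeature(loc, type="CDS")
            feat.qualifiers["locus_tag"] = [f.locus_tag]
            feat.qualifiers["product"] = [f.product]
            if f.gene_name:
                feat.qualifiers["gene"] = [f.gene_name]
            if f.protein:
                feat.qualifiers["translation"] = [f.protein]
            rec.features.append(feat)
        records.append(rec)
    return records


def write_genome(genome: Genome, path: str | Path, format: str = "genbank") -> None:
    """Write a genome; the emitted file re-reads to an equivalent Genome."""
    genome.validate()
    path = Path(path)
    if format == "genbank":
        SeqIO.write(_genome_to_records(genome), str(path), "genbank")
        return
    if format == "gff3+fasta":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for c in genome.contigs:
                fh.write(f"##sequence-region {c.id} 1 {c.length}\n")
            for f in genome.sorted_features():
                attrs = [f"ID={f.locus_tag}", f"locus_tag={f.locus_tag}",
                         f"product={f.product}"]
                if f.gene_name:
                    attrs.append(f"gene={f.gene_name}")
                if f.protein:
                    attrs.append(f"translation={f.protein}")
                fh.write(
                    "\t".join([f.contig_id, "pellicle", "CDS", str(f.start),
                               str(f.end), ".", f.strand, "0", ";".join(attrs)])
                    + "\n"
                )
        fasta_path = path.with_suffix(".fasta")
        with open(fasta_path, "w") as fh:
            for c in genome.contigs:
                seq = c.sequence or "N" * c.length
                fh.write(f">{c.id}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i : i + 70] + "\n")
        return
    raise ValueError(f"unknown format {format!r}")


_ROMAN_RE = re.compile(r"^[IVXLCDM]+$")


def load_table1_fixture() -> list[StrainRecord]:
    """Load the packaged strain table (28 strains; 55 cluster fragments)."""
    data = resources.files("pellicle.data").joinpath("table1.tsv").read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != TABLE1_SHA256:
        raise CorruptedFixtureError(
            f"strain table checksum mismatch: {digest} != {TABLE1_SHA256}"
        )
    rows = []
    lines = data.decode().splitlines()
    header = lines[0].split("\t")
    for line in lines[1:]:
        rows.append(dict(zip(header, line.split("\t"))))

    by_strain: dict[tuple[str, str], dict] = {}
    order: list[tuple[str, str]] = []
    for r in rows:
        key = (r["species"], r["strain"])
        if key not in by_strain:
            by_strain[key] = {
                "cwps_genotype": None, "cwps_fragments": [],
                "eps_genotype": None, "eps_fragments": [],
                "printed_lengths": [],
            }
            order.append(key)
        entry = by_strain[key]
        frag = (int(r["start"]), int(r["end"]))
        printed = int(r["printed_length"])
        if frag[1] - frag[0] != printed:
            raise CorruptedFixtureError(
                f"{r['strain']} {r['locus_kind']}: end-start != printed length"
            )
        if r["locus_kind"] == "cwps":
            entry["cwps_genotype"] = r["genotype"]
            entry["cwps_fragments"].append(frag)
        else:
            entry["eps_genotype"] = r["genotype"]
            entry["eps_fragments"].append(frag)
        entry["printed_lengths"].append(printed)

    records = []
    for (species, strain) in order:
        e = by_strain[(species, strain)]
        records.append(
            StrainRecord(
                species=species, strain=strain,
                cwps_genotype=e["cwps_genotype"],
                cwps_fragments=e["cwps_fragments"],
                eps_genotype=e["eps_genotype"],
                eps_fragments=e["eps_fragments"],
                printed_lengths=e["printed_lengths"],
            )
        )
    if len(records) != 28:
        raise CorruptedFixtureError(f"expected 28 strains, got {len(records)}")
    return records
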