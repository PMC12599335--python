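# pellicle

Typing of **cell-wall polysaccharide (*cwps*)** and **exopolysaccharide
(*eps*)** biosynthesis gene clusters in annotated (pseudo)lactococcal
genomes.

Lactococcal cell-wall polysaccharides consist of a conserved
peptidoglycan-embedded rhamnan and a surface-exposed polysaccharide
pellicle (PSP) — the phage receptor in most dairy lactococci.  Both are
encoded by a single 18–30 kb *cwps* gene cluster whose proximal region
(dTDP-rhamnose precursors *rmlABCD*, rhamnosyltransferases *rgpAB*, the
*rgpCD* ABC transporter) is conserved, while the PSP-encoding terminal
region — from the priming glycosyltransferase *wpsA* onward — is highly
variable and defines letter-labelled **genotypes**.  Heteropolysaccharidic
EPS is encoded by separate *eps* clusters (conserved *epsRXABCD* block plus
a variable region), usually exported by the Wzx/Wzy (flippase/polymerase)
pathway, and frequently embedded in mobile genomic islands.

`pellicle` turns the manual comparative-genomics workflow for these loci
into a reusable, tested pipeline:

- **genome_io** — GenBank / GFF3+FASTA reading and writing (1-based
  inclusive coordinates; cluster lengths use the `end − start` convention of
  the packaged strain table), plus that 28-strain table as a fixture.
- **similarity** — Smith–Waterman protein alignment (BLOSUM62, BLAST-style
  affine gaps) reporting the combined score `query-cover × %identity`.
- **topology** — Kyte–Doolittle TMH calling, signal-peptide heuristic and
  topology classes (flippase-like 12–14 TMHs; DUF2142 polymerase-like 10–12
  TMHs; co-polymerase-like signal peptide + large loop + ≤ 2 TMHs).
- **locus_finder** — marker-gene anchoring, region growing, split-locus
  fragments, rhamnan/PSP partitioning, advisory QC.
- **role_inference** — per-gene roles with precedence *similarity >
  keyword > topology*, plus positional disambiguation of DUF2142 genes.
- **genotyper** — the three *cwps* criteria (polymerase/co-polymerase
  presence; flippase presence; ≥ 2 PSP genes under 30 % similarity) and an
  explicit variable-region rule for *eps*; novel labels continue the
  established series (letters after D, roman numerals for *eps*).
- **context_scanner** — flank MGE census, genomic-island flag and span
  estimate, ICE-without-oriT note, split/replicon flags.
- **glycan** — monosaccharide-composition masses and genotype→structure
  feature prediction (dTDP-Rha / dTDP-6dTal / UDP-Gal precursors,
  O-acetylation).
- **synthetic_data** — annotated-genome generator with implantable loci,
  controlled divergence, transposase splits, MGE islands and truth tables.

## Worked example

```python
from pellicle import run_pipeline, summarize_fixture, load_table1_fixture
from pellicle.synthetic_data import StrainSpec, generate_strain

# a synthetic strain carrying an F-like cwps locus and a VI-like eps locus
genome, truth = generate_strain(
    StrainSpec(strain_id="FIX1", cwps_template="F", eps_template="VI", seed=11))
row = run_pipeline([genome]).rows[0]
print(row["cwps_label"], row["cwps_organization"], row["eps_pathway"],
      row["island_flag"])
```

prints

```
E canonical_rhamnan_psp wzx_wzy True
```

i.e. the locus mints the first novel label after the historical A–D series
(`E`), shows the canonical rhamnan–PSP organization, and its *eps* locus
uses the Wzx/Wzy pathway inside a mobile island.  The packaged strain
table summarises to the study-level statistics:

```python
s = summarize_fixture(load_table1_fixture())
print(s.n_distinct_cwps, s.n_with_eps, s.cwps_length_min, s.cwps_length_max)
# 8 25 18445 30217
```

And the glycan calculator reproduces the reduced PSP repeat-unit
oligosaccharide mass:

```bash
$ pellicle masscalc "Hex6 P1 red+D"
{
  "composition": "Hex6 P1 red+D",
  "monoisotopic": 1073.316,
  "average": 1073.861,
  "nearest_integer_monoisotopic": 1073
}
```

A CLI wraps the library: `pellicle type`, `pellicle cohort`,
`pellicle simulate`, `pellicle fixture-summary`, `pellicle masscalc`.

## Limitations

Topology calling is a hydropathy heuristic, not a deep-learning predictor
(a TSV ingestion path accepts precomputed TMH/domain tables); island
boundaries are keyword-model estimates, not curated ones; *eps* genotype
boundaries use an explicit stand-in rule (mean variable-region similarity
≥ 80 % plus identical pathway class).  See `docs/methods.md` for the full
model description and parameter rationale.
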