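# Methods

This note documents the models, rules and numerical choices behind
`pellicle`, and what the synthetic-data experiments do and do not show.

## Coordinates and lengths

Coordinates are 1-based inclusive (GenBank convention).  Reported cluster
lengths are computed as `end − start`, **not** `end − start + 1`, because
the packaged strain table prints lengths that obey exactly that arithmetic
(e.g. 201332 − 182887 = 18445); a split locus reports the sum of its
fragment lengths.  Whether the printed boundaries are gene edges or include
intergenic margins is not recorded in the table; detected loci use the
outermost included genes' edges.  Origin-spanning CDS features are rejected
(none occur in generated data).

## Protein similarity

"Similarity" throughout is the **combined score** `qcov × pid / 100`
(query cover × percent identity, both 0–100), the same product used when
these clusters are compared with BLAST by hand.  Alignments are
Smith–Waterman local alignments computed with `Bio.Align.PairwiseAligner`:
BLOSUM62, BLAST-style affine gaps where a gap of length L costs
`11 + L × 1` (PairwiseAligner `open_gap_score = −12`,
`extend_gap_score = −1`).  `pid` counts identities over alignment columns
(gaps included); `qcov` is the aligned query span over the query length,
so the score is direction-dependent — the pipeline always aligns
*candidate gene → reference exemplar*.  The test suite checks optimal
scores against an independent quadratic three-matrix DP; identity counts
are asserted only on constructions with a unique optimal alignment, since
co-optimal alignments need not agree on identities.

Best-hit searches optionally apply a 3-mer containment prescreen
(pipeline default 0.05; 0 disables it in the raw API): subject pairs
sharing almost no 3-mers are scored 0 without running the DP.  Unrelated
random proteins score well below every decision threshold (30/40/80), so
the prescreen does not affect classifications; it exists to keep cohort
runs fast on one CPU.

## Membrane topology

TMHs are called from Kyte–Doolittle hydropathy: window 19, mean threshold
1.6, marked runs merged across gaps ≤ 3, spans clamped to 15–35 residues —
standard first-generation TMH-prediction settings.  The signal-peptide
heuristic requires a K/R in the first six residues, a following ≥ 7-residue
hydrophobic stretch within the first 30, and no further helix starting in
residues 31–60.  Topology classes:

| class | rule |
|---|---|
| polymerase_like | DUF2142 hint and 10–12 TMHs |
| flippase_like | 12–14 TMHs, no DUF2142 hint |
| copolymerase_like | signal peptide, ≤ 2 TMHs, largest loop ≥ 100 residues |
| membrane_enzyme | ≥ 1 TMH otherwise |
| soluble | 0 TMHs |

Precedence is fixed in that order, so a DUF2142 protein with 12 TMHs is
polymerase_like, not flippase_like.  `max_outer_loop` is the longest
non-helix stretch *including the termini*: the co-polymerase archetype
carries its large extracytoplasmic loop before its single C-terminal TMH,
so a strictly between-helix definition could never satisfy the class's own
loop rule.  DUF2142/ALG6/PMT hints come from substring matches on product
annotations plus an optional ingested per-protein TMH/domain TSV
(`topology.load_domain_table`), which lets users substitute deep-learning
topology predictions; no HMM scanning is performed.

## Locus detection

Loci are seeded on conserved marker genes matched by a packaged,
user-replaceable keyword vocabulary (first matching row wins; specific
patterns precede generic ones): the rmlA–D precursor enzymes,
rgpA/B/E/F rhamnosyltransferases and rgpCD transporter for *cwps*; the
epsRXABCD/epsL/orfY vocabulary for *eps*.  Regions grow over adjacent
genes that match the polysaccharide vocabulary or are hypothetical,
terminating after 2 consecutive non-matching genes; transposases count as
matching because they genuinely occur inside these loci.  When keyword
anchoring leaves a fragment undiscoverable — the PSP-side half of a
transposase-split locus has no conserved markers — a similarity fallback
seeds regions where ≥ 2 adjacent genes score ≥ 40 against the kind's
reference exemplars.

Two same-kind regions merge into one split locus iff both contain ≥ 2
vocabulary genes, at least one has a transposase within 3 genes of an
edge, and their canonical-role sets are complementary (union ≥ 6 roles,
overlap ≤ 50 %) — the overlap bound keeps two *complete* loci from being
merged.  At most one pair is merged (the best-supported one); the
cwps locus is partitioned at the first priming-glycosyltransferase call
(genes before it: rhamnan region; from it onward: PSP region), and loci
without one are flagged `non_canonical` (the E/G-like organization).
Size/gene-count QC ranges (18 445–30 217 bp, 16–28 genes for *cwps*) are
advisory only and never reject a locus.

## Role inference

Rule precedence is **similarity > keyword > topology**, mirroring how
these clusters are annotated by hand (sequence homology first, structure
prediction as fallback).  The similarity threshold is a combined score of
40 — loose enough that cross-genotype family members at ~56 % similarity
are still identified, strict enough that unrelated membrane proteins
(best spurious scores ~25) fall through to the keyword/topology routes.
DUF2142-containing genes are ambiguous between polymerase and PSP-rhamnan
transferase; keyword/topology-derived calls are disambiguated by context
(adjacent to a co-polymerase → polymerase; no co-polymerase in the locus →
PSP transferase) and tagged `ambiguous_ycaA_like`, while similarity calls
to role-labelled exemplars are taken at face value.

## Genotype assignment

A *cwps* locus is evaluated against every profile on three criteria:
(i) the (polymerase, co-polymerase) presence pair differs; (ii) flippase
presence differs; (iii) ≥ 2 of the locus's PSP genes — the partition-onward
genes, or all non-rhamnan-core genes in non-canonical loci, excluding
flippase/polymerase/co-polymerase/transposase — score < 30 against the
profile's exemplars.  Criterion iii is asymmetric (query = the new locus)
and evaluated per profile.  A locus matches iff no criterion fires; the
highest mean exemplar similarity wins among matches; otherwise a novel
letter label is minted and the locus becomes the new profile.  The
historical A–D profiles ship flag-level only (criterion iii always fires
against them), so observed loci mint labels from E onward — processing
strains in table order reproduces the E–L series.  Novelty is monotone in
the threshold: lowering it can only un-fire criterion iii.

No published numeric rule defines *eps* genotype boundaries; the package
uses an explicit stand-in, reported as such: a match requires mean
best-hit similarity ≥ 80 on the variable region (genes after the conserved
proximal block) *and* an identical export-pathway class (`wzx_wzy` iff
flippase and polymerase present; `abc_transporter` iff ABC roles present
and both absent; else `undetermined`).  Labels are successive roman
numerals in discovery order.

## Mobility context

The MGE census is a keyword model (transposase, integrase, phage
components, relaxase, T4SS, T4CP, conjugal transfer, defense/immunity
genes) over the 30 kb flanks — wide enough that a 45–55 kb island around a
locus is observable.  A locus is flagged as island-borne when a flank has
≥ 3 MGE hits per 10 genes or the replicon is a plasmid; the span estimate
extends from the locus edges over contiguous MGE-rich annotation
(tolerating 2 consecutive non-MGE genes).  These are heuristic estimates
and are not claimed to reproduce manually curated boundaries.  Relaxase +
T4SS + T4CP without an oriT keyword hit yields a
"non-self-transmissible ICE" note; oriT detection is annotation-keyword
only.

## Glycan masses and structure features

Neutral masses are sums of dehydrated residue masses (Hex 162.0528, dHex
146.0579, HexNAc 203.0794 u monoisotopic) plus one water, with HPO₃
(79.9663) and C₂H₂O (42.0106) increments; borohydride reduction adds two
hydrogens, deuteroborohydride replaces one per label with deuterium
(+2.01410 − 1.00783).  Reports round to 0.001 u; the headline
hexasaccharide comparison uses the nearest-integer monoisotopic neutral
mass, which matches the printed precision of the reference value (1073) —
whether that printed value was monoisotopic or average is not stated, and
nearest-integer monoisotopic reproduces it.  Structure features are
precursor-level only: rml roles → dTDP-Rha; a talose 4-dehydrogenase on
top of an intact Rha pathway → dTDP-6dTal (the enzyme interconverts the
talose and rhamnose pathway intermediates, hence the dependency);
NAD-dependent epimerase → UDP-Gal; acetylase → O-acetylation; UDP-Glc is
always the baseline.  No linkage or NMR-level prediction is attempted.

## Synthetic data: what it emulates

Template proteins are composition-biased random sequences with
role-appropriate architectures (13-TMH flippases, 11-TMH DUF2142
polymerases, signal-peptide + 190-residue-loop co-polymerases), **not**
copies of real proteins; rhamnan-core and conserved-eps proteins are
shared across genotype templates, variable-region proteins are
genotype-specific.  Divergence is applied as BLOSUM62-weighted point
substitutions at sampled positions, giving exact ungapped identity
control; indels sit behind an `indel_rate` parameter (default 0) because
ungapped identity is ill-defined under them.

Default study conditions, chosen once: *cwps* implants diverge to 88 %
identity of their template (within-genotype pairwise identity then stays
above 70 %, the regime in which role recovery and criterion iii are
exercised non-trivially), *eps* implants to 98 % — same-genotype *eps*
clusters in the emulated starter-culture strains are near-identical —
islands span 45–55 kb with the upstream flank larger than the downstream,
split loci place their fragments ≥ 100 kb apart with breakpoint
transposases, and the default 28-strain cohort mirrors the observed
composition (21 + 7 strains; 19 F-like; E and G shared across species; two
split strains; *eps* on 25 of 28).  Nucleotide sequences are deterministic
codon back-translations of the proteins, so GFF3 translation works on
generator output; a fixed template seed plus per-strain seeds derived from
the cohort seed make every run byte-reproducible.

What passing these experiments does **not** show: performance on real
annotation noise (truncated genes, mis-annotated products, fused CDS),
real evolutionary divergence (domain shuffling, indel-rich alignment), or
agreement with curated island boundaries.  The generator's products are
drawn from the same vocabulary family the keyword tables target, so
keyword-route recovery on synthetic data is easier than on arbitrary
annotation pipelines; the similarity route, which dominates under the
default thresholds, does not share this bias.

## Problem sizes

The test suite and the acceptance script run the full chain on a
28-strain synthetic cohort (~110–230 kb chromosomes, ~120–240 genes per
strain), 50 random alignment-oracle pairs, and 15 constructed topology
archetypes — sizes chosen so a complete desk-scale replication runs in
minutes on a single CPU while still exercising every rule at cohort scale.
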