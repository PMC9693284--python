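# Methods

## Scope and data model

The pipeline models a protein-level homology survey of disease
resistance gene analogs (RGAs) in Brassicaceae. Its inputs are the three
artifacts such a survey produces upstream: per-protein domain
annotations (InterProScan-style TSV), BLASTp tabular hit files of
proteomes against 49 curated cloned R genes, and gene coordinates
(GFF3). It does not run the annotation or alignment tools themselves;
the computation starts where their outputs end.

All genomic coordinates are 1-based inclusive (the GFF3 convention)
everywhere inside the package. Conversion to 0-based half-open happens
exactly once, at BED export, and a round-trip test pins the convention.
Protein ids are matched to gene ids by exact string match after
stripping one trailing `.<digits>` transcript suffix — the usual, rarely
stated, glue between a proteome and its annotation.

## RGA classification

Raw domain labels are normalized to ten categories (TIR, CC, RPW8, NBS,
LRR, LysM, kinase, transmembrane, signal peptide, other) by an ordered
case-insensitive substring lookup shipped as editable package data, with
source-tool dispatch for the predictors whose output label carries no
information (TMHMM, SignalP, COILS). The exact evidence vocabulary any
given annotation run uses is not standardized, so the lookup is data,
not code; unknown labels sink to OTHER and never fail.

Classification is a first-match decision table over the domain-category
set (see `rga_classifier` module docstring for the full table).
Noteworthy choices:

- **TIR outranks CC** when both are present (TNL rather than CNL), the
  prevailing convention in the NLR literature; the precedence is a
  config flag, so the opposite convention is one argument away.
- **Transmembrane evidence is required for every receptor call**: RLKs
  and RLPs are membrane receptors by definition, so a kinase without TM
  evidence is NonRGA.
- **RNL detection is off by default.** The subclass vocabulary this
  table reconstructs has no RNL output class, which has a real
  scientific consequence: homologs of RNL reference genes can never be
  called retained, and the curated homolog table indeed shows 0 of 130
  retained for the four RNL references. Keeping the asymmetry explicit
  (rather than "fixing" it by detecting RPW8-NBS-LRR architectures)
  reproduces the survey's semantics; the flag exists for users who want
  the fix. Reference genes themselves carry curated subclass labels, so
  the reference side is unaffected.
- Signal peptides are parsed and stored but carry no weight in the
  table; none of the 14 subclasses conditions on them.

An exhaustive test enumerates all 2^10 domain sets against an
independent restatement of the table as ordered (required, forbidden)
rule pairs, asserting that exactly one rule fires per set.

## Homolog identification

A hit survives iff E-value ≤ 1e-45, aligned length ≥ 148 aa, and
similarity ≥ 60.0%. All three boundaries are **inclusive on the keep
side**: the criteria are stated as removal directions ("greater than
E-45" is removed), which literally keeps the boundary values. "Coverage"
is an absolute aligned length in amino acids, not a fraction of either
sequence. Similarity means BLASTp percent positives when the hit table
carries a `ppos` column; falling back to percent identity is allowed but
logged, since identity is systematically lower and would make the 60%
filter stricter than intended.

Each RGA with at least one passing hit is assigned to exactly **one**
reference gene — minimum E-value, then maximum bitscore, then maximum
similarity, then lexicographically smallest reference name. The
one-to-one rule is forced by the arithmetic of the survey: per-gene
homolog counts sum exactly to the global CDRH total, which requires a
partition, not a many-to-many mapping. One-way BLASTp (references vs
proteomes) is assumed; nothing in the survey's totals suggests a
reciprocal-best-hit step. Hits from proteins that failed RGA
classification are dropped with a logged count, enforcing that every
CDRH is an RGA. Disease labels are then inherited from the reference
gene, so a homolog of a multi-disease gene feeds several disease totals
while feeding exactly one gene total — per-disease totals deliberately
over-count.

## Retention and diversification

Retention is decided purely on subclass labels — the per-gene homolog
table is expressed entirely in labels, so any sequence-level definition
would be answering a different question. Canonical domain sets (the
minimal architecture each label implies) are used only to subcategorize
diversification: removed = canonical(reference) − canonical(homolog),
added = the reverse; truncation / addition / combination follow from
which difference is non-empty. TX and Other-NLR carry an explicit OTHER
element ({TIR, other} and {NBS, LRR, other}), so TN → TX is a
combination (NBS removed, other added) — without it the RNL and TN
combination arithmetic is not expressible. The "one or two domains"
phrasing that usually describes truncation/addition is treated as
descriptive, not a constraint; RNL → LRR-RLP legitimately removes two
domains and adds one. A 16×16 enumeration test checks that every
subclass pair yields exactly one category, NONE exactly on the diagonal,
and that swapping the pair swaps truncation with addition.

## Cluster detection

A cluster is a maximal run of ≥ 2 CDRHs on one chromosome whose span
(first member start to last member end, inclusive) is ≤ 200 kb.
Detection is one greedy left-to-right pass per chromosome over all CDRHs
with post-hoc typing (homogeneous GC_NLR/GC_RLK/GC_RLP vs heterogeneous
GC_H). A single pass is the only reading under which homogeneous and
heterogeneous counts can be disjoint; per-class passes would count a
mixed neighbourhood twice. The observed "2–8 members" is treated as a
range, not a cap — a hard cap would require a split rule nobody defines;
clusters above 8 members log a notice. Input order never matters (the
detector sorts by chromosome, start, end, gene id), output clusters are
disjoint, and the semantics are pinned by an oracle test against a
brute-force maximal-window enumeration on 200 random instances. Strand
is ignored; clustering is positional.

## Synthetic data generator

The generator emulates the survey's statistical structure, not protein
evolution. Defaults are the study conditions:

| parameter | default | rationale |
|---|---|---|
| species × genes | 3 × 1250 | three chromosome-assigned genomes, ≈ 3738 proteins in total |
| subclass mix | surveyed RGA composition (195 TNL … 8 LysM-RLP) + ≈ 20% NonRGA | exercises every subclass and the reject path |
| homolog fraction | 0.85 | surveyed ratio of homologs to RGAs (3172/3738) |
| reference weights | per-gene homolog totals | genes with zero surveyed homologs (TM/CC references) get none |
| retention probability | 0.63 | the surveyed headline retention |
| diversification mix | truncation 0.25 / addition 0.25 / combination 0.5 | combination dominates the surveyed diversified counts |
| true hits | log10 E ∈ [−180, −46], similarity ∈ [65, 95], aligned ∈ [160, 400] | strictly inside all three keep regions |
| decoy hits | one criterion drawn from its fail range (E ∈ [1e-44, 1e-5] or sim < 60 or aligned < 148), chosen uniformly | each filter independently exercised |
| clusters | 6 per species, 2–8 members, span ≤ 200 kb, gaps > 250 kb | unambiguous planted truth |
| chromosomes | 8 × 60 Mb | comfortably holds ≈ 156 isolated entities per chromosome |

Homologs of RNL references are always planted diversified (retention is
impossible under the default classifier, see above), and the recovery
estimator accordingly computes its retention fraction over non-RNL
homologs, with an exact (Clopper–Pearson) binomial 95% CI. Protein
sequences are synthetic residue strings carrying literal per-category
motif tokens, enough to exercise the FASTA path; they are not
evolutionarily meaningful. Domain architectures are the canonical set of
the planted subclass plus optional OTHER/signal-peptide noise, added
only when it provably does not change the classification — a
self-validation pass asserts classify(architecture) equals the planted
subclass, every true hit passes all filters, and every decoy fails at
least one. A single named RNG drives everything; identical
configurations produce byte-identical files.

What passing on synthetic data does **not** show: robustness to
threshold-straddling noise in real alignments (true and decoy hit
distributions are disjoint by construction), paralog confusion between
similar references (each homolog is given one hit), annotation-tool
disagreement, or fragmented assemblies. The generator is a correctness
instrument, not a realism instrument.

## Curated reference tables

The 49 cloned R genes (with curated subclass, accession, pathogens), the
per-gene homolog count table, the disease-by-gene lists and the printed
per-disease totals, and the 20 species codes ship as TSV package data.
The loader re-validates every row (retained + diversified = total;
breakdowns sum to their printed totals) and records, instead of fixing,
the places where the source tables disagree with themselves:

- one diversified cell (At_RRS1) prints a total of 15 with no subclass
  composition; it is kept opaque rather than guessed;
- the grand-total row prints 1181 diversified while the rows sum to 1180;
- three printed per-disease totals (bacterial leaf spot 752, blackleg
  509, clubroot 117) are not reproducible from the per-gene totals plus
  the disease lists (sums give 795, 533, 118);
- the TN-reference retention is narrated as 5/13 while the TN row totals
  22; two narrated diversification counts (411 TNL combinations, 71 NL
  additions) differ from the table-derived 407 and 72.

`verify_aggregates()` recomputes everything reproducible and reports these as
documented anomalies; the gene-name drift Bna_MAPk / Bna_MPK9 is kept as
an alias pair because neither spelling is established as canonical.

## Numerical and procedural choices

- Tie-breaks everywhere are total and deterministic (assignment
  comparator ends at the reference name; cluster sorting ends at the
  gene id; output files are sorted before writing).
- Percentages are reported integer-rounded alongside the raw value,
  matching the style of the aggregates they verify.
- Degenerate inputs: empty FASTA/hit/assignment/cluster inputs yield
  empty outputs plus a logged warning, never an exception; malformed
  rows (non-numeric E-value, start > end) fail loudly with line numbers.
- Problem sizes in the test suite are chosen for tight feedback: the
  shared synthetic study is the full default (3750 genes, ≈ 3200
  homologs — enough for the binomial CI check to be meaningful at
  retention 0.63), the cluster oracle runs 200 instances of ≤ 30 genes
  per chromosome, and the enumeration tests are exhaustive (1024
  architectures, 256 subclass pairs).

## Known limitations

- Retention is label-level; two proteins with the same subclass but very
  different domain counts (e.g. 3 vs 12 LRRs) are "retained".
- The domain-label lookup is a best-effort reconstruction of annotation
  vocabularies and will need editing for new annotation tools — which is
  why it ships as data.
- The greedy-disjoint cluster semantics is one defensible reading of
  "within a 200-kb region"; overlapping-window readings exist and would
  count differently. The oracle test pins this package's reading, not a
  universal definition.
- Per-disease totals over-count by design; there is no per-disease
  deduplication.
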