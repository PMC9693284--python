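# cdrh — cloned disease resistance gene homologs in Brassicaceae

Brassicaceae crops (*Brassica* species, *Camelina sativa*, *Raphanus
sativus*, *Sinapis alba*) lose yield to eleven major fungal and bacterial
diseases, and their wild relatives are a reservoir of resistance (*R*)
genes. This package implements, as a tested and reusable pipeline, the
comparative-genomics workflow used to survey that reservoir: starting from
protein domain annotations, BLASTp hit tables and gene coordinates, it

1. **classifies resistance gene analogs (RGAs)** from domain
   architectures into the 14 standard subclasses of the three RGA
   families — NLR (CN, CNL, NBS, NL, TNL, TN, TX, Other-NLR, RNL),
   receptor-like kinases (LRR-RLK, LysM-RLK, Other-RLK) and receptor-like
   proteins (LRR-RLP, LysM-RLP) — via an explicit first-match decision
   table over the categories {TIR, CC, RPW8, NBS, LRR, LysM, kinase,
   transmembrane, signal peptide, other};
2. **identifies cloned disease resistance gene homologs (CDRHs)**: RGAs
   whose best BLASTp hit against one of 49 curated cloned R genes passes
   all three homology filters — E ≤ 1e-45, aligned length ≥ 148 aa,
   similarity (percent positives) ≥ 60% — each RGA being assigned to
   exactly one reference gene, inheriting its disease labels;
3. **calls domain retention vs diversification** per homolog (retained
   iff the subclass labels match) and subcategorizes diversification as
   truncation, addition or combination by differencing canonical domain
   sets (e.g. RNL = {RPW8, NBS, LRR} → CNL = {CC, NBS, LRR} removes RPW8
   and adds CC: a combination);
4. **detects physical CDRH clusters**: maximal runs of ≥ 2 CDRHs within a
   200-kb chromosomal span, typed homogeneous (GC_NLR / GC_RLK / GC_RLP)
   or heterogeneous (GC_H);
5. **aggregates and verifies**: per-species, per-disease and
   per-reference-gene count tables, checked against the packaged curated
   reference tables (the 49 cloned genes, their per-gene homolog counts
   across 20 Brassicaceae proteomes, and the disease-by-gene lists).

A seeded synthetic-data generator (`cdrh.synthetic`) emulates the whole
study — proteomes with the surveyed subclass composition, planted
homologs whose hit statistics straddle the filter thresholds, controlled
retention probability, planted gene clusters — so every stage is testable
without downloading genomes.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and write their tables under `results/`:

```
python analysis/01_simulate.py --seed 1      # inputs -> scratch/sim
python analysis/02_classify_rgas.py
python analysis/03_identify_cdrhs.py
python analysis/04_domain_evolution.py
python analysis/05_detect_clusters.py
python analysis/06_verify_tables.py           # fixture verification
```

`analysis/04_domain_evolution.py` prints, for the default configuration
(3 × 1250 genes, homolog fraction 0.85, retention probability 0.63):

```
1923/3203 CDRHs retained their reference's RGA domain structure
retention estimate 0.6262 (95% CI 0.6088-0.6433, n=3071) vs planted 0.63
assignment precision 1.000, recall 1.000 over 3203 planted homologs
```

i.e. every planted homolog was recovered and assigned to the right
reference gene, and the estimated retention fraction covers the planted
probability within its exact binomial 95% confidence interval (the
estimate is taken over homologs of non-RNL references; RNL homologs can
never be called retained because the classifier vocabulary has no RNL
output class). `analysis/05_detect_clusters.py` reports

```
18 clusters detected ({'GC_H': 4, 'GC_NLR': 6, 'GC_RLK': 5, 'GC_RLP': 3})
planted-cluster recovery: 18/18 exact member-set matches, 0 spurious
```

and `analysis/06_verify_tables.py` recomputes every reproducible curated
aggregate (retained 1992 of 3172 CDRHs = 63%, per-reference-subclass
retention such as 298/298 for Other-RLK references and 604/1356 for TNL
references, the 70 RNL combination calls, per-disease totals) and lists
the documented internal inconsistencies of the source tables as
anomalies rather than failures.

## Layout

```
src/cdrh/            library: model, formats_io, rga_classifier,
                     cdrh_identifier, domain_evolution, cluster_detector,
                     reporting, synthetic, pipeline; fixtures/ holds the
                     curated reference tables as TSV
analysis/            numbered narrative drivers (see worked example)
scripts/acceptance.py
tests/               pytest suite (property tests seeded/derandomized)
docs/methods.md      models, parameters, design choices, limitations
```
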