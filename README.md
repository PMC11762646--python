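# mirgold

Curation and analysis of "gold standard" microRNA–mRNA interaction
networks.

MicroRNAs (miRNAs) repress target mRNAs through seed complementarity,
usually in the 3′ UTR. Public interaction repositories mix direct-binding
evidence (luciferase reporter assays on wild-type vs site-mutated UTRs,
RNA immunoprecipitation) with indirect readouts (western blot, qPCR) and
high-throughput screens, so the reliability of a downloaded network varies
enormously from record to record. `mirgold` implements an evidence-based
curation pipeline and the downstream network statistics needed to
characterise the resulting post-transcriptional regulatory circuit:

- **Ingestion** of interaction records in four source dialects (PSI-MITAB
  2.7 plus TSV dialects of the miRTarBase / RNAinter / GO-annotation-export
  styles), with identifier canonicalisation through an alias table and full
  audit of rejected rows.
- **Gold-standard filtering**: keep a record iff it comes from an
  IMEx-style curated source, or it is low-throughput *and* carries a
  direct-binding assay (luciferase reporter or RNA-IP). Western blot and
  qPCR alone are insufficient (direct-or-indirect effects); records mixing
  them with an accepted assay are kept. Duplicates collapse to one edge per
  (miRNA, gene) pair with aggregated provenance.
- **Network statistics**: bipartite degrees, *degree classes* (the
  abundance of each degree value — two genes bound by 94 miRNAs each put
  degree 94 in class 2), hub genes (more than 20 distinct miRNA
  regulators), and Venn-style target-set overlaps.
- **Abundance-model selection**: each node's degree is one observation from
  a discrete law on x = 1, 2, …; three candidates are fitted by maximum
  likelihood and compared by AIC = 2k − 2 log L:

  | model | P(x) | parameter |
  |---|---|---|
  | zeta power law | x^(−α) / ζ(α) | α > 1 |
  | log-series | −p^x / (x ln(1−p)) | 0 < p < 1 |
  | geometric | (1−p)^(x−1) p | 0 < p < 1 |

  Two datasets selecting the same AIC-best model are taken as similar in
  distributional shape (e.g. transcription factors vs the remaining mRNAs).
- **Mutual information**: plug-in MI (nats, equal-width 10×10 binning)
  between the number of miRNAs regulating each transcription factor and
  the size of its regulon, with relative MI = MI / min(H(X), H(Y)),
  percentile-bootstrap CIs and a permutation p-value.
- **Enrichment**: hypergeometric upper-tail over-representation of
  annotation terms in the hub set vs the whole gene universe (raw-p
  threshold 0.0005, BH q-values reported; optional term-parent closure).
- **UTR correlations**: pairwise Pearson matrix over 3′UTR length,
  transcript length, verified interactors and two predictors' site counts,
  plus the chance spacing of a fixed k-mer (4^6 = 4096 nt for a 6-mer seed
  match).
- **Synthetic data with ground truth**: a seeded generator emulates the
  pre-filter state of all four repositories — zeta-distributed miRNA
  degrees, preferential-attachment gene degrees, noise edges carrying only
  weak or high-throughput evidence, duplicates, aliases, a planted enriched
  term among hubs, a tunable dependence between TF in-degree and regulon
  size, and planted UTR correlations — so every stage has a recovery test.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (seed 1 by default), writing tables under `results/analysis/`:

```sh
python analysis/01_simulate.py
python analysis/02_integrate.py
python analysis/03_network_degrees.py
python analysis/04_fit_abundance.py
python analysis/05_mi_crosstalk.py
python analysis/06_enrich_hubs.py
python analysis/07_overlap_utr.py
```

Selected output (seed 1):

```
simulated 7804 edges (6267 gold, 1537 noise) over 962 miRNAs and 2548 genes
evidence filter: kept 7587, removed 1683 ({"high_throughput": 866, "no_direct_binding_evidence": 817})
deduplicated to 6267 edges; vs manifest gold: precision=1.0000 recall=1.0000
 mirna: degree class 1 holds 529 nodes (55%); max degree 455 (hsa-miR-SIM-498); 11 nodes above degree 100
hubs (genes with > 20 miRNA regulators): 33 = 1.7% of genes
 mirna: best model zeta_powerlaw (params {'alpha': 1.855}, AIC 3715.2; runner-up dAIC 429.4)
MI = 0.2874 nats (95% CI [0.1891, 0.4215]), rMI = 0.6649, permutation p = 0.000999
r(3'UTR length, predicted sites A) = 0.633
r(3'UTR length, verified interactors) = 0.321
a fixed 6-mer occurs by chance every 4096 nt
```

Reading: the evidence filter removes exactly the records that carry only
weak or high-throughput support, so the deduplicated edge list matches the
planted gold network perfectly (precision = recall = 1). Degree data are
heavy-tailed and AIC prefers the zeta power law by a wide margin (ΔAIC
≈ 429 to the runner-up); the fitted exponent 1.855 recovers the generating
α = 1.8. With the default TF link strength, MI between miRNA in-degree and
regulon size is significantly non-random (permutation p ≈ 0.001), and the
UTR table reproduces the planted pattern of a strong predicted-site
correlation (~0.65) against a weak verified-interactor correlation (~0.3).

The same stages are exposed as a console tool (`mirgold simulate`,
`integrate`, `network`, `fit`, `mi`, `enrich`, `overlap`, `utrcorr`,
`run`), each runnable standalone on the previous stage's files; `mirgold
run` executes the whole pipeline from one YAML config and writes a
machine-readable run report.

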