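# Methods

## Curation model

Interaction records arrive in four dialects: PSI-MITAB 2.7 (15-column,
headerless; interactor A is the miRNA by fixture convention, detection
method in column 7, taxa in columns 10/11) and three TSV dialects
emulating miRTarBase, RNAinter and a GO-style annotation export. Free-text
assay names are normalised onto a controlled vocabulary
{luciferase_reporter, rna_ip, western_blot, qpcr, clip_seq, clash,
microarray, sequencing, other} by an ordered substring table (e.g.
"qRT-PCR", "Real-time PCR" → qpcr; "HITS-CLIP" → clip_seq before the
generic immunoprecipitation rule). Unrecognised labels become `other` —
dirty exports are expected, so normalisation never fails a row.

Rows are rejected (never silently dropped) for: empty miRNA or target id,
no evidence method, non-human taxa, or a species conflict between the two
interactors. A species string that cannot be resolved counts as non-human:
a record that cannot be verified as human must not enter a human network.
Identifier aliases are canonicalised through a two-column mapping table;
conflicting aliases are a hard parse error because an ambiguous mapping
corrupts the edge list silently. Mapping precedes deduplication, so two
records of the same interaction under different identifiers collapse
correctly.

The gold-standard filter keeps a record iff it comes from an IMEx-style
source (MITAB or annotation export; treated as already curated and passed
through), or it is low-throughput and carries at least one accepted
direct-binding assay (luciferase reporter, RNA-IP). Western blot and qPCR
describe methods insufficient *on their own* — they can reflect indirect
regulation — but do not disqualify a record that also carries an accepted
assay. Records with `unknown` throughput are treated as high-throughput:
for a gold standard the conservative reading is the right default. Both
method sets, the throughput requirement and the IMEx pass-through are
configurable on `FilterPolicy`.

Removed records carry exactly one reason, with throughput checked first:
a high-throughput record is removed as `high_throughput` even if its assay
list would also fail the method test.

## Network statistics

The network is bipartite; a node's degree is its number of distinct
partners. The *degree class* of degree d is the number of nodes with
exactly d edges; reconstructing the degree multiset from the classes
recovers the degree sequence exactly (a tested invariant). Hubs are genes
with degree strictly greater than the threshold (default 20, "more than
20"), so degree 21 is a hub and degree 20 is not. Target overlaps are
computed either pairwise (|A|, |B|, |A∩B|, members) or as full Venn
regions keyed by exact membership.

## Abundance models

Each node's degree is one observation; fitting uses the degree
observations directly rather than (degree, abundance) pairs — the two are
likelihood-equivalent and the observation form avoids any ambiguity about
what an "abundance distribution" weights. Candidates, all with support
x ≥ 1 and one free parameter:

- zeta power law, P(x) = x^(−α)/ζ(α), α > 1, ζ via `scipy.special.zeta`;
  fitted by bounded 1-D minimisation of the negative log-likelihood on
  α ∈ (1, 60] to a parameter tolerance of 1e−8.
- log-series, P(x) = −p^x/(x ln(1−p)); the MLE solves
  mean = −p/((1−p) ln(1−p)) by Brent root-finding.
- geometric, P(x) = (1−p)^(x−1) p; closed-form MLE p̂ = n/Σx.

Degenerate data (all degrees 1) sit on the boundary of every model's
parameter space and raise a fit error rather than returning a boundary
estimate. AIC = 2k − 2 log L with k = 1 throughout; near-ties
(|ΔAIC| < 1e−9) break toward fewer parameters, then model name, so
selection tables are fully deterministic. Unfittable models are recorded
as failures without aborting the table. Likelihoods always use the full
support; truncation (at the maximum simulated degree) exists only inside
the inverse-CDF sampler. Goodness-of-fit testing (e.g. bootstrapped KS à
la Clauset) and xmin estimation are deliberately out of scope: the
question asked of these fits is comparative (which model, and do two
datasets agree), not absolute.

## Mutual information

X and Y are discretised independently by equal-width binning over
[min, max] (default 10×10 — the choice is explicit and configurable since
no single binning is canonical), and the plug-in estimator is evaluated in
nats over non-empty cells. Relative MI divides by min(H(X), H(Y)) on the
binned marginals, the maximum MI extractable for the dataset at that
binning; when a marginal entropy is zero (constant vector) rMI is defined
as 0.

Inference: 95% percentile bootstrap CI over paired case resampling
(rebinning each replicate, so the interval reflects the full pipeline),
and significance from a permutation test,
p = (1 + #{MI_perm ≥ MI_obs})/(1 + n_perm). The permutation null rather
than a bootstrap null carries significance because the plug-in estimator
is biased upward on finite samples, which ill-centres a bootstrap null;
the bootstrap is kept for interval reporting. Resampling counts below 100
warn but run. TFs with zero regulated genes, and TFs with zero miRNA
regulators, are removed before the analysis.

## Enrichment

One-sided over-representation only: for a term annotating K of N universe
genes with k hits in a query of n, p = P(X ≥ k) from the hypergeometric
upper tail (`scipy.stats.hypergeom.sf`, log-space stable; verified against
exhaustive draw enumeration for every configuration with N ≤ 12).
Benjamini–Hochberg q-values are computed alongside, and a flag chooses
whether the raw threshold (default 0.0005, the whole genome as universe)
or the q-value drives the significance column — curation tools differ on
this, so both are first-class. Term-parent closure is optional and driven
by a plain two-column parent table, not an ontology parser; full GO DAG
reasoning is out of scope.

## Synthetic data generator

The generator defines the study conditions for every test. miRNA degrees
are i.i.d. zeta(α = 1.8) truncated at the gene count; the exponent was set
once to reproduce the heavy tail of curated human collections, where
roughly 1% of miRNAs exceed 100 validated targets. (No pure zeta can
simultaneously match the head of real curated data — about a quarter of
miRNAs with a single target — which is one documented way the synthetic
degrees are idealised relative to reality.) Each miRNA picks its partners
without replacement with probability proportional to per-gene Pareto
weights, P(W > t) = t^(−(a−1)) with a = 2.0 (weighted sampling via the
Gumbel-top-k trick), inducing a right-skewed gene degree distribution
whose exponent is controlled only indirectly — a fixed bipartite degree
sequence would over-constrain the configuration model.

Noise edges (default 20% of all edges, i.e. n_noise = f/(1−f)·n_gold) are
extra pairs disjoint from the gold set; they receive only weak-assay
low-throughput records or high-throughput CLIP records, and only in the
two non-IMEx dialects — the dialects whose records the filter actually
tests. Gold edges receive one low-throughput record with an accepted
assay (30% also carry an insufficient assay, exercising the
mixed-evidence rule). Duplicate records are added at `dup_rate`; at
`alias_rate` an edge gains an extra record under an alias identifier with
the matching mapping row emitted. Manifests store file *names*, keeping
outputs byte-identical across output directories.

The planted-enrichment table annotates hub genes with the designated term
at `planted_term_odds` × the background odds (background rate 10%, large
enough for an odds-5 signal to be identifiable in hub sets of a few dozen
genes); the other terms annotate 2% of genes uniformly. The TF table
draws in-degree x from the zeta sampler and regulon size y from
Poisson(exp(0.7 + strength·ln(1+x) + ε)), ε ~ N(0, 0.4): strength 0 gives
exact independence, making the permutation-test calibration suite an
honest null. The UTR table uses a Gaussian copula over (3′UTR length,
predicted-site counts A and B, verified interactors) with the planted
latent correlations, marginals mapped by quantile transform to a
log-normal UTR length (median ≈ 1.1 kb) and Poisson counts (means 50, 70
and 6); the moderate marginal skew keeps the Pearson correlations of the
transformed variables within the recovery tolerance (±0.1 at n = 500) of
the latent values. What passing recovery tests do *not* show: robustness
to annotation errors in real databases, to non-monotone TF–miRNA
dependence, or to the excess head-mass of real degree data noted above.

## Pipeline and determinism

All randomness derives from one top-level seed through fixed per-stage
offsets (seed·9973 + offset mod 2^31). Artifacts are plain TSV/JSON with
sorted keys; wall-clock timings go to a separate `timing.json`, so two
runs with the same config and seed are byte-identical elsewhere — a tested
contract. The pipeline validates its config against an explicit schema
(unknown keys are errors), logs to stderr, and writes `run_report.json`
with mutually consistent per-stage counts (kept + removed =
read − rejected).

Default problem sizes (962 miRNAs × 3842 genes for the study-scale runs;
n = 2000–5000 for recovery suites; 200 seeded runs for permutation
calibration; n_boot = n_perm = 1000 for reported MI results, 100–200
inside the calibration loops) were chosen as the smallest sizes at which
the statistical contracts hold with comfortable Monte-Carlo margin.

## Known limitations

- The gene-side degree exponent is controlled indirectly via the weight
  tail; only the miRNA-side exponent is a direct dial.
- Equal-width binning makes MI sensitive to outliers in either margin;
  no kernel or k-NN estimator is provided.
- The evidence vocabulary is substring-based; genuinely novel assay names
  fall into `other` and, for non-IMEx sources, are filtered out.
- The annotation parent map handles plain is-a closure only; no cycle
  detection beyond visited-set termination, no relationship types.
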