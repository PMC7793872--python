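# Methods

## The statistical problem

Merging bulk RNA-seq cohorts from different tumor types puts two signals
into one matrix: tissue-of-origin baselines (large, cohort-specific) and
tumor-associated dysregulation (shared across cohorts). The pipeline is
built to look past the first and extract the second without using class
labels in the selection step itself: global normalization puts all samples
on one scale, a pooled tumor-vs-normal fold-change pre-filter restricts to
genes with a consistent shift, and an unsupervised PCA correlation
selector keeps the genes most informative about the dominant axes of the
merged data.

## Synthetic cohorts

Counts are negative-binomial with the mean/dispersion parameterization
(variance = μ + αμ², the standard RNA-seq convention). For gene *g* in
sample *s* of cohort *c*:

    μ(g, s) = exp(b_g + ln2 · (t_{c,g} + Δ_g · 1[s tumor])) · L_s / L0

- `b_g ~ Normal(baseline_log_mean, baseline_log_sd)` — natural-log
  baseline abundance; `exp(b_g)` is the expected count at the nominal
  library size. Defaults (5.0, 1.5) span roughly 2–5,000 counts over ±2.5σ,
  i.e. a moderately-to-highly expressed transcriptome after the usual
  expression filtering, which is the regime the downstream filters assume.
- `t_{c,g} ~ Normal(0, tissue_effect_sd)` — a per-(cohort, gene) baseline
  shift in log2 units, drawn once per cohort, so cohorts separate in
  expression space and the pipeline has to look past tissue of origin.
  Default sd 0.5 (≈ 1.4-fold typical tissue difference).
- `Δ_g = ±effect_log2fc` for planted genes (split exactly between up and
  down, assigned to the leading gene ids), 0 otherwise. Default 2 (4-fold).
- `L_s ~ LogNormal(libsize_log_mean, libsize_log_sd)`, reference
  `L0 = exp(libsize_log_mean)`. Defaults ln(3·10⁶), 0.35 — a scaled-down
  bulk experiment with ~2–3× depth variation.
- `dispersion` α = 0.2 — mid-range biological dispersion for bulk tumor
  cohorts.
- Gene lengths uniform on [300, 10000] bp, fixed per gene.

The default cohort layout is 150+30, 100+0, 120+20 tumor+normal samples;
the middle cohort has no normals, mirroring the ovarian situation where
solid-tissue normals are unavailable, so the fold-change reference must be
pooled from the cohorts that have them.

One `numpy.random.Generator` seeded from `config.seed` drives every draw
in a fixed order; identical configurations are bit-identical.

What the generator does **not** emulate: batch effects beyond cohort
baselines, gene–gene correlation beyond the planted tumor axis and the
tissue shifts, isoform structure, GC/length-dependent efficiency, outlier
samples. Passing tests therefore demonstrate the pipeline's behavior under
its own modeling assumptions — on real data the tissue axes are stronger
and structured, and fold-change attenuation is gene-dependent.

Companion generators (`synthetic_gene_sets`, `synthetic_interaction_table`)
build enrichment and network inputs with known ground truth: a few gene
sets seeded 60% from planted genes among uniform background sets, and hub
regulators wired to planted targets with signs concordant with the planted
direction, plus unsigned background edges.

## Normalization conventions

- **CPM filter**: "CPM above 0.5" is a strict inequality; "at least 90% of
  samples" means ≥ ceil(0.9·n). The ceiling makes the rule well defined at
  any n. CPM filtering precedes the annotation filter.
- **Upper-quartile normalization**: after dividing each gene by its length
  in kb, each sample's 75th percentile (linear-interpolation percentile)
  of *nonzero* values is computed; the sample is rescaled to the geometric
  mean of these quartiles. The geometric mean is a symmetric,
  order-independent reference, and restricting to nonzero values makes
  the quartile robust to the zero inflation of filtered counts. One pass
  equalizes the quartiles exactly (so the operation is idempotent);
  expression is then log2(x + 1).
- **logFC**: difference of mean log2 expression, tumors minus normals,
  pooled over all cohorts (normals come only from cohorts that have
  them). The |logFC| > 1 filter is strict. Per-cohort fold changes are
  available as a diagnostic but are not used for filtering.

## Feature extraction

PCA treats samples as observations and genes as variables; genes are
mean-centered but **not** variance-scaled (values already share the
normalized log2 scale, and scaling would erase the magnitude information
the fold-change pre-filter acts on; `--scale` exists for sensitivity
analysis). The decomposition is a full SVD; retained components are the
smallest *m* whose cumulative explained-variance fraction reaches the
target (default 0.6, with a 1e-12 numerical guard).

Selection is per component: the cutoff q_j is the 95th percentile (linear
interpolation) of |r(·, j)| over all candidate genes; gene g is selected
by component j iff |r(g, j)| > q_j (strict, so boundary ties drop out)
and the two-sided correlation p-value — t = r·√((n−2)/(1−r²)) on n−2
degrees of freedom — is below 0.001. The percentile is applied per
component to absolute correlations, which is the reading that selects
both up- and downregulated genes symmetrically and is invariant to
component sign flips. No multiple-testing correction is applied by
default (an optional per-component Benjamini–Hochberg mode exists).
Zero-variance genes are flagged and never selected rather than raising.

A structural property of this rule worth knowing: each retained component
can select at most ~5% of the candidates, so the signature set cannot
exceed roughly `1 − 0.95^m` of the candidate pool even when per-component
selections barely overlap. With m ≈ 10–20 that ceiling is ~40–64% — the
selector trades recall for a high-precision, component-diverse subset.
The reference synthetic study shows exactly this: precision 1.0,
sensitivity ≈ 0.35–0.39 with m ≈ 10–12.

## Enrichment and networks

Enrichment p-values are hypergeometric upper tails P(X ≥ k) (right-tailed
Fisher exact test) with universe N = the measured transcriptome (genes
surviving the annotation filter) rather than the union of the gene sets —
the background should be the assayable set; a flag overrides it. Sets
smaller than 3 after universe intersection are reported untested. Scores
are −log10 p (p floored at the smallest positive double), significance at
score ≥ 1.3 ⇔ p ≤ 0.05. A BH-adjusted column is reported but does not
drive the flag.

Network growth is deterministic: seed = the unused focus gene with the
most focus-gene neighbors (lexicographic tie-break); repeatedly add the
adjacent node with the most edges into the current set, preferring focus
candidates, until 35 molecules or no connected candidate remains; focus
genes are consumed by the first network that takes them, non-focus
connectors may recur. Direct and indirect edges are both traversable (a
flag restricts to direct). Each network is scored with the same
hypergeometric kernel (universe = all graph nodes, successes = focus
genes in the graph, draws = network size, hits = focus members) and
ranked by score, ties broken by focus count then molecule set. Commercial
network tools keep their growth algorithms unpublished; this rule is this
package's own specified, reproducible choice — only the molecule cap and
the scoring distribution are taken as fixed conventions.

The regulator activity call is a sign-consistency z: over a regulator's
signed targets with fold-change entries, each target contributes +1 if
edge sign and direction agree (activating∧up or inhibiting∧down), −1
otherwise; z = Σc/√n with the conventional |z| ≥ 2 threshold. Targets with
conflicting edge signs are skipped as ambiguous. This is an open analog
of proprietary upstream-regulator predictions, not a reproduction.

## Degenerate inputs and errors

Zero library sizes, samples with no nonzero counts, constant expression
matrices, missing gene lengths, signature genes outside the universe, and
regulators without signed targets all raise typed errors naming the
offending sample/gene/field. Fewer than two fold-change candidates yields
an empty signature set (reported, not an error), which is how a pure-noise
run terminates.

## Problem sizes

The reference study conditions are 3,000 genes × 420 samples across three
cohorts, analyzed in a few seconds; tests and the acceptance script use
these sizes (recovery and null-control runs over three seeds) plus smaller
fixtures (≤ 400 genes) for oracle comparisons, keeping the full suite
under a minute.

## Known limitations

- The UQ reference in the original EDASeq-style workflows (within-lane
  full-quantile variants) is not uniquely determined by common usage; the
  geometric-mean-of-quartiles reference used here preserves the defining
  property (equalized post-correction upper quartiles) and is symmetric
  in the samples.
- Sensitivity of the selector is structurally capped (see above); users
  wanting recall should raise the percentile's complement or union over a
  larger variance target knowingly.
- The enrichment universe and the interaction graph are user-supplied;
  results are only as complete as those resources.
- No batch-effect correction: cohort baselines are handled only through
  global normalization and the unsupervised selector's component
  structure.
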