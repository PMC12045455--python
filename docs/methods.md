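# Methods

## Clone tables and clonotype identity

A repertoire sample is a table of clone records (nucleotide and
amino-acid CDR3, V/J calls, template count, frequency, productive flag)
plus metadata (subject, timepoint, compartment, T cell subset,
stimulation condition, platform). Three dialects are read and written:
AIRR-C Rearrangement TSV, an immunoSEQ-style tab-delimited export, and
an RNA-biopsy dialect that may carry frequencies without template
counts. On load, non-productive rearrangements (out-of-frame or
stop-containing) are retained but flagged and excluded from every
frequency denominator, the prevailing convention for DNA-based
repertoire sequencing; frequencies are always recomputed over
productive templates so upstream normalisation choices cannot leak into
downstream statistics.

Clonotype identity is a configurable key:

* `nt` — nucleotide CDR3. Default for DNA-platform comparisons
  (baseline vs MLR vs post-transplant blood), where the rearrangement
  sequence is directly comparable.
* `aa` — amino-acid CDR3, used for convergence analysis.
* `aa_v` — amino-acid CDR3 plus V-gene family. Default for
  cross-platform matching (DNA blood ↔ RNA biopsy ↔ single-cell),
  because RNA assays report transcript-level sequences whose nucleotide
  coordinates are not guaranteed to align with the DNA assay's. This is
  a documented package choice; the platform-matching rule used in the
  original analyses of such data is typically unstated.

Merging by key sums templates, recomputes frequencies, and (under
amino-acid modes) retains the number of distinct contributing
nucleotide sequences per key — the raw material of the convergence
statistic. Merges conserve total template count exactly.

## Reactive-clone calling

Given a divided (CFSE-low) MLR population and the pre-transplant
unstimulated repertoire of the same subject, a clonotype is called
reactive iff it is detected in the divided population with at least
`min_templates` (default 2) templates and either (a) it is absent from
the baseline — fold recorded as infinite — or (b) its divided-pool
frequency is at least `fold_threshold` (default 2) times its baseline
frequency. The baseline for this criterion is always the
*pre-transplant unstimulated* repertoire, even when post-transplant
cells served as MLR responders. The `min_templates` floor guards
against singleton sorting errors; raising `fold_threshold` can only
shrink the called set (monotonicity is property-tested).

Pathway labels are pure set membership over multiple MLRs: direct-only
→ direct; indirect-only → indirect; both, or detected only in a
late-only MLR → undefined. Subset labels (CD4/CD8) come from the sorted
population of origin, never from sequence; a clone claimed by both
subsets is flagged ambiguous and excluded from subset-specific
statistics. The non-reactive control set is the pre-transplant
repertoire minus the union of all proliferated populations, and is
disjoint from the reactive set by construction.

Whether additional minimum-frequency filters beyond the two-fold rule
were applied in the original analysis is not documented; none are
applied here. Divided-population frequencies are computed within the
sorted subset.

## Tracking statistics

For a clone set S and sample t, the cumulative frequency F(S, t) is the
sum of sample frequencies over members of S (absent members contribute
zero). Derived quantities:

* fold change: F(S, post) / F(S, pre); infinite flag when the set is
  undetected pre-transplant.
* relative detection rate (reactive vs non-reactive control), both sets
  restricted to clones detected pre-transplant. Clone level:
  (#reactive re-detected post / #detected pre) ÷ (same for
  non-reactive). Template level: (F(R, post)/F(R, pre)) ÷
  (F(N, post)/F(N, pre)). Values above 1 indicate reactive-specific
  expansion beyond any lymphopenia-driven background. These formulas
  are reconstructions from figure legends and the y = 1 enrichment
  reference line of the source analyses; the panel formulas themselves
  are not reproduced in the available text.
* "Detected" means at least one template (any positive frequency on
  RNA platforms).

Significance: the pooled two-proportion z test (via statsmodels)
compares detection proportions; Fisher's exact test (scipy) compares
the hyperexpanded compartment against baseline. The Fisher test runs at
two levels: `clone` (default — counts of clonotypes above vs below the
1% threshold) and `template` (templates inside vs outside hyperexpanded
clones). The template level weighs abundance rather than clone counts
and retains resolution at desk-scale repertoire sizes (~10³ clones),
where clone-level counts saturate the hypergeometric tail well short of
the significance the abundance shift carries. Both tests report raw
p-values per timepoint; a Bonferroni correction across timepoints is
available but off by default, matching common figure-legend practice.

Diversity metrics: clonality 1 − H/ln R with H the natural-log Shannon
entropy of productive clone frequencies and R the number of unique
clones (R = 1 returns 1 by convention); R20 is the smallest count of
clones, largest first, whose cumulative frequency reaches 0.20, divided
by R, without interpolation (tie-order invariant); hyperexpanded clones
are those strictly above 1% frequency. Convergence is the mean number
of distinct nucleotide CDR3s per amino-acid CDR3, optionally restricted
to a set; restriction uses amino-acid keys so newly arisen synonymous
variants of a set member count toward its group.

`subset_normalize` divides CD3-measured clone frequencies by a
flow-cytometric subset fraction (capped at 1) to place unsorted
pre-transplant data on the same scale as sorted post-transplant
subsets; the output intentionally no longer sums to 1.

## Cross-compartment and single-cell

Species calls use per-cell human and pig transcript totals: human if
the human share ≥ purity (default 0.9), pig if ≤ 1 − purity, ambiguous
otherwise or when total transcripts < 200. The thresholds are package
defaults — chosen so pure cells are unambiguous and 50/50 doublets are
always ambiguous — since the original analyses describe the species
split as "easily distinguishable" without stating a cutoff. All
non-human cells are removed before TCR matching. Only productive
TCR-beta contigs participate in matching (reactive sets are
TCRB-defined, so an alpha-only match never marks a cell reactive);
cells with several beta chains match if any chain matches and are
flagged. Cluster occupancy is an exhaustive tally per cluster of cells,
reactive cells and per-pathway counts. Clone tracing reports each key's
frequency in each sample of a compartment chain, with chain membership
defined as detection in every sample.

## The synthetic-data generator

The generator produces every input the pipeline consumes, with complete
ground-truth labels. Design and defaults:

* **Baseline repertoire.** 1,000 clones; clone sizes from a smoothly
  truncated power law (density exponent 2.2, largest/smallest size
  ratio 15, inverse-CDF sampling) normalised to probabilities and
  multinomially sampled to 10,000 templates. The truncation keeps the
  largest pre-transplant clone below ~1% and the top-5 near 3% of
  templates — the pre-transplant regime of a healthy adult repertoire —
  so hyperexpansion is a strictly post-transplant phenomenon. A
  lognormal size alternative is available. CDR3s are random in-frame
  codon strings (no stop codons, canonical C/F flanks); no V(D)J
  recombination or sequencing-error model is attempted, so sequence
  content carries no biological signal beyond codon-consistent nt/aa
  pairing.
* **Reactive designation.** Per subset (CD4 fraction 0.6), reactive
  clones are drawn uniformly: 40/25 direct CD4/CD8, 30/10 indirect,
  with 3% of the smaller pathway set shared (labelled `both`) —
  mirroring the direct > indirect, CD4 > CD8 proportions and the small
  pathway overlap seen in MLR data.
* **MLR divided pools.** Reactive clones of the stimulated pathway and
  sorted subset carry weight `baseline_freq × E`, E = 3 × a long-tailed
  lognormal multiplier (minimum expansion `mlr_expansion_factor`).
  Non-reactive clones contaminate the pool with probability 5% per
  clone, entering at `baseline_freq × U(0.05, 0.5)` *relative to the
  proliferated mass* — i.e. the divided pool is dominated by truly
  proliferating cells and bystanders appear near their blood frequency
  times a weak factor. This is the sorting-contamination regime the
  two-fold rule is designed to clean up; under it the rule recovers
  spiked reactive sets with recall and precision ≥ 0.9.
* **Post-transplant course.** Per timepoint, a non-reactive clone's
  frequency scales by the lymphopenia background fold `nf` (default 2);
  a reactive clone's by `nf + (rf − nf)·c`, where `rf` is the reactive
  fold (default 2, 5, 20, 20 at POD14/28/33/49 — rejection at the last
  two) and `c` is a mean-one lognormal immunodominance factor
  (sigma 1.5) drawn once per clone and held fixed across timepoints, so
  the same immunodominant clones recur. When `rf = nf` the reactive
  excess vanishes exactly and the null is exchangeable by construction.
  A mild per-clone lognormal drift (sigma 0.3) perturbs everything;
  weights are renormalised and sampled to depth. Clones whose applied
  fold is ≥ 2 acquire Poisson(0.5) extra synonymous nucleotide variants
  splitting their templates, generating the convergence signal. A
  `subset` option restricts and renormalises within CD4 or CD8,
  emulating the flow sort applied to post-transplant samples.
* **Compartments.** Lymphocele/biopsy subsamples multiply reactive
  clones' sampling weights by an enrichment factor (default 5) before a
  small-depth multinomial draw (default 500), emulating
  reactive-infiltrated tissue at shallow RNA-based depth.
* **Single cells.** 40 human- and 40 pig-prefixed genes with
  Dirichlet-random base expression; pure cells draw 99.5% of 1,000
  transcripts from their own species (ambient contamination 0.5%),
  doublets 50/50. A configurable fraction of human cells carry TCR-beta
  clonotypes sampled from the truth repertoire, reactive ones
  concentrated in one cluster.
* **Randomness.** One seed governs all stages through named substreams
  (`baseline`, `mlr_<pathway>_<subset>_<tp>`, `longitudinal_<subset>_<tp>`,
  `immunodominance`, ...), so any stage regenerates independently and
  byte-identically.

What passing tests on this generator do and do not show: they verify
the calling rule, set arithmetic, statistics and demultiplexing logic
against known truth under realistic frequency structure; they do not
certify performance on real data, where PCR/sequencing error, V-call
ambiguity between platforms, clonotype collisions, batch effects and
non-multinomial overdispersion all exist and are out of the generator's
scope.

## Numerical and design choices

* Frequencies validate to 1 within 1e-9 after any load or merge.
* Ordering ties (top clones, reactive-set reports, R20 ranking) break
  lexicographically by key, making every output deterministic.
* Degenerate inputs: empty stimulated samples yield empty sets with a
  warning; zero denominators in relative detection return an infinite
  flag with a diagnostic naming the zero term; degenerate contingency
  tables return p = 1 with a warning; single-clone repertoires have
  clonality 1 and R20 1 by convention.
* Desk-scale problem sizes (10³ clones, 10⁴ templates, 10³ cells) are
  the package's default study conditions; every quantity scales to
  larger repertoires through the same code paths.

## Known limitations

* Pathway labels are set-membership only; no modelling of avidity,
  antigen specificity or semi-direct presentation.
* No raw-read processing: input begins at clone tables and contig
  annotations.
* No clustering, embedding, differential expression or cell-type
  reference annotation; cluster labels are consumed, not produced.
* The cross-platform `aa_v` key can merge distinct nucleotide clones
  sharing an amino-acid CDR3 and V family; at repertoire scale this
  collision rate is small but nonzero, and is the price of matching
  DNA-defined sets in RNA-derived data.
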