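# Methods

This note documents the models and procedures implemented in `bescreen`,
the parameters that matter, the synthetic-data generator used to validate
them, and the design decisions taken where the method left genuine choices.

## Edit-outcome annotation

A cytosine base editor deaminates cytosines on the protospacer strand
within a fixed window. Window coordinates are given as distance from the
PAM with the PAM-adjacent base at d = 1; the default BE3 window d ∈ [13, 18]
maps to 5′-based protospacer positions p = 21 − d ∈ [3, 8]. Because editing
of individual cytosines is partial and approximately independent, every
non-empty subset of the k window cytosines is treated as a possible DNA
outcome (2ᵏ − 1 outcomes; a configurable cap, default k ≤ 10, bounds the
enumeration, and a `full_edit_only` switch restricts to the fully edited
outcome for sensitivity analyses).

Outcomes are projected onto transcript models (pre-mRNA sequence, exon
intervals, CDS span; 0-based half-open coordinates throughout). A sense
placement maps protospacer position p to transcript position
`offset + (p − 1)` as C→T; an antisense placement maps to
`offset + (20 − p)` as G→A. Projection verifies the reference base and
raises on any library/model inconsistency.

Consequences per outcome and transcript:

- non-coding transcript → **non_coding**, regardless of effect;
- substitution in the two intronic bases of any junction (canonical GT/AG)
  → **splice**. This ±2 rule is a deliberate simplification of a full
  effect-predictor ontology; substitutions here can only touch the donor G
  (via antisense G→A) or acceptor G, both of which break the canonical
  dinucleotide;
- otherwise affected codons are re-translated jointly (standard nuclear
  code, ATG-only start): any stop gain → **nonsense**, any other residue
  change → **missense**, an unchanged protein → **synonymous**. Any edit in
  codon 1 is **nonsense** by the first-codon rule.

A guide collapses to the maximum severity over all outcomes and isoforms
under the fixed order
`empty_window < synonymous < non_coding < missense < nonsense < splice`;
a guide with no window cytosine is `empty_window`, and a guide placed only
on non-coding isoforms is `non_coding`. When a guide hits both coding and
non-coding isoforms the coding isoforms take precedence — the precedence is
a package decision, exposed as such. The most deleterious amino-acid change
(nonsense over missense, then smallest residue number) supplies the lookup
key into the clinical map; among equally deleterious changes the class is
the maximum under `B/LB < NA < VUS < P/LP`. Guides without placements
(non-targeting controls) have no defined category and are written as `NA`.

Correctness is checked against an independent oracle that mutates the full
transcript string, re-splices, re-translates the entire protein and
compares junction dinucleotides (see `tests/oracles.py`).

## Fitness scoring

Counts follow the MAGeCK-count layout (`sgRNA`, `gene`, one column per
sample) with a separate sample sheet (cell line, timepoint T0/TEND,
replicate). Guides with a zero count in **any** sample are removed first;
each retained column is divided by its median, making the per-sample
median of normalized counts exactly 1. The phenotypic score per replicate
is x = log₂((R′ + ε)/(C′ + ε)) with endpoint R′ and baseline C′ and
ε = 0.05 on the median-normalized scale; the guide's LFC is the mean over
replicate pairs. Note that ε deliberately shrinks large depletions: at
500× depth a true 4-fold dropout (LFC −2) has expectation ≈ −1.8. This is
a property of the scoring formula, not an estimation error, and all
validation bands account for it.

Calibration uses the negative controls (AAVS1-targeting + non-targeting):

- **bounds** — q and 1−q quantiles (default q = 0.05) of negative-control
  LFC, by sorted linear interpolation (numpy type-7; the quantile method
  matters for reproducing any specific printed bound);
- **empirical p** — two-sided rank p = min(1, 2·min(r_lo+1, r_hi+1)/(n+1))
  with r_lo = #{negatives ≤ x}, r_hi = #{negatives ≥ x}. The +1 correction
  keeps p positive and slightly conservative (nominal rate ≈ 0.047 at
  n = 300 negatives). This control-empirical test replaces rank-aggregation
  p-values from external screen tools; it is monotone in |LFC| relative to
  the controls and fully self-contained;
- **tiers** — outside the bounds with p < 0.05 → low priority, p < 0.01 →
  high priority.

ROC contrasts rank guides by depletion (score = −LFC, direction explicit
per contrast) and report the AUC, which equals the Mann–Whitney pair
statistic with midrank ties; the implementation delegates to
scikit-learn's `roc_curve`/`auc` and is tested against brute-force pair
counting. The standard contrasts are iSTOP vs each negative class (with an
optional on-target-score > 0.5 filter), nonsense+splice vs
synonymous+empty-window within essential genes, and P/LP vs B/LB within
essential genes. Category depletion enrichment is a one-sided Fisher exact
test on (category vs reference) × (LFC < lower bound), i.e. the
hypergeometric upper tail of the observed overlap.

## Harmonization

Per cell line, nLFC = (x − μ_neg)/σ_ctrl with μ_neg the mean
negative-control LFC and σ_ctrl the sample (n−1) standard deviation of the
pooled positive (iSTOP) and negative controls — the controls are samples
of their populations, hence the n−1 denominator. nLFC is exactly invariant
to shifting or positively rescaling all LFCs. Whether synonymous-outcome
targeting guides belong in the negative set is ambiguous in the field; the
default uses AAVS1 + non-targeting only.

Guides present in every cell line (screens may drop different guides at
the zero-count filter; Ward geometry is undefined on missing cells, and
imputation would invent signal) form the guide × cell-line matrix. Guides
with |nLFC| strictly > 1 in at least one line are "significant" and are
clustered with Euclidean distance and Ward's linkage; the tree is cut to
k clusters (default k = 4, exposed as a flag since no cut rule is
canonical). Cluster labels are deterministic given the input order and are
renumbered by first appearance. For each (cluster, label) pair — labels
being genes or clinical classes — enrichment is the hypergeometric upper
tail P(X ≥ k) with population N (all clustered guides), K label members,
cluster size n. Raw p-values are reported and flagged at 0.05, with a
Benjamini–Hochberg column added for convenience; no correction is applied
to the flags themselves, matching the raw-p presentation conventional for
these cluster plots.

## Synthetic screens

The generator emulates the screen design at reduced scale (defaults: 10
genes of which 4 essential, 40 guides/gene plus 100 AAVS1, 100
non-targeting, ~16 iSTOP and ~28 empty-window controls, ≈ 660 guides
total; the real library tiles ~11,000 guides over 27 genes).

- **Gene models**: random CDSs (ATG start, single stop, no premature
  stops, length divisible by 3) flanked by UTRs; with probability 0.6 a
  GT…AG intron is inserted at a codon boundary; some genes carry an extra
  non-coding isoform; a non-coding safe-harbor locus hosts the
  AAVS1-targeting negatives.
- **Library**: guides tile every NGG site on both strands. Within
  essential genes, sites whose predicted outcome is a premature stop
  become iSTOP positive controls (capped at half the available sites so
  targeting loss-of-function guides remain) and sites without window
  cytosines become empty-window negatives. On-target scores are Beta(2,2).
- **Effects**: expressed directly on the LFC scale. iSTOP controls and
  nonsense/splice guides in essential genes get −2 (configurable);
  pathogenic-annotated missense guides in essential genes are also planted
  deleterious, so the clinical contrast carries signal; everything else —
  including all negative controls — is neutral. Under multi-cell-line
  archetype designs, essential genes are assigned per-line effect profiles
  round-robin, while iSTOP controls keep the full depletion in every line
  (they represent pan-essential function).
- **Counts**: T0 mean = depth · a_g with depth 500 (the screen's minimum
  per-guide coverage) and abundance a_g ~ LogNormal(0, 0.25); endpoint
  mean = T0 mean · 2^effect; counts are negative-binomial with dispersion
  α = 0.2 (variance m + αm²), two independent replicates per timepoint.
  The NB/LogNormal choice is a minimal model of pooled-screen
  overdispersion, validated only by self-consistency.
- **Clinical map**: planted over predicted protein changes — nonsense
  changes are mostly P/LP, missense mostly VUS/B-LB, with a fraction left
  absent (NA).

What the simulations do **not** emulate: editing-efficiency heterogeneity
(beyond the on-target-score covariate), guide-sequence biases, off-target
effects, and realistic library abundance skew — with the narrow
LogNormal(0, 0.25) abundance spread, replicate log-count correlations are
≈ 0.2, far below the ≈ 0.9 typical of real screens where abundance spans
decades. Passing the validation suite therefore demonstrates correctness
of the algorithms under the stated noise model, not robustness to every
artifact of real data.

## Validation designs and problem sizes

Three fixed study designs drive the acceptance checks and
`scripts/acceptance.py`:

- **Effect recovery** (`effect_screen_config`): 40 genes, 20 essential,
  ≈ 5,500 guides with ≈ 330 planted at LFC −2 (≈ 6% of the library, small
  enough that median normalization stays anchored on neutral guides) and
  600 negative controls. The recovered effect is reported as the mean LFC
  of planted guides **minus the mean negative-control LFC**: median
  normalization shifts all raw LFCs slightly when a depleted fraction is
  present, and centering on the negatives isolates the planted effect.
  The design size keeps the standard error of that mean near 0.04, well
  inside the ±0.3 recovery band around −2 (which itself absorbs the ≈ 0.2
  ε-compression described above).
- **Null calibration** (`null_screen_config`): ≈ 2,400 guides, all
  effects zero. The fraction of guides with empirical p < 0.05 must sit
  within 3 binomial standard deviations of 0.05, and the synonymous,
  empty-window and negative-control LFC distributions must be mutually
  indistinguishable (Mann–Whitney p > 0.01).
- **Archetype harmonization**: four per-cell-line effect profiles
  (lethal everywhere / lethal in exactly one of three lines), 30 guides
  each, iid Gaussian noise sd 0.3 — Ward k = 4 must recover the planted
  partition (adjusted Rand index ≥ 0.8) with each cluster's planted label
  as its top enrichment.

## Numerical and degenerate-input conventions

Quantiles: numpy linear interpolation. Standard deviations: ddof = 1 for
control sets. Constant columns make Pearson r undefined → NaN with a
warning. Zero medians, empty control sets, σ_ctrl = 0, empty ROC sides and
k > n clusterings raise validation errors; degenerate Fisher tables return
p = 1 with a warning. Ties in Ward merges follow scipy's deterministic
ordering. All simulation randomness flows from explicit integer seeds via
`numpy.random.default_rng`; derived child seeds come from
`numpy.random.SeedSequence`.

## Known limitations

Consequence calling handles substitutions only (the only mutation class a
cytosine base editor produces here) and a ±2 splice rule; UTR and
regulatory effects are not modelled. The empirical p-value is a
rank-based stand-in for count-model tests and has granularity 2/(n+1).
Clinical-class assignment uses exact protein-change string matching.
Cross-cell-line integration assumes a shared library and control behavior;
batch effects beyond the control-based rescaling are out of scope.
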