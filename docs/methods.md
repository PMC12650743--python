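# Methods

## The ratio transformation

For a target gene *t* and index gene *i*, DiRT replaces the target's read
count in sample *j* by the ratio `r_j = RC_t(j) / RC_i(j)` of **raw**
counts (no pseudocount by default). Because any per-sample multiplicative
factor cancels in the ratio, the transformation is exactly invariant to
rescaling any sample's counts by a positive constant — depth, global batch
scaling and any drift shared by the pair are removed without estimating a
normalization factor. This invariance is the method's central property and
is enforced by tests at < 1e-12 relative tolerance (it is exact in real
arithmetic; for integer-scaled counts the IEEE quotient is bit-identical).

### Index selection

Candidate indexes are ranked per target by the NSD of the ratio vector
across **control samples only** — condition-affected samples must not
inform reference choice. The NSD is not given a formula in the source
description; it is implemented as the coefficient of variation (sample
standard deviation with n−1 denominator, divided by the mean), the
standard reading of "normalized standard deviation". Alternatives
(`sd/median`, sd of the log ratio) are switchable via `nsd(kind=...)`.
Genes with any zero control count are ineligible as indexes (their ratio
is undefined); ties in NSD break toward the lexicographically smaller gene
id for cross-platform determinism. Self-pairing is forbidden; reciprocal
pairs (A/B and B/A) are allowed. The scan is blocked over targets so the
full 10,000 × 9,999 sweep runs in bounded memory; results are independent
of block size (tested), and the blocked path is checked exactly against a
per-pair brute-force scan.

### Testing and filtering

Each pair's control and case ratio vectors are compared with a two-tailed,
two-sample equal-variance (pooled Student) t-test on the linear ratio
scale — the same kernel used for every gene-level baseline, so method
comparisons differ only in the normalization. Degenerate inputs follow a
fixed convention: zero pooled variance with equal means gives t = 0,
p = 1; with unequal means, p = 0. Benjamini–Hochberg adjustment uses an
explicit family size *m* equal to the full candidate count (n_targets × k;
100,000 at full scale) — a required argument, never a silent default,
because the adjusted values scale directly with it. Adjustment happens
*before* index filtering, across all tested pairs.

A pair is retained only if its index gene shows no response to the
condition: RLE-normalized gene-level BH-adjusted p **strictly greater**
than 0.05 (a boundary value exactly at 0.05 is excluded), adjusted at the
candidate-gene family size. This is the only guard against DEG–DEG
artifact pairs (an up-regulated target over a down-regulated index
doubles the apparent contrast); no directional filter is applied. A
target's significance is the minimum adjusted p among its retained pairs;
targets whose pairs are all filtered are omitted and counted, and can be
rescued by extending the candidate list (`extend_candidates`, default 100).

### Zero handling in case samples

Index genes are zero-free in controls by construction but may hit zero in
a case sample. Default policy drops such pairs with a warning;
`zero_policy="pseudocount"` instead adds 0.5 to both numerator and
denominator counts of the affected pairs.

## Baselines

CPM, RLE and TMM are native implementations sharing the t-test/BH kernel:

- **CPM** — counts / column total × 1e6; columns sum to 1e6 exactly.
- **RLE** — geometric-mean pseudo-reference over genes positive in every
  sample; factor = linear median of count/reference ratios. (The log-scale
  median used by some implementations coincides for odd gene counts; the
  frozen oracle fixture uses an odd count.)
- **TMM** — reference sample = the one whose 75th percentile of count
  proportions is closest to the mean; per-sample log2 fold changes (M) and
  average abundances (A) over genes positive in both libraries are doubly
  trimmed (0.30 per tail on M, 0.05 on A, the published defaults,
  configurable), averaged with inverse asymptotic-binomial-variance
  weights, and the factors rescaled to product 1. Values match an
  independently run reference implementation to ~1e-12 on a
  composition-biased fixture (frozen in the tests).

Normalized values enter the t-test on the linear scale, matching the
ratio scale of the transformation (a log2 option is available on the
`NormMatrix` consumer side by transforming `data`); abundance filtering
takes the `n_top` genes by mean CPM over *all* samples and reports the
mean CPM of the last admitted gene as the effective threshold.

## Null split

`make_null_design` relabels samples into artificial control/disease arms
with exact per-time-point quotas, deterministically by sorted sample id
(optionally shuffled by seed). On the reference layout — 19 control and 18
case subjects at 3 time points, quotas 10 and 9 — the artificial control
arm holds 30 original controls and 27 original cases. Because both arms
mix the original groups, any genuine effect cancels; running the full
pipeline under the relabeling (`run_null_pipeline`, with index-validity
statistics recomputed under the artificial labels) should leave no small
adjusted p-values.

## Synthetic data

`simulate_counts` draws `count(g, j) ~ NB(mean = λ_g · s_j · b_{t(j)}(g) ·
f_g^[j is case]`, variance `= mean + φ·mean²)`:

- λ_g log-normal baseline abundance (defaults: log-mean ln 100, log-sd
  1.5 — a wide blood-like dynamic range);
- s_j log-normal library scale (log-sd 0.3);
- b per-time-point batch multipliers, either **global** (one factor per
  time point shared by all genes — removable by any scaling
  normalization) or **module** (each gene follows its own trajectory —
  removable only by a within-module ratio, the regime where the pairwise
  transform has its advantage; log-sd 0.4 default);
- planted DEGs with fold f_g (default 20 genes, folds 2–4, random
  direction) and planted **stable partners** that copy their target's
  batch trajectory exactly, so the target/partner ratio carries counting
  noise only.

Planted DEGs and partners are drawn from genes above the median baseline
abundance (`plant_abundance_quantile = 0.5`): the workflow analyzes
abundantly expressed genes only, so truth planted in the low-count tail
would be unmeasurable by construction. The generator emulates
multiplicative structure and NB counting noise; it does not model
per-subject biological correlation across time points, cell-type
composition shifts, gene-length effects or read-level artifacts, so
passing tests demonstrate correct behavior under multiplicative batch and
depth distortions, not robustness to every property of real blood data.

### Study conditions used by the tests and acceptance script

- **Structural funnel** — 10,500 genes (log-mean ln 300, log-sd 1.2,
  emulating the abundant analyzed universe), 3 time points × 4/3 samples;
  top 10,000 genes × k = 10 gives exactly 100,000 pairs. These sizes keep
  the full-scale scan under a minute while preserving the printed pair
  count.
- **Null runs** — 500 genes, 3 time points × 5/5 samples, φ = 0.1,
  library log-sd 0.3, no DE; the pipeline keeps the top 20% of genes
  (n_top = 100), the same abundant fraction the full-scale analysis keeps
  (10,000 of ~50,000). At this scale single chance pairs (p ≈ 4e-5)
  occasionally cross the BH boundary: index selection conditions on low
  control-sample variance, which deflates the pooled variance and
  amplifies chance mean differences — visible at n = 15 vs 15 with a
  family of 1,000 but absorbed at full scale (57 vs 54 samples,
  m = 100,000, where the reference null split bottoms out at adjusted
  p ≈ 0.11). In 53 of 60 seeded runs the filtered database contains no
  adjusted p < 0.05.
- **Co-regulation / sensitivity scenario** — 1,000 genes, 6 time points ×
  10/9 samples, module batches (log-sd 0.4), φ = 0.01, twenty 2-fold DEGs
  each with a stable partner. Six time points give each gene's batch
  trajectory enough structure that chance trajectory matches are rare
  (with only 3 time points, ~6% of genes match a target's trajectory by
  luck and partner recovery is capped near 30% for any dispersion), and
  the low dispersion puts ratio stability in the regime where the planted
  partner dominates: partners rank in the top-10 candidates for ~100% of
  targets, and the median adjusted p of planted DEGs via the ratio
  transform beats the CPM-scale median in 10/10 seeds.

## Numerical choices

- NSD scan: ratios formed by direct division (matching the brute-force
  reference bit for bit on contiguous vectors), two-pass variance; the
  k-smallest selection takes all values ≤ the kth order statistic and
  re-sorts by (value, gene id), so boundary ties are deterministic.
- BH: step-up computed by reverse cumulative minimum of m·p_(j)/j, capped
  at 1; permutation-equivariant and exactly equal to the standard
  procedure when m = n.
- t-test p-values via the Student-t survival function; vectorized row-wise
  over pair/gene matrices.
- Result tables are written with `%.17g` formatting and read back with
  correctly-rounded float parsing, so round-trips are lossless.

## Known limitations

- The equal-variance t-test on linear ratios is the prescribed kernel; it
  is not robust to heavy-tailed ratios at very small sample sizes (see the
  null-run discussion above). No moderated-variance or rank-based
  alternative is provided.
- Two-group designs only; no paired tests, no >2 conditions, no
  gene-length/GC correction.
- KEGG/DAVID-style enrichment of result gene lists is out of scope; the
  comparison module exports ranked lists for external tools.
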