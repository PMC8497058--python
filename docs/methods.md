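# Methods

## Scope and data model

`mitoshape` implements the single-cell quantitative layer of studies that
relate mitochondrial fission/fusion balance to stem/progenitor cell states:
per-cell shape metrics computed from skeletonized mitochondrial networks,
bivariate subpopulation gating with contingency statistics, robust quadrant
gating of two-channel immunofluorescence intensities, cell-cycle reciprocity
between transcriptomic clusters, and single-hit limiting-dilution frequency
estimation. Real inputs enter at the summary level that upstream software
produces: per-cell component-length tables (skeletonization), per-cell
intensity pairs (image quantification), per-cell cluster/phase labels
(single-cell RNA-seq scoring), and well-outcome tables (dilution assays).
Image segmentation, transcriptomic clustering and phase scoring are
deliberately upstream and out of scope.

## Shape metrics

For a cell with component lengths `l_1..l_n` (micrometres):

- `fission = n / sum(l_i)` (1/um) — higher means more fragmented;
- `fusion_k = 100 * (sum of k largest l_i) / sum(l_i)` (percent), reported
  for k = 1 and k = 5; `fusion_k = 100` whenever `n <= k`.

Both metrics describe the steady-state shape, not the kinetics of either
process. `fusion_k` is invariant to rescaling all lengths; `fission` scales
as `1/c`. Splitting any component can only raise `fission` and can only
lower `fusion1`. Readers reject nonpositive, NaN or infinite lengths instead
of dropping them: silent filtering would shift the metric distributions.

## Fission–fusion simulator

The synthetic-data generator is a fragmentation–coagulation chain on a
conserved length partition:

- fission of component `i` at rate `k_fis * l_i` with a uniform breakpoint,
  rejected when either daughter would fall below `min_len`;
- fusion of every unordered pair at rate `k_fus` (well-mixed mass action).

Events are selected by the Gillespie rule and the chain runs for a fixed
number of *accepted* events (default 5000) from a single fused component,
which makes generation cost deterministic and is ample burn-in for the
component counts used here (relaxation takes on the order of a few hundred
events). Rejection, rather than absorption, of sub-`min_len` daughters
mimics the optical resolution floor of confocal skeletonization without
breaking mass conservation. Detailed balance of total rates puts the mean
component count near `sqrt(2 * (k_fis/k_fus) * total_length)`, so the rate
ratio is the single knob along the fragmented–hyperfused axis.

Defaults: `total_length = 100 um` (a typical epithelial cell's network
mass), `min_len = 0.2 um` (roughly the confocal resolution limit). Three
named archetypes are provided and were fixed from the balance relation, not
fitted: `HYPERFUSED` (ratio 0.02, ~2–4 components, fusion5 = 100),
`INTERMEDIATE` (ratio 2.5, ~20 components, fission ~0.22, fusion5 ~52 —
inside the intermediate gate), `FRAGMENTED` (ratio 12, fission ~0.45).
Populations are mixtures of archetypes with planted weights; each cell's
stream derives from a master seed plus the cell index (SeedSequence), so
populations are reproducible element-by-element.

The rates are calibration knobs for producing realistic steady-state shape
distributions; they make no claim about biological fission/fusion kinetics,
and the simulator has no spatial embedding or branched topology (components
are linear length masses). Passing recovery tests therefore demonstrates
that the analysis correctly measures what was planted in data with the
assumed statistical structure — not that real microscopy data satisfy that
structure.

Intensity tables are two-channel log-normal lo/hi mixtures; the two binary
hi states are coupled through their Pearson correlation (the joint hi–hi
probability is clipped into the Fréchet-feasible range when necessary).
Default log-sd 0.25–0.3 gives the well-separated, right-skewed dot-plot
clouds typical of immunofluorescence; real data differ in having continuous
rather than binary expression states. Cluster × phase tables are
multinomial with planted per-cluster phase probabilities. Dilution wells
are binomial under the single-hit model below.

## Bivariate gating

Gates on the (fission, fusion5) plane: `HF` for `fusion5 > 80` (strict),
`Int` for `fission` in [0.15, 0.4] and `fusion5` in [40, 80] (closed), else
`Other`. The published box bounds do not state inclusivity; declaring the
HF bound strict and the Int box closed makes the gates a partition with the
boundary cell `fusion5 = 80` assigned to Int. Cells in neither box form a
single `Other` class. Gate counts across populations are compared with the
Pearson chi-square statistic without continuity correction; an expected
count below 5 triggers a warning, not an automatic exact test. The inverse
fission–fusion5 relationship within a population is summarized by Pearson r
and by the residual standard error `sqrt(SSR/(n-2))` of the OLS fit of
fusion5 on fission — the regression orientation is a convention (r itself
is orientation-free), and the residual SD is this package's explicit
operationalization of "scatter around the regression line", which the
source figures show but do not define numerically.

## Quadrant gating

Per-channel signal threshold: `median + 1.5 * MAD` with the MAD left
unscaled (no 1.4826 normal-consistency factor). The threshold never falls
below the median, so at most half of the sample defining it can exceed it;
"hi" is strictly greater than the threshold so that a degenerate MAD of 0
does not flood the hi quadrants with ties. Whether thresholds should come
from each population or from a common sample is genuinely open in this
assay class; the default computes them on a designated reference (control)
population and applies them uniformly — cross-population percentages are
only comparable against a common cut — with per-population thresholds
available behind an explicit flag.

## Cell-cycle reciprocity

With three phase labels (G0/G1, S, G2M) consumed as given, the reciprocity
of clusters A and B within a population is `(G1%/S%)_A / (G1%/S%)_B`. It is
invariant to the population's total cell count and inverts exactly under
swapping A and B. A zero S percentage raises an error naming the offending
group rather than silently regularizing a headline ratio; `pseudocount=True`
adds 0.5 to every phase cell first. Fold-changes against a reference
population are reported per population, so both the minimum and the mean
across comparators can be read off.

## Limiting-dilution frequency

Under the single-hit Poisson model, a well seeded with `d` cells is negative
with probability `exp(-f d)`; outcomes are binomial with a complementary
log-log link and log-dose offset. The MLE of `log f` is found by root
finding on the score (the likelihood is unimodal in `log f` for interior
data; verified by grid scan in tests), and the 95% interval comes from the
profile likelihood at the chi-square(1) cutoff 3.841 — preferred to a Wald
interval because the likelihood is skewed at 24 wells per dose. The search
is capped at `f = 1`, the largest value the model can mean. Datasets with
every well negative (or positive) have no interior maximum and are returned
as one-sided bounds with a `boundary` flag instead of a point estimate.
Frequencies are reported both per cell and in the conventional "1 in N"
form. Two groups are compared by a likelihood-ratio test of a shared
frequency against separate ones (1 df). Goodness-of-fit tests of the
single-hit assumption and multi-group trend tests are out of scope.

## Numerical choices and problem sizes

Root finding uses Brent's method with `xtol = 1e-14` on the score and
`1e-12` on profile endpoints; mass conservation in the simulator holds to
1e-9 relative. Top-k sums use `numpy.partition`; ties among equal lengths
cannot affect the sum. Monte-Carlo checks in the test-suite and acceptance
script use 100–200 cells per condition for simulator grids, 200–600 cells
for gate recovery, 500 cells per population for quadrant recovery, 10^4
cells per cluster for reciprocity convergence, and 150–500 replicates for
limiting-dilution calibration — sizes at which the binomial/multinomial
sampling error is comfortably inside the stated tolerances.

## Known limitations

- The simulator's fission kernel (rate proportional to length, uniform
  breakpoint) and constant-pair fusion kernel are the simplest choices
  consistent with tubule geometry and a well-mixed cytoplasm; no kinetic
  data constrain them.
- Quadrant recovery inherits a small upward bias from the lo-state tail
  crossing the MAD threshold (about +2 to +3 percentage points at the
  default log-sd), which is the expected behaviour of a robust threshold
  applied to overlapping mixtures, not an estimator defect.
- Reciprocity ratios are ratios of percentages and thus noisy when S
  fractions are small; the multinomial sampling error at 10^4 cells is
  about 4% relative.
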