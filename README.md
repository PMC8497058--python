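# mitoshape

Single-cell quantitative machinery for studies of mitochondrial
fission/fusion balance in stem/progenitor cell biology. Cells whose
dynamin-related fission machinery (Drp1) is partially repressed shift from
a hyperfused mitochondrial network toward smaller fused networks; this
package quantifies that shift cell by cell and carries the associated
statistics through to subpopulation abundances, marker co-expression,
cell-cycle residency and stem-cell frequency.

It is aimed at analysts who already have the standard upstream outputs —
skeletonized mitochondrial component lengths per cell, background-corrected
two-channel immunofluorescence intensities, single-cell cluster/phase
labels, and limiting-dilution well tallies — and need the downstream
numbers reproducibly.

## What it computes

For a cell with mitochondrial component lengths `l_1..l_n` (um):

- **[Fission]** = `n / Σ l_i` (um⁻¹), and **[Fusion_k]** =
  `100 · (Σ of k largest l_i) / Σ l_i` (percent), for k = 1 and 5;
- **bivariate gates** on the (Fission, Fusion5) plane — hyperfused
  `HF: Fusion5 > 80`, intermediate `Int: Fission ∈ [0.15, 0.4] and
  Fusion5 ∈ [40, 80]`, else `Other` — with Pearson chi-square comparison of
  gate abundances across populations and the residual SD of the OLS fit of
  Fusion5 on Fission as the scatter measure;
- **robust quadrant gating** of two-channel intensities at the per-channel
  threshold `median + 1.5 · MAD` (MAD unscaled), thresholds taken on a
  reference population and applied uniformly;
- **G1-to-S reciprocity** between two clusters,
  `(G1%/S%)_A / (G1%/S%)_B`, per population and versus a reference;
- **limiting-dilution frequency** under the single-hit Poisson model
  `P(well negative | dose d) = exp(−f·d)`: maximum-likelihood `f` with a
  95% profile-likelihood interval and a likelihood-ratio comparison of two
  groups.

A stochastic fission–fusion simulator (Gillespie fragmentation–coagulation
on a conserved length partition) plus intensity/phase/well generators
produce all four input kinds with planted ground truth, so every estimator
is exercised by parameter recovery. See `docs/methods.md` for models,
assumptions and limitations.

## Worked example

Simulate two populations of 120 cells — a control mixing 55% hyperfused
with 45% intermediate cells and a "weak knockdown" mixing 38/62 — plus
spheroid-formation wells at 1-in-75 vs 1-in-750 stem-cell frequency, then
run the pipeline. `demo.yaml`:

```yaml
populations:
  - name: control
    n_cells: 120
    archetypes:
      - {archetype: hyperfused, weight: 0.55}
      - {archetype: intermediate, weight: 0.45}
  - name: weak_kd
    n_cells: 120
    archetypes:
      - {archetype: hyperfused, weight: 0.38}
      - {archetype: intermediate, weight: 0.62}
lda:
  - {group: weak_kd, frequency: 0.0133}
  - {group: control, frequency: 0.00133}
```

```sh
mitoshape simulate --config demo.yaml --out demo --seed 3
mitoshape metrics --in demo/cells.csv --out demo/metrics.csv
mitoshape gate    --in demo/metrics.csv --out demo/gates.csv
mitoshape lda     --in demo/lda.csv --compare weak_kd control
```

The gate step prints:

```
             frac_HF  frac_Int  frac_Other  n_HF  n_Int  n_Other  fusion1_hi  pearson_r  residual_sd
population
control     0.541667  0.433333       0.025    65     52        3    0.233333  -0.981459     4.725132
weak_kd     0.391667  0.583333       0.025    47     70        3    0.083333  -0.975960     5.203307
chi2=5.549 df=2 p=0.0624
```

The recovered hyperfused fractions (54.2% and 39.2%) sit within binomial
error of the planted 55% and 38%; the weak-knockdown population shows the
expected enrichment of the intermediate gate, a lower fraction of cells
dominated by a single element (`fusion1_hi`), and slightly more scatter
about the inverse Fission–Fusion5 regression. The LDA step prints:

```
weak_kd: frequency 0.01387 (1 in 72.1), 95% CI [0.008778, 0.02087]
control: frequency 0.001511 (1 in 661.9), 95% CI [0.0009494, 0.002294]
LR test weak_kd vs control: stat=46.02 p=1.173e-11
```

i.e. the planted tenfold difference in self-renewing-cell frequency is
recovered (1 in 72 vs 1 in 662, truths 75 and 750) and decisively detected.

The same operations are available as library functions
(`mitoshape.metrics_table`, `gate_table`, `quadrant_table`, `reciprocity`,
`lda_fit`, ...), which the CLI wraps thinly.

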