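# circaphase

Detection of circadian (24-hour) rhythmic genes from replicated bulk-RNA-seq
time courses, and analysis of how their peak times are organized on a gene
regulatory network.

The package is built for the common two-condition design in chronobiology:
an organism entrained to a 12:12 light:dark cycle is assayed at two constant
temperatures (e.g. 18 °C vs 25 °C), in two independent experiments with
different sampling schemes, and one asks (i) which genes cycle at each
temperature, (ii) how the distribution of their peak phases differs between
conditions, and (iii) whether genes that are close on an interaction network
peak at similar times. All inputs can be produced by a built-in simulator
with known ground truth, so every estimator in the package can be checked by
parameter recovery.

## Method

**Rhythm detection (cosinor).** For each gene and experiment, expression
(log2(TPM+1)) is regressed on a fixed-period harmonic,

    y(t) = β₀ + β₁ cos(ωt) + β₂ sin(ωt),   ω = 2π/24,

by ordinary least squares. Amplitude is A = √(β₁²+β₂²), the peak phase
φ = (24/2π)·atan2(β₂, β₁) mod 24 (the ZT hour of the fitted maximum), and
significance is the F-test of the harmonic terms against the intercept-only
model with (2, n−3) degrees of freedom.

**Dual-experiment consensus.** A gene is called cycling only if p < 0.1 in
*both* experiments and its two phase estimates agree within 3 h on the
circle (|Δφ| < 3, with |Δφ| = min(|φ₁−φ₂|, 24−|φ₁−φ₂|)). Under the null the
per-experiment p-values are uniform and the phases independent and uniform,
so the chance-pass probability is 0.1² · (6/24) = 0.0025 and the expected
number of false cyclers among n tested genes is 0.0025·n — an analytic FDR
that needs no resampling. For a 6774-gene filtered transcriptome this is
≈17 expected false calls.

**Phase statistics.** Consensus phases (circular mean of the two
experiments' estimates) are compared between conditions with the
Watson–Wheeler uniform-scores test; bimodal phase distributions are
summarized by a two-component von Mises mixture fitted by EM; paired phases
of genes cycling at both temperatures are measured by the
Jammalamadaka–SenGupta circular correlation, and systematic phase advance is
tested by an exact binomial sign test about the zero circular median.

**Network phase organization.** On the largest connected component of a
gene-interaction network, every pair of cycling genes at geodesic distance
d ≤ 6 contributes |Δφ|; per-distance medians are regressed on d, and
significance per distance comes from a permutation null that re-places the
cycling-gene set uniformly over the network (5000 permutations by default,
0.025/0.975 null quantiles, add-one two-sided empirical p).

## Worked example

Simulate a full study (two experiments × two temperatures, 1000 genes, 12%
cyclers per condition with a built-in 1.9-h phase advance at 18 °C, plus a
300-node network on which the 18 °C cyclers are placed assortatively), then
run the whole pipeline:

```
circaphase simulate --config demo/cfg.yaml --seed 17 --outdir demo/sim
circaphase run --matrix demo/sim/expression_tpm.tsv \
               --samplesheet demo/sim/samples.csv \
               --network demo/sim/network_edges.tsv \
               --n-perm 1000 --seed 17 --outdir demo/out
```

prints

```
circaphase run summary
========================================
genes passing expression filter: 994
cyclers at 18C: 118 (expected false positives 2.49, FDR 0.021)
cyclers at 25C: 120 (expected false positives 2.49, FDR 0.021)
common cyclers: 70
Watson-Wheeler 18C vs 25C: W=3.96, p=0.138
phase peaks at 18C: ZT5.38, ZT22.15
phase peaks at 25C: ZT17.88, ZT22.53
circular correlation of common cyclers: 0.963
phase advance at 18C (V1): 69/70 genes, median +1.95 h, p=1.2e-19
phase advance at 18C (V2): 70/70 genes, median +1.96 h, p=1.69e-21
network: 300 nodes / 900 edges (largest component)
phase-distance slope at 18C: 0.707 h/step (p=0.118, df=4; significant distances: [1, 3, 4, 5])
phase-distance slope at 25C: 0.373 h/step (p=0.352, df=4; significant distances: [1, 3, 4, 5])
```

Reading the output: 994 of 1000 simulated genes clear the median-TPM > 5
expression filter; ~118 genes are called cycling per condition, of which
only ≈2.5 are expected to be false (the analytic FDR of 2%); 70 genes cycle
at both temperatures, with near-identical phase order between conditions
(circular correlation 0.96) and an almost universal ~2-h phase advance at
18 °C — recovering the simulator's built-in 1.9-h shift. On the network,
the median phase difference of adjacent cyclers (2.13 h) falls far below
the permutation null's 0.025 quantile (3.93 h): network neighbors are
synchronized, as constructed. Per-gene fits, cycler tables, the
per-distance profile with null quantiles, and a JSON manifest are written
to `demo/out/`.

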