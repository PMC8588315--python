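# soiltox

Analysis pipeline for soil-ecotoxicology pot experiments that cross a
phenolic contaminant gradient (*o*-cresol at 0, 0.1, 1, 10 and 50 mg kg⁻¹
dry matter of soil) with exposure time (days 15, 30, 45) and a mussel-shell
biostimulant (*Perna canaliculus*).  It is written for soil microbiologists
who monitor the stress response of the culturable community (plate counts of
eight microbial groups), soil biochemistry (seven enzyme activities),
amplicon-based community structure (OTU tables with taxonomic lineages) and
contaminant dissipation — and who want the whole statistical analysis to be
scripted, seeded and testable.

## What it computes

**Colony development index (CD).**  For daily increments N₁…N₁₀ of newly
appeared colonies over a 10-day plate observation, with pᵢ = Nᵢ / N_total,

    CD = 100 · Σᵢ pᵢ / i        ∈ [10, 100].

High CD means colonies appear early — fast-growing, r-strategist
communities; low CD marks slow, K-type growth.

**Ecophysiological diversity index (EP).**  The Shannon-type entropy of the
appearance-day distribution,

    EP = −Σᵢ pᵢ · log₁₀ pᵢ      ∈ [0, 1] for 10 observation days,

1 when colonies emerge uniformly over the window, 0 when all appear on one
day.  The log base is a parameter (base 10 by default, which gives the [0,1]
scale).

**Biostimulation impact factor (IF_Pc).**  The ratio IF_Pc = A_Pc / A_C of a
response (enzyme activity or microbial count) with the biostimulant to a
baseline without its effect; > 1 stimulation, < 1 inhibition.  Two baseline
conventions are implemented (`paired`: same dose without the amendment;
`control-soil`: clean amended soil), because published descriptions of such
ratios are often ambiguous between the two.

Around these sit the inferential layer (Tukey HSD at p = 0.01 with
compact-letter homogeneous groups, Pearson dose correlations, PCA of IF
matrices with explained variance and loadings), the taxonomic-profile layer
(rank aggregation with read conservation, <1 % elimination and ≥1 %
difference-between-proportions filters, shared-genus sets, and a
G-test(Yates)/Fisher two-proportion procedure with continuity-corrected
confidence intervals), first-order residue-decay summaries, and a seeded
synthetic-data generator that emulates the full factorial design so every
stage is testable without any external data.

## Worked example

Generate a dataset and compute the community indices:

```bash
python analysis/01_generate_dataset.py --seed 1   # writes results/data/
python analysis/02_microbial_indices.py
```

```
mean CD / EP over unamended cells:
  Act           CD  14.91 (K-strategist)   EP 0.800
  Fun           CD  69.05 (r-strategist)   EP 0.575
  Org           CD  48.90 (r-strategist)   EP 0.864
  ...
percent change at the top dose vs control:
  Fun           day 15:   -74.3%
  ...
```

Actinobacteria are back-loaded growers (CD ≈ 15, K-strategists), the
organotrophs front-loaded (CD ≈ 49, r-strategists), and the fungal plate
count collapses by about three quarters at the top dose on day 15 — the
generator's configured effect is a 0.24× multiplier, i.e. −76 % in
expectation, and three replicate pots land at −74.3 %.  The remaining
drivers (`analysis/03…06`) add the enzyme post-hoc letters and dose
correlations, the taxonomic profiles and shared genera, the IF_Pc PCA, and
the residue decline (96.00 % of the dose gone by day 15 under the default
first-order rate).

The same analysis runs as one command over the library API or the CLI:

```bash
soiltox run --seed 1 --out results/report
soiltox report --out results/report
```

Reports are plain CSV plus a JSON manifest and regenerate byte-identically
for the same (config, seed).

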