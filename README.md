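# cqindex

Segmented developmental-index analysis of RT-qPCR time courses.

`cqindex` is for researchers who track the maturation of a biological
system — here, human cortical organoids patterned into GABAergic (VCO) or
glutamatergic (DCO) lineages — with a panel of developmentally regulated
transcripts measured by quantitative PCR, and who want to ask whether a
treatment shifts the *trajectory* of development rather than any single
gene. The motivating application is neurosteroid (allopregnanolone, ALLO)
exposure and withdrawal as a model of preterm loss of placental hormone
support.

## What it computes

Starting from replicate-level quantification cycles (Cq):

1. **Relative quantification.** ΔCq = Cq_gene − Cq_GAPDH per sample;
   fold change FC = 2^−ΔΔCq against a calibrator group (undifferentiated
   cells at DIV0); scaled relative abundance 2^−ΔCq × 10⁴; a group-level
   detectability filter for transcripts that never amplify within the
   40-cycle run.
2. **Segmented developmental index.** The time course is cut into four
   segments (DIV26–55, 55–78, 78–95, 95–138). Within each segment, every
   gene's trend in the *control* arm is classified by the Pearson
   correlation of replicate-level log₂FC against day (two-sided t-transform
   p, df = n−2): significantly up (r > 0, p < .05), down (r < 0, p < .05),
   or neither. Each sample is then scored

   &nbsp;&nbsp;&nbsp;&nbsp;index = mean( FC_g / s_g : g ∈ up ) / mean( FC_g / s_g : g ∈ down ),

   where s_g is gene g's control-arm segment mean — the equal-weight
   rescaling that stops any single high-FC gene from dominating the ratio.
   The same gene sets and rescaling constants are applied to the treated
   arm.
3. **Trajectory comparison.** Per-segment index-versus-day slopes (OLS) and
   an ANCOVA interaction test (index ~ day + arm + day×arm); the
   day×arm F-test is the operational definition of "the treatment changed
   the developmental slope in this segment". By default slopes are fitted
   on log₂(index), where the index is linear in developmental time and the
   test holds its nominal level.
4. **Group statistics.** Two-way factorial ANOVA (Type II sums of squares,
   robust to unbalanced replicate counts), Benjamini–Hochberg adjustment,
   per-stratum Welch post-hoc contrasts, and percent-change reporting.
5. **Synthetic studies.** A generator that emulates the full design —
   23-gene panel plus GAPDH, days 0/26/55/78/95/138, n = 3 per arm per day,
   two arms, 0.3-cycle replicate noise — with a latent *maturation clock*
   that slows by a factor (1−δ) in a post-withdrawal window, so the
   ground truth ("which segments carry a slope difference") is known in
   closed form.

## Worked example

```bash
cqindex simulate --preset withdrawal_delay --seed 0 --out cq.csv
cqindex quantify --in cq.csv --out-dir quant/
cqindex devindex --in quant/fold_change.csv --out-dir dev/
```

`dev/slopes.csv` then contains (seed 0, δ = 0.5, delay window DIV67–95):

```
segment,slope_control,slope_treated,interaction_F,interaction_p,evaluable,degenerate,error
DIV26-DIV55,0.1855105406,0.1870532391,0.08281224443,0.7808360305,True,False,
DIV55-DIV78,0.2047894965,0.1556464065,39.21668288,0.0002424530089,True,False,
DIV78-DIV95,0.183351367,0.09817481513,47.53579025,0.0001252063467,True,False,
DIV95-DIV138,0.1951084849,0.1892976947,3.089728286,0.1168442422,True,False,
```

Read: in the two segments overlapping the delay window the treated arm's
index climbs at roughly half to three-quarters the control rate (0.16 vs
0.20, then 0.098 vs 0.18 log₂ units per day) and the interaction test
fires (p ≈ 2.4×10⁻⁴ and 1.3×10⁻⁴); in the flanking segments the slopes
agree and the test is silent — a delay that begins at withdrawal and
resolves, in rate, by the final segment. The same library surface is
available from Python (`cqindex.run_devindex_pipeline`).

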