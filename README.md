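# ssgimme

Transcriptome-driven reduction of genome-scale metabolic models (GEMs):
gene expression is normalized by metabolic-function gene-set enrichment
(single-sample GSEA), mapped onto reactions through gene–protein–reaction
(GPR) rules, and fed into the GIMME penalty LP to extract context-specific
models. The package also ships the evaluation harness such models are
judged with: FBA/FVA, glucose-limited chemostat sweeps with
critical-growth-rate detection, hexokinase-style flux normalization, and a
prediction coefficient of determination.

It is aimed at systems biologists who tailor constraint-based models
(e.g. the consensus yeast GEM) to a condition using RNA-seq or microarray
data, and who want each stage — enrichment, weighting, GPR mapping,
extraction, evaluation — independently scriptable and testable.

## The methods in brief

**FBA.** A metabolic state is a flux vector *v* satisfying steady-state
mass balance *S·v = 0* and bounds *lb ≤ v ≤ ub*; flux balance analysis
maximizes the biomass pseudoreaction flux, read as the specific growth
rate μ (h⁻¹). Exchange fluxes follow the COBRA sign convention
(negative = uptake).

**ssGSEA.** For one sample, genes are ranked from high to low expression
and the ranks turned into correlation values *r_g* (their z-scores by
default). For a gene set *G*, walking the ranked list accumulates

    RES(i) = P_in(i) − P_out(i),

where *P_in* is the |r_g|^α-weighted ECDF over in-set genes (α = 0.75)
and *P_out* the plain ECDF over the rest. The enrichment score is the
area under RES; NES standardizes it against a permutation null of
size-matched random gene sets (1000 permutations), and sets with
|NES| ≥ 1.96 are flagged significant (BH-FDR is reported alongside).

**Integration.** Significant-set NES values become multiplicative gene
weights (median-rescaled to 1 so the expression scale is preserved), and
each reaction's expression *x_i* is the GPR collapse of its gene values
(AND → min, OR → max). Reactions with no gene evidence carry a NO_DATA
sentinel.

**GIMME.** With threshold *t* = 25th percentile of the data-bearing
reaction expressions, reactions below threshold get penalty
*c_i = t − x_i* and the LP

    min Σ c_i·|v_i|   s.t.   S·v = 0,  lb ≤ v ≤ ub,  v_biomass ≥ 0.9·Z*

is solved (Z* = parent FBA optimum). Penalized reactions with no flux in
the penalty minimum are removed; NO_DATA reactions are protected. The
optimal penalty sum is the inconsistency score.

## Worked example

The bundled overflow fixture is an 8-reaction lumped model of yeast
energy metabolism (respiration yields 26 ATP per glucose, fermentation 2;
biomass costs 10 ATP), whose optima are closed-form: with glucose uptake
G and oxygen cap O, μ = (2G + 24·min(G, O/6))/10 and the critical growth
rate is μ_crit = 13·O/30.

```sh
ssgimme fixtures make-toy -G 10 -O 6 --out toy.xml
ssgimme sweep --model toy.xml --glc-exchange EX_glc --o2-exchange EX_o2 \
    --o2-cap 6 --grid 0.5:2.0:4 --track EX_etoh,EX_co2 \
    --ethanol-exchange EX_etoh
```

prints

```
glucose_uptake	growth_rate	status	EX_co2	EX_etoh
0.5	1.3	optimal	3	-0
1	2.6	optimal	6	-0
1.5	2.7	optimal	7	1
2	2.8	optimal	8	2
```

Below the oxygen limit (uptake g ≤ O/6 = 1) growth is fully respiratory
and ethanol secretion is zero; above it the overflow regime begins —
ethanol appears and the growth gain per extra glucose drops (the
Crabtree-effect pattern of glucose-limited chemostats). The first
fermenting grid point has μ = 2.7 h⁻¹, just above the fixture's
μ_crit = 2.6.

The combined framework on an oxygen-sufficient variant with
respiration-biased synthetic expression:

```sh
ssgimme fixtures make-toy -G 10 -O 100 --out toy_o2rich.xml
ssgimme fixtures make-gmt --model toy_o2rich.xml --out sets.gmt
# expr.tsv: genes x samples TSV (here: synthetic, respiration genes high)
ssgimme ssgsea-gimme --model toy_o2rich.xml --expr expr.tsv \
    --gmt sets.gmt --sample sample_1 --seed 7 --out context.xml
```

prints `removed	FERM`: the low-expressed fermentation branch is removed,
and the provenance sidecar records the run —

```json
{
 "parent_optimum": 26.0,
 "objective_fraction": 0.9,
 "inconsistency": 0.0,
 "removed_reactions": ["FERM"],
 "threshold": 5.411404107553362,
 "weighting": {"enabled": true, "mode": "multiply_positive_nes", "combine": "max"}
}
```

Inconsistency 0 means the retained network meets 0.9·Z* without any
below-threshold flux. The same run with weighting disabled
(`run_pipeline` with `weighting_enabled: false`, or the `gimme`
subcommand) produces the identical context model — the degenerate
equivalence the test suite asserts.

Real-model usage is identical with an SBML file such as the consensus
yeast GEM in place of `toy.xml` (its summary is 4058 reactions, 2742
metabolites, 1150 genes) and measured exchange bounds set via
`set_exchange_bounds`.

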