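# Methods

This note documents the models and procedures implemented in `ssgimme`,
the parameters that matter, the numerical choices made where conventions
diverge, and what the synthetic fixtures do and do not establish.

## Constraint-based model and LP analyses

A `MetabolicModel` holds the stoichiometric matrix *S* (rows =
metabolites, columns = reactions), per-reaction flux bounds in
mmol·gDW⁻¹·h⁻¹, boolean GPR rules, and one objective reaction (a biomass
pseudoreaction whose flux is read as the specific growth rate μ, h⁻¹).
Exchange reactions are exactly the single-metabolite boundary columns;
uptake is a negative exchange flux, so a measured uptake rate *u* is
imposed as lower bound −|u|.

FBA maximizes the objective flux over {v : S·v = 0, lb ≤ v ≤ ub}; FVA
reports each reaction's flux range subject additionally to
v_obj ≥ fraction·Z*. All LPs go through HiGHS
(`scipy.optimize.linprog`). Because an FBA optimum is generally a
degenerate vertex, only solver-independent quantities (objective value,
mass balance, FVA ranges) are treated as meaningful; single-vertex flux
values are reported but never asserted on in tests.

Numerical floors: flux activity ε = 10⁻⁶ mmol·gDW⁻¹·h⁻¹ (the LP noise
floor); objective-floor constraints carry a 10⁻⁹ relative slack so that
fraction = 1 does not go infeasible from round-off.

### Chemostat sweep and critical growth rate

`chemostat_sweep` emulates a glucose-limited chemostat: at each grid
value g the glucose exchange is fixed as an equality (lb = ub = −g,
substrate supply is what the vessel fixes), oxygen uptake is capped
one-sided at O, and biomass is maximized. `critical_growth_rate` bisects
on g for the onset of overflow metabolism and returns μ there. "Ethanol
formation detected" is defined through the FVA minimum of the ethanol
exchange at objective fraction 1 — ethanol counts only when *every*
optimal flux vector secretes more than ε — which makes the onset
solver-independent where a single FBA vertex would not be. Bisection
tolerance defaults to 10⁻⁴ on uptake; on the toy fixture this localizes
μ_crit far below the 10⁻³ accuracy the tests require.

The prediction R² is 1 − SSE/SST against the measured values (not squared
Pearson): it penalizes systematic bias and can be negative when a
prediction is worse than the measured mean. Squared Pearson is available
as `method="pearson"` for comparison.

## ssGSEA

Per sample, genes are ordered from high to low expression; ranks run
1..N from the bottom so the top gene carries rank N. Correlation values
are either the descending ECDF ranks (rank/N) or, by default, the rank
vector standardized to mean 0, sd 1 ("z-score" correlation type). Ties
are broken by a seeded shuffle of gene ids (seed recorded in the config)
— deterministic but not alphabetically biased.

For a set G with N_G of N genes present, the running score at position i
is RES(i) = P_in(i) − P_out(i) with

- P_in(i) = Σ_{g∈G, pos(g)≤i} |r_g|^α / Σ_{g∈G} |r_g|^α,
- P_out(i) = #{g∉G, pos(g)≤i} / (N − N_G).

Both ECDFs end at 1, so RES(N) = 0 identically. The enrichment score is
Σ_i RES(i) (area under RES) by default; the signed KS extremum is the
alternative statistic. The weight exponent defaults to α = 0.75, the
common ssGSEA convention; α = 0 reduces P_in to a plain ECDF.

Significance: ssGSEA has no phenotype labels to permute, so the null
resamples gene labels — ES values of uniformly random same-size gene
sets (default 1000 draws, cached per set size within a sample).
NES = (ES − mean(null))/sd(null) is a z-statistic, so the default cutoff
|NES| ≥ 1.96 reads as a two-sided 5% normal bound; the add-one two-sided
permutation p-value and BH-FDR (within sample, across sets) are reported
alongside. Sets with fewer than 3 genes present are dropped. A
degenerate all-zero-weight set (possible at α > 0 when every member has
r_g = 0) falls back to unweighted membership rather than dividing by
zero.

## Gene-set weighting and GPR mapping

How enrichment scores should modulate gene expression is genuinely open;
the package implements it as explicit modes and records the choice in
provenance. Default: for each gene in ≥ 1 significant set, the per-set
weight is max(NES, 0) (`multiply_positive_nes`; `multiply_nes` uses
|NES|), combined across the gene's sets by max (or mean), then all
affected genes' weights are rescaled so their median is 1. The median
rescaling keeps the weighted values on the original expression scale —
important because the downstream threshold is a quantile of these values
— while moving enriched processes up relative to depleted ones. Genes in
no significant set keep weight 1; a flag admits non-significant sets.
If the median raw weight is ~0 (all contributing sets depleted),
weighting is disabled with a warning rather than zeroing the transcriptome.

GPR evaluation: AND → min (a complex is limited by its scarcest
subunit), OR → max (the best isozyme carries the reaction); EMPTY rules
give NO_DATA. Unmeasured genes are dropped from the aggregate under the
default `ignore` policy (a node with no measured child is NO_DATA);
under `propagate`, missingness anywhere makes the node NO_DATA — strict
for both node kinds, chosen for simplicity and conservatism. Evaluation
is monotone in every gene value and invariant under child reordering and
flattening, both property-tested.

## GIMME

The threshold t is the 0.25 quantile (linear interpolation between order
statistics, the numpy default) of the *reaction-level* expression of
data-bearing reactions — the threshold is computed on what the LP
penalizes, per sample; NO_DATA reactions are excluded. Penalties are
c_i = max(t − x_i, 0). The "weight −1" convention for unmeasured
reactions is realized out-of-band: zero penalty plus membership in a
protected set that extraction may never remove. (A literal −1 objective
coefficient would reward flux through unmeasured reactions and unbound
the minimization.)

The LP minimizes Σ c_i·|v_i| with |v_i| realized by splitting each flux
into nonnegative forward/backward components, subject to S·v = 0, the
original bounds, and v_obj ≥ f·Z* with f = 0.9. Its optimum is the
inconsistency score. Extraction removes reactions with c_i > 0 and
|v_i| ≤ ε in the penalty minimum; because that test is vertex-dependent
in degenerate LPs, `fva_confirm` optionally restricts removal to
reactions whose whole FVA range at fraction f lies within [−ε, ε]. The
reduced model is re-checked by FBA to attain f·Z*; failure raises rather
than returning a silently broken model. Removing zero-flux reactions
preserves the penalty-minimal vertex, so on the fixtures the extracted
model's inconsistency equals the exhaustive-enumeration minimum over all
removable subsets — asserted per run in the test suite.

## Synthetic fixtures: what they emulate, what they don't

The toy overflow model lumps yeast energy metabolism into two
ATP-producing routes — respiration (26 ATP/glucose, oxygen-limited) and
fermentation (2 ATP/glucose, 2 ethanol + 2 CO₂) — plus transport, a
10-ATP biomass drain and four exchanges: 8 reactions, 6 metabolites, 3
genes, carbon-balanced. Every optimum is closed-form
(μ = (2G + 24·min(G, O/6))/10; overflow onset g* = O/6;
μ_crit = 13·O/30), so analytic oracles replace simulated ones. Defaults
G = 10, O = 6 put the model in the oxygen-limited overflow regime;
oxygen-rich variants (O ≫ 6G) are used where extraction should be free
to drop fermentation.

Synthetic expression draws active genes around a high level (default 10)
and the rest around a low level (default 1) with multiplicative
lognormal noise (log-sd 0.1), roughly a ±10% expression noise — values
chosen as a plausibly strong, clean two-state transcriptome. Synthetic
gene sets give one set per pathway, padded to the minimum set size 3
with decoy genes that exist only in the expression matrix (never in a
GPR), so set-size filters are honored without perturbing flux optima.

These fixtures establish internal correctness — score arithmetic, LP
optimality, the objective guarantee, end-to-end recovery of a planted
active pathway — at desk scale. They do not emulate genome-scale network
redundancy, realistic transcriptome dispersion, or curated-annotation
granularity, so passing tests do not by themselves certify predictive
accuracy on real chemostat data; the evaluation operations (sweeps,
μ_crit, normalized-flux R²) are provided for exactly that assessment
when measured uptake bounds and flux data are available.

## Problem sizes and determinism

Test and acceptance runs use deliberately small instances: 50-gene
profiles for score-oracle checks (100 instances), 500 genes × 300 sets ×
4 samples with 1000 permutations for null calibration (~1200 draws,
seconds of runtime), 8-reaction instances for exhaustive GIMME
enumeration (≤ 2⁶ subsets each, 50 instances). All randomness flows from
explicit integer seeds (numpy `default_rng`); identical configuration
and seed reproduce byte-identical result tables, which the CLI tests
assert.

## Known limitations

- Single-objective GIMME only; no MILP variants (iMAT/INIT-style) and no
  required-functionality sets beyond biomass.
- The gene-weight construction from enrichment scores is one defensible
  choice among several; alternatives are exposed as modes, not decided.
- No transcript-isoform resolution, no proteomics input, no raw RNA-seq
  or microarray preprocessing — expression arrives pre-normalized.
- SBML support is limited to what cobrapy reads/writes (Level 3 + fbc);
  exotic kinetic-law annotations are ignored.
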