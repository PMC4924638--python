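# Methods

## The miniature ME formalism

`protalloc` implements a deliberately small metabolism-and-expression (ME)
model that keeps exactly the constraint classes the analysis procedures
manipulate: metabolic steady state with the biomass flux pinned to the
growth rate μ, enzyme capacity coupling fluxes to catalyst amounts,
ribosome capacity with growth-rate-dependent dilution (`Σ L_i·μ·e_i ≤
κ·e_ribo`, the ribosome translating itself included), and a hard proteome
budget `Σ mw_i·e_i = Φ` shared with a single un-modeled ("dummy") protein.
Genome-scale reconstruction detail — compartments, mRNA/tRNA species,
growth-dependent translation-rate functions — is intentionally out of
scope: the procedures being reproduced (utilization quantification,
demand inference, segmentation, shift simulation), not the reconstruction,
are the subject of the package.

Units are fixed so every example is reproducible: fluxes mmol/gDW/h,
protein amounts mmol/gDW, kcat 1/h, molecular weight g/mmol, mass g/gDW.
The dummy protein has mw = 1 g/mmol and the model-average protein length.

### Solving

At fixed μ the constraint set is linear; all problems are solved with
HiGHS via `scipy.optimize.linprog`. Maximal growth is located by bisection
on LP feasibility over [0, κ/L_ribosome] with absolute tolerance 1e-6 h⁻¹
(the upper end is the closed-form ceiling at which the ribosome can only
sustain its own dilution). Enzyme capacity is encoded with
per-(reaction, isozyme) usage variables (`v_j ≤ Σ_i kcat_{j,i}·u_{j,i}`,
`Σ_j u_{j,i} ≤ e_i`) so a protein catalysing several reactions is never
double-counted; this reduces to the plain `|v| ≤ Σ kcat·e` coupling when
each enzyme serves one reaction.

Degenerate alternate optima at the growth maximum are resolved by a
secondary objective maximizing the dummy protein — identical, under the
budget equality, to minimizing total modeled protein mass — which yields
the unique minimal proteome whose support defines the *expressed set*
(threshold: protein mass > 1e-9·Φ, a numerical-zero guard).

Protein *demand* at a measured growth rate is that same maximization at
fixed μ: whatever budget the dummy can absorb is not needed, so the
remaining expression is the minimal requirement. The dummy's share of Φ at
this optimum is the maximum unused-protein fraction compatible with the
measured rate. Infeasible measured rates are reported as infeasible, never
clamped.

Chemostat-style conditions are solved at their fixed dilution rate with
the same dummy-maximizing objective. In the toy networks the limiting
uptake is stoichiometrically determined at fixed μ, so a separate
uptake-minimization phase would change nothing; the demand objective is
used directly.

## Utilization sampling

Which proteins *can* serve growth in an environment depends on uncertain
kcats. Every isozyme's kcat is therefore resampled independently as
`10^X`, `X ~ Normal(mean 1.11, variance 1.31)` (the global base-10
lognormal distribution of catalytic turnover numbers), 100 parameter sets
per condition by default, and growth is re-maximized per set. The ribosome
elongation capacity κ is *not* resampled: resampling translation capacity
would confound the enumeration of alternate metabolic pathway choices.
Infeasible samples are skipped (with a warning), not redrawn, to keep
sample provenance explicit; in practice they do not occur because zero
growth is always feasible.

Measured abundances are interrogated with each sampled utilized set:
utilized fraction = measured mass of the set; un-utilized fraction of a
scope (the modeled proteome) = scope mass minus utilized scope mass. Both
are reported **relative to total measured proteome mass**, so
utilized + un-utilized(scope) + out-of-scope = 1 sample-wise. The
alternative normalization (relative to scope mass) is a one-line change;
the total-mass denominator is the default because utilized and
out-of-scope fractions are displayed side by side downstream.

## Relative turnover and its confidence interval

The demand/measured ratio per protein and condition is proportional to
in-vivo flux per enzyme; max-normalizing each protein's ratio across
conditions gives relative turnover in [0, 1]. Proteins unmeasured in any
condition, or never demanded, are excluded (listed, never divided by
zero). The per-condition mean is taken over the core-proteome rows with a
Student-t 95% confidence interval of the mean — the CI method is a
package choice; only "95% CI of the mean" is inherent to the quantity.

## Growth prediction

The inferred unused fraction is quantitative and is forced directly into
the model as the dummy fraction. Relative turnover needs one quantitative
anchor: a global multiplier τ_ref (scaling all kcats and κ) is calibrated
by bisection so the model reproduces the reference condition's measured
growth rate with the reference unused fraction forced (tolerance 1e-5 on
μ). Other conditions use τ_c = τ_ref·ρ_c/ρ_ref, the minimal assumption
preserving the relative structure of the turnover means. τ_c may exceed
τ_ref when a condition's mean relative turnover exceeds the reference's;
values above 1 are allowed (only τ ≤ 0 is a domain error). The
unused-fraction point estimate is the distribution median; percentile
endpoints serve as sensitivity runs, not formal CIs.

A reference-fixed prediction mode holds both (φ, τ) at reference values,
isolating the growth-rate variation attributable to nutrient quality
alone; on panels with heterogeneous planted allocation this mode
correlates strictly worse with the generating rates than the
per-condition mode, reproducing the qualitative gap between
nutrient-only and allocation-aware prediction.

## Segmentation

An environment panel swaps one element source at a time off a base
minimal medium; variants that cannot support growth (μ ≤ 1e-4) are
dropped with a log entry, and the base medium counts as the variant for
its own default sources (so "usable sources per element" includes the
defaults). Classification runs constrain isozymes of a reaction to equal
usage, so every capable isozyme of a used reaction counts as expressed
rather than an arbitrary cheapest one — expressed sets under this
constraint are supersets of the free-mode sets.

The core proteome is the intersection of expressed sets over all panel
environments. Attribution of non-core proteins needs care: a plain union
over an element's variants would classify the base carbon pathway into
the N segment (it is expressed in every N-variant, which all carry the
base carbon source). The rule adopted: a non-core protein belongs to
segment E iff it is expressed in at least one E-variant **and** absent in
at least one E-variant — i.e. its expression depends on the E source.
This reproduces designed membership on constructed toys, puts an enzyme
shared by an alternative-C and an alternative-N pathway in both segments,
and guarantees core ∪ segments covers every protein expressed anywhere in
the panel.

Regulon enrichment is a one-sided hypergeometric upper tail
(population = the modeled proteome, successes = regulon, draws = segment),
reported without multiple-testing correction. Trend analysis is ordinary
least squares of per-condition quantities against growth rate (a constant
response returns slope 0, R² = 0 rather than an error), plus a grouped
mode reporting median per-protein Pearson correlation with growth rate.
Out-of-scope ("non-ME") proteins are summarized by the smallest
abundance-ranked prefix covering ≥ 80% of out-of-scope mass per condition
(ties broken by identifier), unioned across conditions.

## Shift simulations

Up-shift: steady state is solved in the pre-shift environment (optionally
with a reduced turnover multiplier, inflating the proteome per unit flux),
and post-shift growth is maximized subject to `e_i ≤ e_pre,i` for a
constrained scope. The default scope is every modeled protein — no
instantaneous synthesis of anything — which is the physically conservative
reading but makes a shift to a disjoint substrate instantly lethal (no
transporter exists). The pipeline's default scenarios therefore constrain
the **core** proteome only, leaving substrate-specific proteins free; with
zero excess this pins the instantaneous rate exactly at the pre-shift rate
(the capped biosynthetic backbone carries flux μ), and an over-expressed
core (low pre-shift turnover) yields a strictly higher instantaneous rate.
Both readings are exposed via `constrained_scope`.

Supplementation compares maximal growth under an uptake limitation with
and without an additional source opened in excess. An alternative source
of the limiting element helps; a source of a non-limiting element changes
nothing — *provided* the supplement is not catalytically better than the
source already open, in which case the model correctly grows faster even
unlimited (the even-kcat toy is used where the strict no-benefit property
is asserted).

## Synthetic data: what it emulates and what it does not

The toy model has one dedicated transporter/catabolic chain per carbon and
nitrogen source feeding a shared biosynthetic backbone plus a ribosome, so
segment membership is known by construction. Defaults: 3 C + 2 N sources,
chain length 2, backbone length 3, enzyme mw 1 g/mmol and length 3 aa,
ribosome κ = 60 aa/h with length 10 aa and mw 3 g/mmol, Φ = 0.5 g/gDW.
Catalytic chains (kcat 80/h × a seeded per-source factor in [0.75, 1.25])
are deliberately faster than the backbone (kcat 8/h) so that the
conditionally-used proteome is a modest share of demanded mass, as in real
proteomes where the core dominates the utilized fraction; backbone-scale
kcats sit near the median of the sampled global distribution (10^1.11 ≈
13/h in the model's abstract hourly units) so nominal and sampled
parameterizations share a scale. These are abstract, not physiological,
units; growth rates land in a realistic 0.1–1 h⁻¹ band.

Proteomics generation follows the model's own logic. Per condition with
planted unused fraction u* and turnover τ*: the measured utilized
abundances are the demands of the τ*-scaled model at the generating growth
rate (i.e. over-expression by 1/τ* relative to nominal demands); planted
unused mass u*·Φ is placed on pathway proteins whose substrate exchange is
closed — structurally unusable, hence un-utilized under *every* sampled
kcat set, which keeps recovery well-posed despite sampling; the
per-condition total is exactly Φ, so mass-fraction conversion preserves
ratios and noise-free recovery of u* is exact. Batch growth rates are the
self-consistent optimum of the τ*-scaled model with u* forced; chemostat
conditions run at their dilution rate, with utilized demands uniformly
rescaled to fill the remaining budget and the rescale folded into the
recorded *effective* turnover truth (at slow fixed growth the proteome is
over-expressed relative to demand — exactly the under-utilization
phenomenon the analysis measures). The ribosome row of the turnover matrix
deviates slightly from the planted factor because demand under a τ-scaled
model is not exactly demand/τ (the κ − μL dilution term is nonlinear in
τ); exact-recovery checks therefore use enzyme rows.

Default planted conditions mirror the structure of a 16-environment
proteomics design at toy scale — batch cultures on each carbon source,
slow glucose-analogue chemostats, a stress condition encoded as a global
kcat scale (how real stress environments map onto model parameters is
genuinely open; the modifier is exposed but no fidelity is claimed) — with
unused fractions rising (0.10 → 0.45) and turnover falling (1.0 → 0.5)
toward slower growth. Trend-mode generation plants linear segment-mass
trends (core 0.33·μ + 0.26, C segment −0.28·μ + 0.40, out-of-scope
−0.09·μ + 0.26) directly in fraction space for regression-recovery tests.
Transcriptome generation allocates 1 − u_wt of transcript mass to the
genes demanded at the wild-type growth rate and shifts a planted Δ into
the utilized genes for each evolved strain, optionally scaling the
ribosomal share to emulate faster translation; gene length is 3 nt per
amino acid and FPKM = fraction/length × constant.

What the generator does **not** emulate: measurement error structure
beyond multiplicative lognormal noise, incomplete proteome coverage,
absolute copy-number calibration error (the copies-per-cell constant,
2.0e-13 g protein/cell, cancels in every mass-fraction computation),
regulatory correlations between proteins, or genome-scale pathway
redundancy. Passing recovery tests therefore demonstrates correctness of
the inference machinery under the stated generative assumptions, not
robustness to real-data pathologies.

## Determinism and problem sizes

Every stochastic step is driven by `numpy.random.default_rng` with seeds
derived from one global seed via stage-name-keyed `SeedSequence` spawn
keys, so inserting a stage does not perturb another stage's draws and
pipeline reruns are byte-identical. Default problem sizes — a ~15-protein
toy, 100 kcat samples per condition, 6-condition default panel,
8-condition prediction panel, 100k sampler draws for moment checks — keep
a full analysis plus test suite in the minutes range while leaving every
statistical check comfortably powered; all sizes are configurable.

## Known limitations

- The LP-based demand inference assumes a unique minimal proteome; ties
  between exactly cost-equal pathways are resolved by the solver's basis
  choice (measure-zero under sampled kcats).
- The per-condition turnover scaling τ_c = τ_ref·ρ_c/ρ_ref treats the
  condition mean of relative turnover as a global multiplier; protein-
  specific turnover variation is averaged away, as in the quantity it
  anchors.
- Stress conditions as a uniform kcat scale are a stand-in, not a claim
  about mechanism.
- The miniature formalism omits membrane/compartment constraints and
  growth-dependent translation kinetics; conclusions about those layers
  are out of reach by construction.
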