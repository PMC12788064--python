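# Methods

## Scope and data model

The package operates on a samples × indicators table: each row one
biological replicate of one treatment, each column a positive-valued soil
or plant indicator. All stages treat indicators generically; units live in
the column metadata (direction of merit and, for optimum-type indicators,
a target value). Missing values are rejected at validation with the row
and column named — no imputation — because the correlation network and the
treatment means that follow are both sensitive to silent gap-filling in
panels this small.

## Correlation network

Spearman rank correlation is used throughout (average ranks; two-sided
p-values from the t approximation t = ρ√((n−2)/(1−ρ²)) on n−2 degrees of
freedom, delegated to scipy). Pairs with |ρ| = 1 receive p = 0, where the
t statistic is undefined but the exact permutation p is 0 at any usable n.
Correlations are computed over all samples pooled across treatments: with
3–4 replicates per treatment this is the only option that clears the n ≥ 4
floor, and it is the version of the indicator network that reflects both
within-treatment covariation and treatment-driven co-movement. Constant
columns are excluded with a warning rather than propagating NaN.

Edges require |ρ| ≥ 0.60 (inclusive) **and** p < 0.01 (strict). The
absolute value is the default because a strong negative correlation is
equally informative about redundancy between indicators; a signed-only
mode is available. The adjacency is binary: the centrality definition
below operates on connection structure, not correlation magnitude (a
|ρ|-weighted variant would change the question being asked, so it is not
the default).

## Eigenvector centrality

Node importance satisfies xᵢ = (1/λ) Σⱼ aᵢⱼ xⱼ — the dominant eigenvector
of the adjacency, computed per connected component. Numerical choices:

* **Lazy power iteration.** The update is v ← (A + εI)v with ε = 1.
  Shifting by εI leaves the eigenvectors unchanged while making the
  dominant eigenvalue strictly largest in magnitude, so the iteration
  converges on every connected component — including bipartite ones such
  as 3-node paths, where the unshifted update (ε = 0, still available)
  oscillates between the two vertex classes forever. The reported
  eigenvalue is the Rayleigh quotient under the unshifted A.
* **Convergence.** Uniform positive start, renormalization to unit maximum
  each sweep, stop when successive iterates differ by < 1e-10 in max norm,
  hard cap 1000 iterations with a descriptive error (component and last
  residual) on failure.
* **Cross-component scaling.** Power iteration fixes each component's
  vector only up to scale, and eigenvector centralities of disconnected
  components are not mutually comparable in any canonical way. Each
  component's vector is therefore scaled to unit maximum, so every
  non-trivial component has a node at 1.0 and a single high-centrality
  threshold reads identically within each block of the network. The
  caveat: a centrality of 0.95 in one component and 0.95 in another do not
  certify equal "importance" across components — the threshold is a
  within-component statement. Isolated nodes get centrality 0.

The test suite checks the iteration against a dense `numpy.linalg.eigh`
eigendecomposition (same per-component normalization) on random graphs of
up to 12 nodes; agreement is required to 1e-6 and observed at ~1e-10.

## Candidate selection and redundancy

Two candidate rules are provided because both circulate in the composite-
index literature: keep nodes with centrality ≥ 0.9 (the default), or keep
the ⌈10%⌉ highest-centrality nodes extending the cut through ties. Both
are monotone in their threshold.

Candidates are then clustered as connected components of the
significant-edge subgraph *restricted to the candidate set* (same |ρ|/p
gates). "Cluster" here is deliberately graph-based — the pipeline performs
no PCA, so a "principal component" of inter-correlated indicators is read
as a correlation cluster. Within each cluster of size ≥ 2 the survivor is
the member with the largest cumulative Σ|ρ| to the rest of its cluster;
ties (which occur exactly in 2-clusters) break lexicographically for
determinism. One survivor per cluster; singletons survive unchanged. The
full decision trace (clusters, per-member sums, survivor) is serialized so
the selection is auditable.

## Normalization and the radar-area index

The observed value Pᵢ of an MDS indicator is its treatment mean — the
index compares treatments, so the treatment is the scoring unit (a
per-replicate mode with mean ± SD of the index would be a straightforward
extension and is out of scope). References P:

* more-is-better: P = maximum treatment mean (score ≤ 1; the literature
  states only the lower-is-better and target-value rules, so the maximum
  rule is this package's documented symmetric choice);
* less-is-better: P = minimum treatment mean. In the literal mode
  stPᵢ = Pᵢ/P ≥ 1 — i.e. *worse* treatments score *higher*, inflating the
  index for degraded soils. This is kept as the default because it is the
  printed definition, and a warning in the documentation rather than a
  silent correction; the `ratio_inverted` mode scores P/Pᵢ (and
  min(Pᵢ/T, T/Pᵢ) for optimum indicators) so that all scores lie in (0, 1]
  and the index is bounded by 0.5·n·sin(2π/n) with equality at all-ones.
* optimum: P = target.

The index uses the circle constant 3.14 exactly as its default
(`pi_constant`), with true π one flag away; the default formula is the
squared form SHI = 0.5·Σ stPᵢ²·sin(2π/n). The squared form is **not** the
geometric radar-polygon area — that is 0.5·sin(2π/n)·Σ stPᵢ·stPᵢ₊₁ (cyclic
adjacent products), provided as `polygon_product` with spokes ordered by
descending centrality (deterministic). The two coincide on equal-score
vectors and are both degree-2 homogeneous; the squared form is
permutation-invariant, the polygon form invariant only under rotation and
reversal of the spoke order. Degenerate case worth knowing: with n = 1 and
pi_constant = 3.14, sin(6.28) < 0 makes the "area" negative — a faithful
consequence of the rounded constant. A realistic MDS has n ≥ 3; the
pipeline surfaces the resulting domain error rather than masking it.

## Alpha diversity

Observed richness, Chao1 and ACE estimate within-sample richness; Shannon
entropy (natural log — the dominant convention in microbial ecology; the
base is an option) measures richness + evenness. Chao1 defaults to the
bias-corrected form S_obs + F1(F1−1)/(2(F2+1)), defined for all inputs;
the classic F1²/(2F2) form errors when F2 = 0 with advice to switch. ACE
uses rare threshold 10, coverage C = 1 − F1/N_rare, and a CV² term floored
at 0; all-singleton rare groups (C = 0) error. The implementations are
small closed forms written here so the error policy is exact; scikit-bio's
estimators serve as an independent oracle in the tests (agreement to
1e-9 under hypothesis-generated count vectors). No rarefaction is
performed — depth normalization is the caller's responsibility.

## Exposure risk and economics

EDI = C × IR × conversion / BW. The conversion factor handles dry-weight
concentrations consumed fresh; all four factors are explicit so any
parameterization can be reproduced. The default RfD is the standard
selenium oral reference dose 5×10⁻³ mg·kg⁻¹·day⁻¹; HRI = EDI/RfD. The
enrichment band is [0.15, 1.0] mg·kg⁻¹ dry weight, both bounds inclusive
per the GH/T 1135-2024 wording (≥ / ≤). EB = yield × price − cost, a plain
decimal with a currency label; negative EB is meaningful (loss) and not an
error.

## Synthetic data generator

The generator emulates a small multi-treatment pot/pool trial: default 4
treatments (control CK, a combined nanocomposite NanoZSe, single-element
Se and Zn) × 3 replicates and a 14-indicator panel in 4 blocks (carbon/
nutrients, trace elements, physical/electrochemical, community diversity),
one designated hub per block.

Mechanics: indicator i in block b has latent score
zᵢ = lᵢ f_b + √(1−lᵢ²) εᵢ with loading lᵢ = √rho_block (hubs optionally
boosted, capped at 0.995 to stay a valid correlation), so within-block
latent correlation is rho_block and cross-block is 0; the observed value
is baseline_mean × effect × exp(σz − σ²/2) with σ² = ln(1+cv²), a
lognormal with exact mean baseline × effect and coefficient of variation
cv. Because Spearman correlation is invariant under the monotone lognormal
transform, the planted rank structure carries through to the observed
table (Gaussian copula). At cv → 0 the values are exactly deterministic.

Defaults and why: rho_block = 0.9 (soil carbon/nutrient pools and
physically coupled properties are strongly inter-correlated in field
panels); cv = 0.10 (typical analytical replicate variability of composite
soil chemistry measurements); NanoZSe = uniform 1.20× on more-is-better
indicators, Se/Zn = 1.10× (a clear primary-treatment signal over modest
single-element effects). Community counts are Dirichlet-multinomial:
symmetric Dirichlet proportions with treatment-specific concentration
(default 0.4–0.8; higher = more even = higher expected Shannon), multinomial
counts at depth 20,000 over 120 taxa.

What the generator does **not** emulate: spatial heterogeneity, temporal
dynamics, measurement censoring/detection limits, compositional artifacts
of relative-abundance sequencing, or cross-block ecological coupling.
Passing tests on this generator therefore demonstrate that the pipeline
recovers planted block/hub structure and planted treatment effects under
lognormal noise — not that any particular field dataset satisfies those
assumptions.

All randomness flows from a single root seed through
`numpy.random.SeedSequence` substreams (indicator table and community
counts are independent substreams), so identical config + seed gives
byte-identical output files.

## Benchmark conditions and observed behavior

Problem sizes used in the test suite and acceptance script: hub-recovery
runs use 100 samples (2 treatments × 50 replicates, boost 1.2, no
treatment effects — the pure correlation-recovery setting) over 100 seeds;
the improvement-sign runs use the default 12-sample experiment over 100
seeds; centrality oracle comparisons use 100 random graphs of ≤ 12 nodes.
Pilot runs before the bars were frozen observed 99/100 hub recovery
(bar ≥ 90) and 99/100 positive SHI change for the improved treatment
(bar ≥ 95); the rare failures are 12-sample seeds whose network collapses
to a degenerate 1-indicator MDS, counted honestly as failures.

## Known limitations

* Eigenvector centralities are comparable within, not across, network
  components (see above); the candidate threshold is a per-block rule.
* The literal normalization inflates the index when less-is-better
  indicators worsen; use `ratio_inverted` for a bounded, internally
  consistent index.
* The squared-form index is not the geometric radar area; both are
  reported options and neither is silently corrected into the other.
* With ~12 samples, edge significance at p < 0.01 requires |ρ| ≳ 0.7, so
  the realized network is noisy at realistic replicate counts; the MDS is
  correspondingly seed-dependent at that scale.
* Exposure assessment is deterministic single-scenario; no Monte-Carlo
  intake distributions, no multi-element aggregate hazard.
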