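# Methods

## Spatial model

Roads are undirected segments with a single speed per road class; the
travel time of an edge is `(length_m / 1000) / speed_kmh × 60` minutes.
Segment endpoints are merged into graph nodes within a 0.5 m snap
tolerance; zero-length segments are dropped with a warning, and parallel
segments collapsing onto one node pair keep the fastest edge. Traffic,
one-way restrictions, turn penalties and multi-modal travel are out of
scope. Coordinates must be planar metres; input whose bounding box looks
like geographic degrees (inside ±180/±90 with a span under one unit) is
rejected rather than silently mis-measured.

A provider's **catchment** is computed from its nearest graph node (the
snap distance is recorded so callers can flag bad snaps; snapping is to
nodes, not edge interiors, for exactness and simplicity). Single-source
Dijkstra times feed an edge-walk: an edge (u, v) entered from its cheaper
endpoint at time t is fully reached when `t + time(u,v) ≤ budget`,
otherwise each reachable endpoint contributes a partial piece of fraction
`(budget − t_end) / time(u,v)`; both entry directions are considered. The
polygon is the union of the reached (possibly partial) segment
geometries buffered by `buffer_width`, plus a disk at the snapped node —
so a zero budget yields exactly that disk. A buffered sub-network was
chosen over a convex hull because hulls overclaim unreachable pockets;
the cost is that with a buffer much smaller than the block spacing the
polygon is a ribbon web with holes. The demo city therefore pairs 500 m
blocks with a 300 m buffer (≈ half the spacing), which dissolves the
ribbons into filled isochrones; the library default stays at 100 m,
appropriate for realistically dense street networks.

**Coverage** is counted on a regular grid (default cell 100 m,
configurable; the demo uses 250 m) by cell-centroid membership: each
catchment adds 1 to every cell whose centroid its polygon contains. This
makes the surface deterministic, resolution-controlled, and exactly
checkable against a brute-force point-in-polygon oracle. Integer values
map to ordered levels through per-stratum interval schemes (partner:
0 none, 1–2 low, 3–4 medium, 5–18 high, 19–29 very high; non-partner:
0 none, 1–2 low, 3 medium, 4–20 high). The schemes end at the maxima
observed in the study that motivated them, so values beyond the top
interval clamp to the top level with a logged warning; value 0 in the
partner stratum maps to "no coverage" even though the partner scheme's
published intervals start at 1. **Sampling areas** are the cells whose
partner level equals "low" and whose non-partner level equals "high"
(both configurable); the selected cells are dissolved into one polygon.

## Sampling

Sample size uses the Cochran single-proportion precision formula
`n = ⌈z²₁₋α/₂ p(1−p)/d²⌉`. The study context quotes "80% power", but a
precision formula has no power term; the implementation exposes α and d
explicitly and reproduces the study's n = 216 at p = 0.385, d = 0.065 —
the margin is an interpretation, since no d is printed anywhere.
Households are drawn uniformly without replacement from the points inside
the dissolved sampling polygon with a recorded seed. An unreachable
household is replaced by the nearest (Euclidean) eligible unselected
candidate, ties broken by household id for determinism; replacements are
logged and can never duplicate an existing selection.

## Survey statistics

Categorical variables are cross-tabulated against the habitual choice
group with row percentages; independence is tested by Pearson chi-square
**without** continuity correction — recomputing the published
216-resident survey tables from their printed counts reproduces the
printed p-values (gender 0.347, mild illness 0.150, chronic illness
0.112, hospitalization 0.446, occupation 0.542, education 0.004, medical
cost 0.133, cost burden 0.585) only under the uncorrected statistic, so
that is the default and a Yates flag exists but is off. One printed row
(insurance status, printed p = 0.004) recomputes to ≈ 0.003 under any
standard variant; it is treated as an inconsistency of the source table
and excluded from validation. Age is compared by a pooled-variance
t-test (Welch by flag). Missing values are excluded pairwise per table,
which is why each table reports its own n; p-values below 0.001 render
as "<0.001" with the exact value retained.

## Preference-factor PCA

The 12 item ratings are standardized and the correlation matrix
eigen-decomposed (correlation rather than covariance, the standard choice
for Likert-scale items; the alternative is unverifiable from the source).
Components are retained by the strict eigenvalue-greater-than-one rule —
an eigenvalue numerically at 1.00 (within 1e-10) is *not* retained — and
no rotation is applied, since the motivating tables show the mid-sized
cross-loadings typical of unrotated components. Loadings are
eigenvector × √eigenvalue, interpretable as item–component correlations;
salience is |loading| ≥ 0.32, sign-blind. Scores are standardized items ×
eigenvectors, so fitted scores have mean 0 and variance equal to the
eigenvalue. Components are sign-oriented so the largest-|loading| item
loads positively. Rows with any missing item are dropped listwise per
scenario. A near-isotropic correlation matrix (all eigenvalues ≈ 1)
makes Kaiser retention unstable; the result is flagged.

## Choice models

Both the binary and the multinomial model are baseline-category logits
fitted by Newton–Raphson on the full likelihood with step-halving, so the
log-likelihood never decreases; convergence requires the score vector to
be numerically zero (max |component| < 1e-8). Standard errors come from
the inverse observed information; effects are reported as exp(β) (AOR for
binary, RRR for multinomial) with 95% Wald intervals exp(β ± 1.959964·se)
and two-sided normal p-values — the Wald form matches the
`exp(β ± 1.96·se)` pattern of the motivating tables, whose exact CI
method is unstated. Categorical covariates are dummy-coded against their
first (or explicitly specified) level; age enters linearly. Separation
is detected (coefficient beyond ±15 or failure to converge) and flagged
per equation with the affected estimates withheld rather than silently
penalized; an optional ridge (off by default) exists for exploration.
Rank-deficient designs are rejected with the offending columns named.
Missing rows are deleted listwise per model and the n actually used is
reported. Outcome categories absent from the data are dropped with a
warning, which is how scenario-specific column sets arise naturally.

Whether the preference-factor models should also adjust for the
sociodemographic covariates is ambiguous in the source; the operation
accepts an optional adjustment set and defaults to scores-only.

## Synthetic data-generating process

The generator's defaults are the study conditions: 106 partner and 97
non-partner providers, a 15-minute budget, a target n of 216, and
covariate marginals matching the published survey (e.g. 150/215
government-paid beneficiaries, 132/216 female, age ≈ truncated
normal(44, 13) on 18–82). Providers place on distinct network nodes; in
clustered mode partners and non-partners draw from separate
Gaussian-kernel cluster centres, which is exactly what creates zones of
low partner but high non-partner access for the sampling rule to find.
Small per-variable missingness (income, medical cost, cost burden,
insurance status) mirrors the varying per-table n of a door-to-door
survey.

Preference items follow x = Λf + ε with f ~ N(0, I₅). The default Λ is a
block structure over the 12 items (block sizes 3, 3, 2, 2, 2) with
deliberately well-separated factor strengths, so that correlation-matrix
PCA retains exactly five components and each estimated component matches
one true factor; near-equal factor strengths would create near-tied
eigenvalues whose sample eigenvectors mix across factors, making recovery
ill-posed rather than merely noisy. Items are generated on the latent
continuous scale and discretised to a 1–5 Likert rating by fixed normal
quantile thresholds (±0.5, ±1.5 sd); the item response scale of the
original instrument is unknown, and a continuous-scale switch exists
because discretisation attenuates correlations, so the closed-form
factor-model correlation limit (corr → normalized ΛΛᵀ as noise → 0)
holds on the latent scale. Choices follow the multinomial-logit DGP on
covariates and f, with per-scenario category sets (the serious scenario
is binary — pharmacy and self-medication collapse away). Default effect
magnitudes are set at the odds/risk-ratio levels reported for comparable
urban insured populations (e.g. other-insurance membership strongly
raising the odds of bypassing partner providers); they are realistic
settings, not reproduction claims — the original individual-level records
are unavailable, so the published coefficient tables are *not*
reproducible and parameter recovery of known DGP effects is the
validation standard instead.

What the generator does not emulate: real street topology (it is a
grid), traffic and time-of-day variation, household clustering within
buildings, interviewer effects, item nonresponse mechanisms beyond
missing-completely-at-random, and any correlation between a household's
location and its survey answers. Passing tests therefore demonstrate the
correctness and calibration of the estimators under a known DGP, not the
external validity of any substantive estimate.

## Validation and problem sizes

The recovery simulations run at n = 50 000 respondents per replicate with
100–300 replicates per target effect (mean bias within 5%; Wald-CI
coverage inside [0.92, 0.98] at these replicate counts); type-I error of
the chi-square (2×3 independent multinomial, n = 400) and pooled t-test
(30 per group) is checked over 5000 null replicates against
[0.042, 0.058]. Shortest paths are verified against exhaustive simple-
path enumeration on graphs of up to 12 nodes, coverage counts against a
cell-by-cell point-in-polygon scan (up to 50×50 grids, 20 catchments),
and the saturated one-covariate logit against contingency cross-product
ratios to 1e-6 relative. The PCA two-block eigenvalue check uses a
constructed item matrix whose sample correlation is exactly r (Helmert
basis), giving the closed-form eigenvalues 1 ± r to 1e-8. The demo city
is a 40×40 grid of 500 m blocks (≈ 20 km span) — large enough that the
15-minute reach covers part, not all, of the city and both classification
schemes and the sampling rule are exercised.

## Known limitations

- Node snapping can misplace a provider by up to half a block on coarse
  grids; the recorded snap distance is the guard.
- Centroid-membership coverage is resolution-dependent near catchment
  boundaries; halving the cell size is the standard sensitivity check.
- The buffered-network polygon is one of several reasonable service-area
  definitions; results near the budget frontier depend on it.
- The Kaiser retention rule is known to be unstable near isotropy; the
  implementation flags that case but does not switch criteria.
- Wald intervals are first-order; with quasi-separated data they can be
  badly calibrated, which is why separation is flagged and withheld
  rather than reported.
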