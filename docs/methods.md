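# Methods

`nestnet` implements an analysis pipeline for home-range use and movement of
a gliding forest specialist (the Siberian flying squirrel, *Pteromys
volans*) in a partly urbanized landscape: movement-burst metrics, habitat
composition and compositional habitat selection, landscape connectivity
between daytime nest sites, and — the centrepiece — a hierarchical Bayesian
Markov-chain model of day-to-day nest-site switching. Because the original
telemetry is not public, a first-class synthetic-data generator reproduces
the statistical structure of such a study so that every stage is testable
end to end.

## Landscape and home ranges

The landscape is a single-band raster at 25 m resolution with five habitat
classes: H1 suitable habitat (mature spruce-dominated forest, the breeding
habitat), H2 movement habitat (other forest taller than 10 m), H3 urban,
H4 unsuitable (clear-cuts, fields, saplings) and H5 water. A planar metric
CRS is assumed throughout; no reprojection is supported. Raster I/O uses
the plain-text ESRI ASCII-grid dialect.

Home ranges are 100 % minimum convex polygons (MCP) of all relocation
fixes, with area in hectares. Composition queries (within a polygon, or
within a buffer of default radius 25 m along a movement path) use the
**cell-center rule**: a cell counts iff its center lies inside or on the
boundary of the (closed) region. The rule is a deliberate choice — how the
original GIS workflow treated partially overlapped boundary cells is not
knowable — and it makes proportions exactly sum to one over counted cells.
H5 is never traversable habitat but is reported by composition queries so
proportions close to 1.

## Movement bursts

A night of telemetry is a sequence of fixes, each with the minutes the
animal stayed put there (0 while moving). A *movement burst* is a maximal
run of movement delimited by stationary periods of at least a threshold
(default 10 min; the field protocol behind the data did not pin a numeric
value, so the threshold is exposed and its effect is monotone: raising it
never increases the number of bursts). The stop fix that ends one burst
also starts the next, so burst lengths partition the nightly distance
exactly. Burst duration excludes time parked at the start or at interior
stops. Consecutive fixes at the same tree are merged, accumulating
stationary time. Downstream mixed models are out of scope; the pipeline
exports a tidy burst/night table (responses, log durations, H1–H3
proportions in the 25 m burst buffer and in the home range) with missing
covariates flagged rather than dropped.

## Connectivity between nest sites

Each individual's nest network yields a log-distance matrix
`D_ij = log(d_ij + 1 m)` and twelve alternative binary connectivity
matrices crossing three choices — allowed habitat {H1} or {H1, H2},
straight-line versus free route, restricted to the home range or not —
with a gap tolerance of 0 (C1–C6) or 50 m (C1g–C6g), the treeless distance
a flying squirrel can glide.

*Straight-line definitions* decompose the segment between two nests
exactly at cell boundaries (a parametric grid traversal, so gap lengths
carry no sampling-step artifacts); every maximal run of arcs through
non-allowed cells is a gap, and the pair is connected iff all gaps are at
most the tolerance. A cell is "allowed" iff its class is allowed and (for
restricted definitions) its center lies in the home range — cells outside
the home range count as gap, not hard barrier, because gaps are defined by
habitat, not by boundaries.

*Free-route definitions* work on the grid graph: allowed cells are nodes,
8-neighbour adjacency gives edges (diagonal habitat runs are traversable),
and under a positive gap tolerance, gap-jump edges join allowed cells whose
centers lie within `max_gap + cell diagonal + res/5` (the glide plus the
grid quantum). A nest reaches every component with an allowed cell center
within `max_gap + half diagonal`; two nests are connected iff their
reachable component sets intersect, or directly if they are within
`max_gap` of each other (a route consisting of a single glide). These
slacks are the minimal ones under which the structural facts hold exactly:
a straight route is a route, and relaxing any constraint never disconnects
a pair (C1⇒C2⇒C4, C1⇒C3⇒C5, C4⇒C6, Cx⇒Cxg). Both facts are asserted
against independent oracles (dense 0.1 m resampling; an explicit-graph
flood fill) on random landscapes.

## The nest-switching Markov chain

An individual with `n` nest sites is a discrete-time Markov chain over
those sites, one step per day. The transition matrix is a row-softmax
multinomial regression on the nest network:

    L = β_I I + (1 − I)(β_D D + β_C C),      P_ij = e^{L_ij} / Σ_j e^{L_ij}

so β_I is the log-weight of staying put and, *conditional on switching*,
β_D and β_C weigh log-distance and connectivity. Observations `Δt` days
apart contribute `log [P^Δt]_{ij}` to the likelihood; weeks with no record
are simply longer gaps, handled exactly by the matrix power. Same-day
duplicates collapse to one observation. The likelihood reduces to
sufficient statistics (per-gap transition-count matrices), computed once
per individual.

Numerics: softmax rows are max-subtracted before exponentiation; matrix
powers use repeated squaring; `log` arguments are floored at 1e−300 (for
finite `L` the floor is unreachable).

## Hierarchical Bayesian estimation

Individual coefficient vectors β_l = (β_I, β_D, β_C) follow
β_l ~ N(μ_l, Σ) with μ_l = α0 + α1·s, sex coded s = −1 (female) /
+1 (male). Priors: improper flat on α; inverse-Wishart on Σ with scale I
and degrees of freedom p + 1 — the minimal value that makes the
distribution proper (4 for the full three-parameter model; note that at
this minimal ν the IW *mean* does not exist, so "prior mean I" is read as
prior scale I). Reduced models (distance only; connectivity only) keep
β_I and shrink the hierarchy to the active components.

Sampling is Metropolis-within-Gibbs, default 25,000 iterations with 5,000
burn-in:

* **β_l** — random-walk Metropolis–Hastings. The proposal is
  `scale_l · Λ_l^{1/2} z`. During burn-in the shape `Λ_l` is re-estimated
  every 50 sweeps from the individual's own draws (trace-normalized,
  adaptive-Metropolis style) and the scalar `scale_l` is tuned
  multiplicatively toward a 0.23 acceptance rate
  (`scale ← scale · exp(observed − 0.23)`). The shape freezes at 80 % of
  burn-in so the scale can re-equilibrate against the final shape; both
  are fixed after burn-in, leaving a fixed Markov kernel. Shape adaptation
  matters: the posterior has a near-ridge (raising every off-diagonal
  entry of a row of L trades off against β_I), and isotropic proposals
  traverse it too slowly for calibrated intervals at practical chain
  lengths. β_I starts at the empirical stay log-odds.
* **α** — exact Gibbs from the multivariate-normal full conditional of the
  linear model β_l = α0 + α1 s_l + ε (GLS mean, design-based covariance).
  With a single sex, α1 is not identifiable; the sampler refuses unless
  configured to pin α1 = 0.
* **Σ** — exact Gibbs from IW(I + Σ_l r_l r_lᵀ, ν + n_ind), r_l = β_l − μ_l.

Update order per sweep: β_1…β_n, then α, then Σ. All randomness descends
from one seed; identical seeds give bit-identical chains. Multiple chains
from dispersed starts support convergence checks (a potential-scale-
reduction diagnostic is included).

Models are compared by the **conditional DIC** focused on the β level:
D̄ + pD with pD = D̄ − D(β̄) at the posterior-mean β. The comparison
family is 1 (distance only) + 12 (connectivity only) + 12 (distance and
connectivity) = 25 models.

## Compositional habitat selection

Habitat use (H1–H4 shares along buffered movement bursts) is compared with
availability (shares within the MCP) by the log-ratio method: per
individual, d_i = ln(used_i/used_ref) − ln(avail_i/avail_ref); Wilks
Λ = |residual cross-products| / |total cross-products| tests mean(d) = 0,
with a p-value from sign-randomization over individuals (exhaustive over
all 2ⁿ flips when n ≤ 12, else 999 + observed Monte-Carlo flips). Λ is
invariant to the reference habitat (H1 by default); if all d vanish
(use ≡ availability) Λ is defined as 1. Zero *used* proportions are
replaced by 0.01 without renormalizing (the common implementation of the
method; switchable in principle, documented here). Log-ratios undefined
because a habitat was *unavailable* to an individual are imputed with the
cross-individual mean of that log-ratio; a habitat unavailable to everyone
is an error. The ranking matrix is the antisymmetric matrix of mean
pairwise log-ratio differences; each cell gets its own univariate
sign-randomization p-value (the original sub-test is unstated; we use
randomization for consistency), and ranks are positive-entry row counts.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study magnitudes:

* **Landscape** — 2 × 2 km at 25 m; class mixture 32 % H1 + 20 % H2
  (52 % forest), 38 % urban, 7 % unsuitable, 3 % water. Patches are grown
  from random seeds to exact per-class cell quotas (typical diameter
  ~200 m), so realized proportions match targets to rounding and
  connectivity definitions meaningfully differ. A fractal-noise generator
  would not give controllable contiguous patches.
* **Population** — 10 females + 10 males; nests per individual drawn
  around 4.2 (SD 1.6) for females and 7.0 (SD 2.7) for males, minimum 2;
  nest placement biased 67/20/10/3 toward H1/H2/H3/H4 within sex-specific
  cloud radii (300 m F, 1000 m M, echoing maximum inter-nest distances of
  ~600 m vs ~2000 m); nest structures 48 % cavities / 41 % twig / 8 %
  box / 2 % building. Home ranges are MCPs of nests plus a jittered
  relocation cloud.
* **Switching model truth** — α0 = (1.2, −0.4, 0.6), α1 = (0.2, −0.1, 0.2),
  Σ = diag(0.3, 0.05, 0.2). These are not published values (the source
  study prints no fitted coefficients); they were chosen once to give a
  daily stay probability around 0.6–0.8 and weekly-scale switching, i.e. a
  squirrel that changes nests frequently but not chaotically, with a clear
  negative distance effect and a moderate connectivity effect. Sequences
  are simulated from the model itself under the C5g connectivity matrix of
  the generated landscape, on a daily schedule over 120 days with 10 % of
  days missing (so Δt mixes 1–3 days).
* **Telemetry** — correlated random walks around the nest cloud with
  planted ≥ 25-min stops every 10th fix and sex-specific step scales
  (female bursts shorter than male), clipped to the landscape.

Limits worth keeping in mind: the simulated tracks are habitat-blind, so
compositional analyses on synthetic tracks show weak or no selection —
they exercise the machinery, not the biology; nest-switching is generated
from exactly the fitted model class, so recovery tests demonstrate sampler
calibration, not robustness to misspecification; and the landscape has no
roads, edges or within-class heterogeneity.

## Problem sizes used by the test suite

Sampler calibration checks run at deliberately reduced scale, chosen as
the smallest sizes at which the properties are cleanly decided: parameter
recovery uses 20 replicate studies (10 F + 10 M, ~5/7 nests, 120 days)
fitted with 5,000-iteration chains; DIC model recovery uses 10 replicates
of a 10-individual study against a reduced family (distance-only, the
generating distance + C5g model, and a deliberately wrong distance + C2
model); conjugacy moment checks use 50,000 exact Gibbs draws; connectivity
oracles run on 50 random 60 × 60 rasters. The acceptance-rate target runs
one full-length chain (25,000 iterations, 5,000 burn-in).

## Known limitations

* Free-route connectivity is grid-graph reachability; least-cost paths,
  resistance surfaces and graph centralities are out of scope.
* The DIC is conditional on β; a marginalized focus would need integrating
  over the hierarchy and is not implemented.
* GLMM fitting and AICc model averaging for the movement responses are
  intentionally left to standard mixed-model software; this package stops
  at the tidy model frame.
* With very few individuals (≤ 6) the hierarchy's posterior is heavy-tailed
  and chains mix slowly; convergence diagnostics across dispersed starts
  are recommended at that scale.
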