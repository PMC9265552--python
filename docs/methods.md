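# Methods

This note records the statistical model behind each stage, the parameters
that matter, the design choices made where convention did not settle the
question, and what the synthetic-data tests do and do not establish.

## Indirect standardization and the expected-case background

Cancer incidence in the reference setting varies by two orders of magnitude
across gender–age strata (from ~42 to ~4372 per 100,000 over five years), so
raw case maps are dominated by where old people live. We remove this by
indirect standardization: county stratum rates r_j = C_j/N_j (kept
internally as proportions; the ×100,000 scaling is presentation only) are
applied to each village's stratum populations,

    E_i = Σ_j N_ij · r_j ,    SIR_i = O_i / E_i .

When the r_j come from the pooled county data, Σ E_i = Σ O_i identically;
this conservation is asserted to 1e-9 relative tolerance in the tests and is
the invariant that justifies using the expected-case raster as the Monte
Carlo "control". SIR is flagged undefined (NaN) where E_i = 0. Coarse
gender–age groups can be formed from five-year census bands by greedily
merging contiguous bands whose crude-rate ratio stays below a configurable
threshold (`merge_strata_by_rate`); the threshold is a free parameter
because no single similarity criterion is canonical.

Village expected counts are spread over raster cells **proportional to each
cell's population**, not uniformly by area: the background must put expected
risk where people live, which is the entire point of using a gridded
population. Cells are assigned to villages by nearest village point
(equivalently, cell-center containment in the clipped Voronoi cell).

## Heterogeneous-background KDE

Both the case points and the expected-case raster are smoothed with the same
kernel specification and the intensity is the cellwise ratio. The kernel is
the 2-D quartic (biweight) K(u) = (3/π)(1−u²)², u = d/h < 1 — the convention
of GIS density tooling, with compact support that keeps computation local; a
3σ-truncated, renormalized gaussian is available as an option. Distances are
planar Euclidean in projected meters; geographic coordinates are rejected at
the IO layer rather than silently reprojected.

Bandwidths: fixed (defaults 1/3/5/10 km) or adaptive, where each kernel
grows until it covers at least k cases (defaults k = 1/3/5/10; a case
coincident with its own case-based center counts as the first, so k = 1 at a
case yields the floor bandwidth, which defaults to the cell size). With
fixed bandwidths the geo-based (bandwidth anchored at each evaluation cell)
and case-based (anchored at each kernel center) conventions are the same
estimator and the implementation makes them bitwise equal; in adaptive mode
they genuinely differ and both are provided.

Numerics: point-based KDE is evaluated exactly on the kernel's support
window (it matches an independent double-loop oracle to 1e-10 on 50 points ×
10⁴ cells). When cases are given as per-cell counts — always the case inside
the Monte Carlo loop, where cases are deconstructed to cell centers — the
same estimate is computed by convolution; adaptive bandwidth fields are
quantized to the cell size (error ≤ half a cell) so that each distinct value
is one convolution. The ratio is NaN where the smoothed background falls
below a floor (default 1e-6 cases/km²) instead of being divided. **No edge
correction is applied**; mass-conservation holds for interior kernels only,
and conservation tests restrict accordingly. This is a deliberate fidelity
choice and a known limitation near the county boundary.

## Monte Carlo significance

Case addresses are known only to village. Each *restricted* realization
scatters every village's observed count over that village's own cells,
multinomially with probability ∝ expected mass (counts preserved exactly).
The *unrestricted* null scatters the county total over all cells by expected
mass: the null hypothesis is "cases follow the demographic risk surface
exactly", so flagged cells mean excess beyond demography. Per cell,

    p = (#{null intensity ≥ actual intensity} + 1) / (k + 1),

ties counting toward exceedance. One shared ensemble of k null surfaces is
compared against r restricted realizations, so the spread of the r p-surfaces
isolates the placement (address) uncertainty of the observed cases — this is
what std_p is meant to measure; redrawing nulls per realization would mix
null-sampling noise into it. A cell is a hotspot when mean_p + 2·std_p < α.
Defaults k = 999 (making the smallest attainable p = 0.001), r = 19 in the
library default, r = 5 in the bundled simulation studies (a
runtime/stability compromise; both configurable), α ∈ {0.001, 0.005}.

Note an arithmetic consequence of the strict inequality: with k simulations
the smallest attainable mean_p is 1/(k+1), so k = 199 can never flag at
α ≤ 0.005, and even k = 999 cannot flag at α = 0.001 (0.001 < 0.001 is
false). The implementation warns when 1/(k+1) > α. The bundled
cluster-recovery studies therefore run k = 999 at α = 0.005; the type-I
study runs the stricter α = 0.001 setting, where the rule is maximally
conservative. Cold spots (left tail) are implemented symmetrically behind a
flag, default off.

Robustness across bandwidths is handled by consensus: the per-setting binary
masks are summed cellwise, and cells flagged under at least a quorum of
settings (default 2) are "certain" hotspots.

## Geographical detector

q = 1 − SSW/SST with population (1/N) variances, so SSW and SST are literal
sums of squares and q ∈ [0, 1] with q = 1 iff Y is constant within every
stratum. Continuous factors are discretized by quantiles (default 5 classes,
ties broken by value then village ID for determinism); equal-interval and
user-supplied stratifications are also supported. Significance is a
permutation test (default 999 label shuffles) rather than the noncentral-F
approximation: it is exact at these sample sizes and assumption-free, and
the output metadata says so. The interaction detector overlays two
stratifications (Cartesian label pairs; empty combinations simply do not
occur) and classifies q12 against q1, q2 with a 1e-9 tolerance at the class
boundaries, since floating-point equality is otherwise meaningless.

## GTWR

One weighted least squares fit per observation, gaussian weights on the
additive space-time distance d² = d_S² + (λ_t·Δt)² — the standard GTWR
construction. λ_t (meters per year) converts temporal separation to the
spatial metric; λ_t = 0 reduces to GWR, b → ∞ to global OLS (verified to
1e-6 against an independent OLS fit). Covariates are z-scored internally for
conditioning; coefficients *and their covariances* are mapped back to the
original scale exactly through the linear back-transform, so reported
standard errors are scale-correct. Local inference uses pseudo-t statistics
with effective degrees of freedom n − 2tr(S) + tr(SᵀS) from the hat matrix —
the conventional GWR-family approach, used here because the significance
maps it feeds (coefficients shown where local p < 0.01) need *some* local
test and no better-calibrated closed form exists. A small ridge term
resolves locally singular systems; bandwidth and λ_t can be chosen jointly
by leave-one-out cross-validation on a grid.

## The synthetic county

The generator emulates the study conditions of a mid-sized Chinese county:
293 villages in a ~625 km² rectangle (100 m cells), total population 524,799
split over the eleven reference gender–age strata, five registry years, and
annual stratum rates equal to the printed five-year rates divided by five so
that expected five-year totals match the reference table. Village points are
uniform with a 2×cell-size minimum separation (keeps Voronoi cells
non-degenerate); population density is a mixture of village-centered
gaussians (lognormal sizes, 300–800 m spreads) over a small rural floor,
with each stratum's county total allocated exactly by largest-remainder
rounding. Cases are Poisson — the standard registry model at rates ≤ ~4% —
with village relative risks of 1 outside planted circular clusters. A
synthetic river polyline and facility points sit on the cluster centers so
that distance covariates carry real signal for the detector and GTWR stages.
All randomness flows from one seed through fixed stage offsets, so fixtures
are bitwise reproducible.

Simulation studies use a scaled county — 50 villages, 10 km extent, 250 m
cells, one tenth of the population — chosen so the full Monte Carlo study
(20 seeds × 999 simulations × several bandwidths) completes in minutes on a
single core; recovery and error-calibration conclusions were stable between
this and larger configurations. When clusters are planted, a village is
pinned at each cluster center so "is the cluster center flagged?" is well
defined regardless of random placement.

**What passing tests show — and do not.** The synthetic county has
homogeneous stratum rate *ratios* across villages, exactly Poisson counts,
exactly circular clusters, and covariates constructed to correlate with the
planted risk. Passing recovery tests therefore demonstrates that the
pipeline's machinery is correct and has power under its own assumptions; it
does not validate the method against misspecification (overdispersion,
registry under-ascertainment, address errors beyond village level,
non-circular exposure plumes), none of which the generator emulates.

## Degenerate inputs and tie-breaking

Duplicate village coordinates, points outside the boundary, all-zero
expected surfaces, villages with cases but no within-village expected mass,
constant outcomes in the q-statistic (SST = 0), and constant covariates in
GTWR all raise errors naming the offending object. Quantile ties are broken
deterministically; Monte Carlo ties count toward exceedance; hotspot masks
are exactly 0/1 surfaces and consensus counts are their integer sums.
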