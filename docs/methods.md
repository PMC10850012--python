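# Methods and modelling notes

## The mass-balance model

Every living group is assumed to be at steady state over the modelling
period (the packaged ponds use a 300-day culture season; `period_days`
is stored so all rates stay per-period and no unit conversion ever
happens implicitly). The master equation per group,

    B (P/B) EE = Σ_j B_j (Q/B)_j DC_j· + Y + E + BA,

balances production used inside the system against predation, catches,
net migration and biomass accumulation. Consumption is partitioned as
Q = P + R + U with U = GS·Q; a negative R is physically meaningless
and is therefore a first-class audit flag rather than an exception, so
unbalanced drafts of a model can still be inspected.

Unknown parameters (at most one of {B, P/B, Q/B, EE} per living group)
are solved in one linear system. Every product in the master equation
contains at most one unknown, so the system is linear exactly; solving
all equations simultaneously removes any dependence on iteration
order when an unknown biomass of a prey appears inside another group's
predation term. Two identifiability caveats are deliberate behaviour:

* a group with zero production facing positive demand makes the system
  singular (reported as such, naming the groups involved);
* Q/B never enters its own master equation, so it is identifiable only
  when a consumption loop (cannibalism) closes the system; otherwise
  the solver reports a singular system. Practitioners normally supply
  Q/B via a P/Q ratio instead.

## Detritus routing

Egestion plus non-predation mortality of each living group is routed
to the detritus pools by a per-group fate vector; any shortfall
relative to 1 leaves the system as export. Pools settle in topological
order of their surplus-routing links (cycles among pools are
rejected): inflow = imports + routed flows + upstream surplus;
consumption by detritivores is the outflow; the EE of a pool is
consumption/inflow. Unrouted pool surplus follows a per-group
disposition: `export` (water-column detritus washed out with effluent)
or `accumulation` (sediment build-up that stays inside the pond until
draining and therefore does not enter the throughput). In the packaged
ponds the sediment pool accumulates and the water pool passes a fitted
~20 % of its surplus down to the sediment pool.

The summary statistics count as "flow into detritus" only what
actually reaches a pool (routed flows plus imports); unrouted shares
are exports. Total system throughput is defined as
TST = TC + TAE + TR + TD and closes exactly by construction; the
accumulation term sits outside TST and is reported separately.

## The packaged pond models

The two CSV model directories encode the published monoculture (16
groups) and 80:20 polyculture (18 groups) grass-carp pond webs; the
inline CSV comments carry per-value provenance. Resolutions that go
beyond straight transcription:

* the monoculture water-bacteria P/B is stored as 164.3: the printed
  value is internally inconsistent with the system respiration total,
  the bacteria detritus flow and its printed EE, all three of which
  agree with 164.3;
* two printed diet columns that sum to 1.0005/0.9997 are renormalized;
* fish catches are set to P·EE (fish have no predators and are fully
  harvested at season end);
* a net-migration term closes the balance for groups whose published
  EE exceeds what predation plus catch explain by more than 1 %
  (benthos and sediment bacteria are removed with the sediment at
  draining); it is derived, not measured;
* the water-column fate fraction f_w (0.2845 / 0.3161) and the
  water→sediment surplus fate (~0.20 in both ponds) are fitted once so
  the pool EEs and the inter-pool flow match their published values;
  they are fixture constants, not free parameters of the methods.

Re-solving every living EE from scratch reproduces the published
efficiencies within 1 %, the published per-group flows to detritus
within 2 % (the one documented exception is the polyculture Copepoda
row, whose printed value contradicts its own parameters by ~2.4 %),
and the published trophic levels to ±0.005.

## Trophic structure and aggregation

Effective trophic levels solve tl = 1 + DC·tl with producers and
detritus-type groups pinned at 1 (imports carry level 1; feed and
precipitation are level-1 pools). The same recursion yields each
group's fractional composition over integer levels, which apportions
consumption, respiration, exports and detritus flows onto the Lindeman
spine. Transfer efficiency per level is (flow to the next level +
catches and migration at that level) / level throughput; the mean is
the geometric mean over levels II–IV. Level I pools net primary
production together with the detritus inflows, mirroring the
producer/detritus double box of conventional spine diagrams.

The per-group "origin of flow" decomposition (share of consumption
tracing back to detritus vs producers) reproduces the published
per-group proportions to three decimals. The system-level detrital
fraction is defined here as the detrital share of level-I inflow;
the value printed for the study ponds (≈68 %) appears to follow a
different, undocumented weighting and agrees with ours only to a few
points.

Omnivory is the diet-weighted variance of prey levels about the
predator's feeding level; the system index weights consumers by
log(consumption) (clipped at zero), a convention choice the source
material does not pin down — treat SOI comparisons across software as
±20 %. Connectance defaults to L/N² over living groups (which matches
the published values to 0.6 %); L/(N(N−1)) is selectable.

## Cycling and information indices

Finn's cycling index uses the input-normalized flow-fraction matrix G
over all compartments (consumption flows plus detritus routing),
N = (I − G)⁻¹, and cycled throughflow Σ T_j (N_jj − 1)/N_jj, expressed
as a percentage of TST. It is zero on acyclic webs and invariant under
uniform flow scaling (both property-tested). The packaged ponds give
22.3 % and 25.2 %; published figures for these systems are some eight
points higher, a gap consistent with variant treatments of the
import-fed pools in cycling routines — comparisons of absolute FCI
across implementations should allow for that.

Ascendency, overhead and development capacity are computed with
base-2 logarithms on the boundary-extended flow matrix (import row;
export column carrying catches, migration, unrouted surplus and
accumulation; respiration column). A + O = TDC identically and all
three scale linearly with flows; the organization ratio A/TDC of both
ponds is ≈ 0.34. Absolute flowbit totals are convention-sensitive;
ratios are the comparable quantity.

## Impacts and overlap

The mixed trophic impact matrix inverts I − q, where q holds diet
fractions (positive, prey→predator) minus predation shares (negative,
predator→prey) taken over biological consumption only — harvest is not
modelled as a fleet compartment. Detritus pools are donor-controlled:
zero diet rows, active predation columns. Because those shares sum to
one, q generally has spectral radius ≥ 1 and the impact-path series
does not converge term-by-term; the inversion is its closed-form
summation, and the implementation is verified against the defining
fixed point M = q + qM and against hand-inverted examples. Pianka
overlap is the normalized inner product of diet vectors (prey overlap)
or predation-composition vectors (predator overlap); groups without a
diet or without predators get zero rows, flagged by a zero diagonal.

## The synthetic generator

`generate_web` emulates the structure of pond webs — import-fed pools,
internal water/sediment-style detritus pools, optional bacterial loops
feeding 95 % on a pool, a consumer guild ordered so prey precede their
predators — and constructs flows first: diets are Dirichlet draws,
consumption is fixed from the top predator down, and production,
biomass, rates, catches and imports are back-derived so every living
EE equals a planted value in [0.05, 0.95] and respiration is strictly
positive. There is no rejection sampling; one seed determines the web
exactly, and the planted EEs, flow matrix and trophic levels are the
ground truth the solver must reproduce to 1e−9.

What the generator does not emulate: seasonal dynamics, stanza/age
structure, nutrient limitation, behavioural diet shifts, or empirical
noise in measured biomasses. Passing the recovery and property tests
therefore demonstrates the correctness of the accounting and solving
machinery, not the fidelity of any particular field parameterization.

## Numerical conventions

* Master-equation residuals below 1e−6·max(P, 1) count as balanced;
  larger residuals are audit diagnostics, not errors.
* Diet rows must sum to 1 within 1e−6; zero flows contribute zero to
  the information indices by convention.
* Trophic-level fractions are truncated at level 10 and renormalized;
  webs whose diets concentrate near the base (all tested webs) lose
  mass < 1e−9 to the truncation.
* Dense numpy linear algebra throughout; the webs this package targets
  have tens of groups, far below any scale where sparsity matters.
* CSV serialization keeps 12 significant digits, making write/load
  round trips lossless at 1e−9 relative tolerance.

## Known limitations

* No dynamic (time-forward) simulation; the model is steady-state.
* No fleet compartments, pedigree scoring or diet auto-rebalancing;
  the audit reports violations and leaves adjustment to the modeller.
* Absolute FCI and flowbit totals are implementation-convention
  dependent (see above); use ratios and directions for comparisons.
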