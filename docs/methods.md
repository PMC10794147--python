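# Methods

This note documents the models implemented in `multinuc`, the conventions
and parameter choices behind them, what the miniature fixture systems do and
do not emulate, and the numerical decisions that affect results.

## Lattice and glue conventions

Tiles are abstract unit squares on a square lattice; the slanted geometry of
the physical single-stranded tile (SST) motif is abstracted away.
Coordinates are 0-based and row-major; N = (r−1, c), S = (r+1, c),
W = (r, c−1), E = (r, c+1).  Connectivity is the 4-neighbourhood only —
diagonal contacts carry no bonds.  A glue label `g` binds exactly its
starred complement `g*` (complement of complement is identity); sides bind
N↔S and E↔W.  The null glue (represented as `None` / JSON `null`) binds
nothing and is required on every shape boundary edge.  Physically a tile is
a 42-nt strand with alternating 10- and 11-nt binding domains
(`SST_DOMAIN_LENGTHS`); nothing at sequence level is represented.

## Assembly free energy

For a partial assembly *A* with *B* internal bonds,

    G(A) = Σ_{i∈A} G_mc^i − B·G_se − α,    G_mc^i = α − ln(c_i/u0),

in units of RT, with natural logarithms.  Defaults are `u0 = 1 M` and
`α = 0`.  These are pure conventions: α cancels in the monomer free energy,
in every attachment ΔG, and in all rate *ratios*, which are the only
quantities used downstream; absolute rates carry arbitrary units throughout
the package.

Temperature dependence is optional and enters only through the bond
strength: `G_se(T) = (−ΔH° + T·ΔS°)/(R·T)` with a per-bond enthalpy ΔH°
(kcal/mol) and entropy ΔS° (kcal/mol/K), R = 1.9872×10⁻³ kcal/(mol·K), T
absolute.  `EnergyParams.from_bond_thermo()` builds these from a bond
free-energy design target, default −9.0 kcal/mol at 53 °C with
ΔH° = −80 kcal/mol — a typical design point for 10–11-nt binding domains
between their melting and growth temperatures.  A fixed-`G_se` mode bypasses
temperature entirely; the worked examples in the tests use `G_se = 3` with a
uniform chemical potential `G_mc = 5` (the regime
`G_se < G_mc < 2·G_se` where one bond is insufficient and two are
favourable), and the fixture classification studies use `G_se = 10.5` with
concentrations of 50–880 nM, the same regime at realistic concentrations.

## Stochastic Greedy Model (SGM)

A growth path starts from a chosen monomer and repeatedly adds one tile on
the frontier of the current assembly, confined to the target layout (each
location grows its correct tile; chimeric growth is not sampled):

* while any frontier attachment has ΔG < 0, the most favourable one is made
  deterministically (ties broken by row-major location order); favourable
  attachments only lower G, so exhausting them one at a time leaves the
  barrier unaffected;
* otherwise one unfavourable attachment is chosen with Boltzmann probability
  ∝ e^(−ΔG) — the thermodynamically natural reading of weighting by relative
  free-energy differences; a linear-in-(−ΔG) weighting is available behind
  the `unfavourable_weight` switch;
* the path stops at full coverage, at a configurable size cap, or once the
  running G has dropped 10 RT (configurable `commit_margin`) below the
  running maximum — at that point the path is committed to downhill growth
  and its barrier is fixed.  Tests that compare against the exhaustive
  oracle disable the margin so paths complete.

The barrier of a path is the highest G visited; the barrier state is the
assembly at that point.  Rates are estimated from `n_paths` paths per start
site over all start sites.  Each *distinct* barrier state (identical
occupied set) contributes once — deduplication prevents double-counting
critical nuclei reached via different growth orders — with the Arrhenius
form `exp(−G(A_s)) × Σ_forward c/u0`, summing the second-order forward
attachment flux over the state's frontier (no per-tile rate constants).
Accumulation is in log space (`logsumexp`), so barriers of hundreds of RT
do not underflow.

Diagnostics: a per-location participation map (fraction of sampled paths
whose barrier state contains the location), the per-start minimum barrier,
and the seed-size statistic K (median barrier-state size over paths), which
shrinks as `G_se` rises — colocalization acts over a smaller area at lower
temperature.

Correctness anchor: on layouts of ≤ 9 tiles the test suite computes the
exact minimax barrier (minimum over all single-tile-addition orders of the
maximum G, by Dijkstra-style search over the connected-subassembly lattice)
and checks that SGM sampling reaches it and never undercuts it, for uniform
and for randomly non-uniform concentrations.

## Window Nucleation Model (WNM)

The fast proxy sums, over every k×k window lying fully inside a shape, the
equilibrium weight of the assembled window:
`exp(Σ_{i∈window} ln(c_i/u0) + B_w·G_se)` with `B_w = 2k(k−1)` internal
bonds.  Windows never extend across unoccupied canvas.  The score is
monotone in every concentration and is used wherever many rate evaluations
are needed (training, the anneal model).  Default k = 2; the fixture
classification and anneal studies use k = 3, for which a window spans five
chequerboard (shared-sublattice) cells and discrimination between
colocalized and scattered enhancement is strong.

## Merge designer

The unique initial design gives every occupied location its own tile and
every internal edge its own glue pair.  Merging repeatedly identifies two
tiles drawn from two different shapes whose null glues (if any) sit on the
same sides — the stricter reading of side compatibility — and never two
tiles that exist only in the same single shape.  Glue identifications
propagate through a union–find over labels in which identifying `g ≡ h`
also identifies `g* ≡ h*`; a class that would contain both a label and its
own complement rejects the merge (a glue cannot be self-complementary).
Canonical labels prefer unstarred names so complement structure survives
rewriting.  After substitution, tiles with identical four-glue signatures
collapse to one type; a collapse that would place one tile type twice in a
single layout rejects the merge.

Every candidate system must pass layout validation and two proofreading
criteria, checked against the full pooled tile set (errors can come from any
shape's tiles, since all tiles are mixed together):

* **self-healing** — at every location, every wrong tile bonds at most one
  of the four glue constraints presented by the location's correct
  neighbours.  The all-four-neighbour profile is the worst case; match
  counts are monotone under neighbour subsets, so the check covers every
  correct subassembly.
* **second-order sensitivity** — for every wrong tile that attaches by
  exactly one bond, no further tile can attach by two bonds in its
  neighbourhood using the erroneous tile's glue plus correct neighbours
  (positions outside the shape are included; the worst case assumes all
  correct neighbours present).  Deeper error chains are out of scope.

Both checks are index-accelerated but verified in the test suite against a
brute-force enumeration written independently, including the full witness
sets, on the 42-tile fixture and on adversarial hand-built failures.

Proposals are drawn uniformly at random from the untried eligible pairs;
"no further acceptable merges" means every currently eligible pair has been
tried and rejected since the last accepted merge.  The first phase is
restricted to one chequerboard parity (configurable, default even), which
is likelier to be mergeable; the second phase opens to all tiles.  Across
restarts the smallest system wins.  Everything is driven by one seeded
generator, so runs are reproducible.

## Image standardization and the concentration map

Images are resampled to 30×30 by exact box-overlap (area-average)
resampling, then pixels are ranked by intensity (ties broken by row-major
scan order) and assigned ten grayscale levels `p = k/9, k = 0..9` according
to a fixed standard histogram.  This makes the output invariant under
monotone intensity transforms and idempotent on standardized images.

The ten level concentrations are `c·e^{3·p·ln 3}` with base
`c = 16.67 nM` — geometric from 16.67 to 450 nM, factor 3^(1/3).  The
standard histogram is **frozen here as part of the file contract**:
(254, 185, 135, 99, 72, 53, 38, 28, 21, 15) over levels 0..9.  It was
derived once as the integer histogram closest (largest-remainder rounding)
to the geometric level profile n_k ∝ ρ^k whose mean tile concentration is
exactly 60 nM over 900 pixels (ρ ≈ 0.7303); the frozen integer counts give
60.09 nM, i.e. 60 nM to the nearest nM.  For toy images with fewer pixels
the histogram is rescaled by the same largest-remainder rule.

A pixel-to-tile map θ assigns pixels to tiles injectively.  Tiles not
assigned by any pixel stay at the base concentration; *reserved* tiles
(fluorophore/quencher label locations, which must not vary in
concentration) are constrained to that unassigned pool and are never
assigned to pixels — with a 917-tile pool and 900 pixels, 17 tiles remain
unassigned.

**Flags** are the hand-designed pattern family: all tiles at a base
concentration (default 50 nM) except the shared-sublattice tiles inside one
window of one shape (default 5×5, 880 nM).  The chequerboard parity of the
shared sublattice is read from the system's sharing structure (the parity
class holding more multi-layout tiles in that layout), falling back to the
window-corner parity on a tie; tiles unique to the shape are never
enhanced, so the flag biases nucleation kinetics without directly biasing
the thermodynamics of any one structure.  A full 5×5 window holds 13 cells
of the corner parity and 12 of the other.

## Training the pixel-to-tile map

The loss for a candidate θ sums over training images

    −( log r_on − log Σ_off r_off )

on per-shape log nucleation scores (WNM or SGM), plus two optional
penalties: λ_site times one minus the preference-weighted share of SGM
nucleation participation inside user-preferred regions of the on-target
shape (the neutral default is no site weighting), and λ_rep times the
number of reserved-tile assignments (always zero for maps produced here,
where reserved exclusion is a hard move constraint).  The published
heuristic is not available in closed form; this softmax-margin form is this
package's own documented stand-in, validated by behaviour — correct toy
classification, recovery of planted colocalized problems, and the capacity
decline below — rather than by matching any reference loss values, and all
weights are configuration.

Optimisation is strict-improvement hill climbing over two move types (swap
the tiles of two pixels; swap an assigned tile with an unassigned
non-reserved one), so the loss trajectory is non-increasing by
construction and θ validity is preserved by every move.  Plateau moves are
rejected; restarts supply the exploration.  The standard schedule runs many
cheap WNM-loss steps and then refines the WNM optimum under the SGM loss
(`train_theta(wnm_steps=..., sgm_steps=...)`), with the SGM made
deterministic by a fixed internal seed so hill climbing compares like with
like.

On a 6-pixel, 6-tile, two-shape toy problem the suite verifies that 20
restarts of hill climbing attain the global optimum found by exhaustive
search over all 720 assignments.  On the three-shape fixture, training with
one image per class reaches accuracy 1.0 and the mean training accuracy
over ten seeds is non-increasing as the images per class grow from 1 to 6 —
the associative-memory-like capacity decline (at fixed optimisation budget
of 150 WNM steps per run).

## Winner-take-all anneal model

The competition model is a deterministic mean-field caricature — the
package's own documented definition, constrained to reproduce the
qualitative behaviours expected of nucleation/growth competition — not a
reversible kinetic simulation.  Per shape s with layout L_s:

    dN_s/dt = k_n · min( WNM_s(c(t), T(t)) · u0 ,  c_scarce,s )
    dA_s/dt = k_g · N_s · max(0, ⟨c_i − c_eq(T)⟩_{i∈L_s}),  c_eq = u0·e^{−2·G_se}

N_s is nucleated assemblies (nM), A_s incorporated tiles (nM).  Two choices
matter and are deliberate:

* the WNM score times u0 is the equilibrium concentration of assembled
  critical windows; it is **capped by the scarcest free member tile**,
  because an equilibrium occupancy cannot exceed its limiting species.
  This cap makes nucleation rate-limited near the window melting point and
  is what gives anneal *speed* its leverage;
* growth per site is forward attachment minus detachment, `c − c_eq` —
  bounded by the free concentration (attachment is second order in reality)
  and zero exactly where 2-bond attachment is neutral (`2·G_se = G_mc`).
  This is the same net-attachment-bias quantity `e^{−ΔG} − 1` expressed on
  the concentration scale (they differ by the factor c_eq(T)), with the
  advantage of not diverging at low temperature.

Growth consumes tiles pro rata (an assembly draws each of its constituent
tiles equally, 1/|L_s| of its growth per tile type); A_s is capped at
N_s·|L_s| (assemblies complete); nucleation of a shape stops when any
required tile falls to a floor fraction of its initial value (default 1%);
total consumption is jointly scaled back so no free concentration goes
negative.  Integration is explicit Euler with these per-step clips; the
bookkeeping identity free + incorporated = initial is asserted every step
and the simulation aborts with a diagnostic if it drifts, which is the
step-too-large signal.  Halving the default step changes final selectivity
by well under 1% on the fixture.

Defaults `k_n = 0.1/h` and `k_g = 3.6/(nM·h)` set the overall time scale
relative to the anneals studied (tens to hundreds of hours); `k_g` is the
order of a typical DNA tile attachment rate constant (10⁶ M⁻¹s⁻¹), and only
ratios of nucleation rates are meaningful.  Selectivity is on-target
cumulative nucleation over total, reported as undefined (None) when total
nucleation is exactly zero.

With a shared tile pool, a slow anneal lets the early-nucleating shape
deplete the common tiles before the competitor's nucleation window opens,
raising selectivity; with disjoint pools the same slow anneal only gives
the competitor more time, lowering it.  This contrast holds across fixture
seeds and is exercised at ramps of 15 h versus 150 h over 66→56 °C — a
temperature range matched to the fixture's own melting window under the
default bond thermodynamics (its 10×10 shapes at 50–880 nM melt higher
than a 24×24 system at 50 nM would).

Temperature protocols are piecewise-linear segment lists.  The presets
follow the experimental pattern: 71→53 °C in 40 min, 1 °C/h down to the
initial growth temperature, a main growth segment (47 °C held 51 h;
48→46 °C over 100 h; or 48→45 °C over 150 h), then a final cool to 39.5 °C
at 1 °C per 26 min.  The end of the main segment defines the growth-time
reference used by the fluorescence analysis.

## Fluorescence quench analysis

Each trace is normalized to its own maximum.  The quench time is the first
time the signal falls 10% below the reference level, linearly interpolated
between samples; the growth time is max(0, growth-segment end − quench
time), zero when quenching never reaches 10%.  Per-shape growth time is the
mean over that shape's labels across samples; the selectivity fraction is
on-target growth over the summed shape growth times, with ternary
coordinates the per-shape fractions — reported as undefined rather than
NaN when the total is zero.  Sampling intervals of 12 or 30 min are both
supported; nothing in the analysis assumes a specific interval.

Two robustness choices, both switchable:

* the drop is referenced to the **running** maximum by default (robust to
  signals that drift upward after an early drop); a global-maximum mode
  matches plain max-normalization referencing, and the two agree whenever
  the maximum precedes the drop;
* the signal is pre-smoothed with a centred 5-sample rolling median, and
  the reference level is an **unbiased plateau estimate** — the median of
  samples within 3% of the maximum, re-centred once — rather than the raw
  maximum, whose own extreme-value statistics sit ~2 standard deviations
  above the plateau under multiplicative noise and would bias every quench
  time early.  On locally monotone stretches the rolling median passes
  samples through unchanged, so noise-free crossings are still exact to
  interpolation.

The synthetic trace generator produces a drifting baseline times a logistic
quench of configurable depth (default 0.6) and width (default 1 h), with
multiplicative log-normal noise, positioned so the clean curve's
10%-below-maximum crossing sits exactly at the scheduled time; the schedule
is returned as ground truth.  At zero noise recovery is exact to
interpolation; at 2% noise ≥95% of quench times are recovered within one
sampling interval.  AFM shape counts are accepted only as pre-counted
tables and aggregated (means over samples, fractions, ternary coordinates);
no image analysis is performed.

## Fixture systems

The published-scale system (three 24×24 shapes, 917 tiles) is optional
input data; everything in the repository runs on miniature synthetic
analogues:

* **mini three-letter system** — three 5×5 letter masks (13 + 14 + 15
  cells).  Its fully unique design (42 tiles, 42 glue pairs) is small
  enough for the exhaustive proofreading oracles, and the merge designer
  compresses it to ~25 tiles with both criteria intact.
* **shared-block fixture** — n×n fully occupied shapes (default 10×10)
  whose even chequerboard sublattice carries one shared tile pool, arranged
  row-major in the first shape and in seeded random scatter in the others,
  with shape-unique interaction tiles on the odd sublattice.  This mirrors
  the shared/interaction sublattice structure of the full design and is the
  substrate for flag classification, training, and anneal studies.  Its
  tiles carry only null glues: it defines occupancy, sharing and
  concentration structure, not a glue-valid design — nucleation models read
  only layout adjacency and concentrations, so glue validity is not needed
  there, and glue-valid systems come from the merge designer.

What passing tests on these fixtures do **not** show about real data: no
chimeric or off-lattice growth is sampled (paths are confined to one target
layout); the anneal model is mean-field, with no stochastic nucleation
timing, spatial effects or assembly-size distribution; fixture shapes are
solid blocks or thick letters, not 24×24 structures with corners and
defects; synthetic quench curves have a single clean quench event, while
real traces carry temperature-dependent fluorophore artefacts and
assembly-intermediate effects that are out of scope here.

## Numerical choices and degenerate inputs

Log-space accumulation everywhere rates are summed; ties in classification
are declared (predicted = None) when the top two log scores agree within
1e−9 rather than broken silently; SGM favourable-attachment ties break by
row-major location order; constant images standardize by scan order;
single-tile layouts return the monomer path; empty masks, ragged grids,
discontinuous protocols, non-positive concentrations and
self-complementary glue unifications raise immediately with specific
messages.  Problem sizes in the shipped tests and acceptance script —
10×10 fixtures, 25–200 SGM paths per start, 150–500 hill-climbing steps,
ten seeds for the capacity sweep, 0.02–0.05 h anneal steps — were chosen
so the full suite exercises every claim at statistically stable scale on a
single core.

## Known limitations

Rates are relative, never absolute; there is no reversible kinetic tile
assembly simulation (an xgrow-format export is provided best-effort, with
glue star-structure flattened to xgrow's self-complementary bonds);
second-order proofreading checks single-glue errors and immediate
neighbours only; the merge search is greedy-stochastic with restarts, so
merged tile counts vary by seed and no optimality is claimed; the published
θ and the published 917-tile merged system are not reproduced tile-for-tile
(the merge algorithm is stochastic and the published system was itself
selected across repeated runs).
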