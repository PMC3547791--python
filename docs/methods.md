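# Methods

This note documents the models and numerical conventions behind
`repeatpull`: what the synthetic pulling generator simulates, what each
analysis stage assumes, the tunable parameters with their units and
defaults, and the limits of what desk-scale synthetic cohorts can show
about real all-atom pulling data.

## Units and constants

Length in Å, time in ps, force in pN, work in pN·Å internally. Work is
reported in units of kBT at the 300 K simulation temperature;
kBT(300 K) = 41.419 pN·Å (1 pN·Å = 1e-22 J). Residues are numbered from
1 at the first resolved residue; frames are 0-indexed.

## The synthetic pulling model

The generator (`synthetic_pulling`) is a reduced, seeded stand-in for
atomistic steered MD of a stacked repeat array. It is *not* fitted to
any trajectory data; it exists to give the analysis stack inputs with
exact ground truth.

**Mechanics.** A harmonic spring of stiffness k (default 20 pN/Å) has
its rest position moved at constant velocity v (0.01 or 0.05 Å/ps). At
every integration step the chain extension x solves the static force
balance k(X − rod − x) = F_WLC(x; Lc, p), where F_WLC is the
Marko–Siggia interpolation

    F = (kBT/p) · [ 1/(4(1−x/Lc)²) − 1/4 + x/Lc ],

Lc is the currently unfolded contour and `rod` the summed rigid rise of
folded repeats. The balance is solved by bisection on [0, 0.999·Lc] to
1e-8 Å. Solving a static balance means the chain is treated as
mechanically equilibrated at every step — dissipation enters only
through the force-dependent rupture kinetics, not through chain
friction.

**Folded rise defaults to 0** (folded repeats are point-like nodes on
the pulling axis). A real folded repeat spans ~10 Å, but a nonzero rise
biases every fitted contour-length increment by −rise (the fit's
divergence point tracks rod + Lc), decoupling the analysis' measured
period from the generator's ground-truth L. Treating folded domains as
points is the standard idealisation in Monte-Carlo sawtooth generators
and keeps increment ground truth exact; set `folded_rise` if the bias is
wanted.

**Kinetics.** Each repeat consists of two half-repeat Bell elements;
each rupture releases L = 56.8 Å of contour (the unfolded length of
half an ankyrin repeat; 2L = 113.6 Å per whole repeat). A competent
element ruptures with rate

    λ = k0 · exp(F·Δx‡/kBT − ΔΔG_r·[bound]) · (η if N-edge else 1).

Rates are accumulated on a fixed dt = 0.1 ps step (per-step hazard λ·dt,
an event fires when the accumulated hazard crosses an Exp(1) draw —
the discrete-hazard form of per-step Bernoulli trials, vectorised over
constant-contour segments). Defaults k0 = 1e-5 /ps and Δx‡ = 1.0 Å are
synthetic: they were placed by the standard loading-rate estimate
F* ≈ (kBT/Δx‡)·ln(loading·Δx‡ / k0·kBT) so rupture forces land in the
100–400 pN window at the two supported speeds. They are not derived
from, or fitted to, any molecular system.

**Order model.** Only the two edge repeats of the folded core are
unfolding-competent (interior repeats are protected by both
neighbours); the N-terminal edge is damped by η (`n_edge_bias`, default
0.05). This yields dominantly C→N sequential unfolding with occasional
N-terminal events — the degenerate near-sequential behaviour expected
of near-identical stacked repeats. When the first half of a repeat
ruptures, the second follows instantly with probability `q_whole`
(default 0.3); q → 1 makes whole repeats unravel in single 2L steps,
q → 0 gives independent L steps. Pulling is monotonic: there is no
refolding and no constant-force mode.

**Ligand stabilisation.** With `ligand=True`, repeats 1..R−1 gain an
unfolding-barrier increase ΔΔG (default 4 kBT) with a graded profile
ΔΔG·(1.5, 1.25, 1, …, 1, 0.75, 0): strongest on repeat 1, weakest on
the last ligand-contacting repeat, zero on the C-terminal repeat, which
the ligand does not touch. The gradient reflects the observed per-repeat
asymmetry of binding effects (repeat 1 shows the largest change, the
penultimate repeat none) and is what makes the bound unfolding order
robustly restricted: with a uniform profile the first-two-ruptures
probability is capped at 1/(1+η) regardless of ΔΔG because the two edge
competitors are suppressed equally. A uniform or arbitrary profile can
be supplied via `ddg_per_repeat`.

**Reported trace.** Frames are saved every 4 ps at 0.01 Å/ps and every
1 ps at 0.05 Å/ps. Gaussian noise (σ = 8 pN) is added to the *reported*
force only; the dynamics are noise-free, so the force distribution has
a Gaussian body and the ruptures supply its high-force tail. σ was
chosen jointly with the detector defaults: the 30 pN peak prominence
must sit far (~8 sd) above the smoothed noise floor, otherwise noise
alone opens hysteresis cycles on multi-10k-frame traces and the
prominence rule cannot do its job. Per-repeat anchor positions are laid
along the pulling axis proportionally to each repeat's released contour
(the initial 30 Å linker is split between the terminal repeats), so the
per-repeat end-to-end vectors telescope exactly. Freed contour is
ramped into the anchors over `anchor_relax_ps` (200 ps) rather than one
frame: an instantaneous jump would concentrate ~45 Å of anchor motion
at the rupture frame and couple reported-force noise into per-repeat
work with ~300 pN·Å errors; the ramp also mirrors how the freed chain
straightens during the subsequent loading phase.

**Coordinate synthesis.** `make_native_template` builds a deterministic
toy array: each repeat is two antiparallel strands of Cα/Cβ sites
(12 residues by default, 2.5 Å spacing, 5 Å strand separation, 15 Å
stacking rise), so native contacts exist within repeats and between
adjacent repeats only; one ligand bead per bound repeat sits 4 Å from
the middle of the repeat's first strand. `synthesize_trajectory`
interpolates each repeat from its native block to a straight segment
(9.47 Å/residue, offset 12 Å in y from the native lane so the extended
chain does not thread through still-folded blocks) across a window
(default 1600 ps) centred on the repeat's ground-truth midpoint, plus
0.3 Å Gaussian jitter. Ligand beads ride their anchor residue until the
repeat's window opens, then retreat at 0.1 Å/ps; releasing at the
window onset (not the midpoint) prevents an attached bead from sweeping
across already-extended repeats and fabricating cross-repeat contacts.
Coordinates are quantised to 1e-3 Å (PDB precision) so written
trajectories round-trip.

## Analysis conventions

**Work (Eq. above).** The trapezoid sum over frames is exact for
constant force; the per-repeat components use the same averaged force
dotted into per-repeat anchor displacements and sum to the total by
construction (asserted to 1e-6 relative). Quasi-statically the total
equals the Marko–Siggia stretching integral
(kBT·Lc/p)[1/(4(1−s)) − s/4 + s²/2 − 1/4]; the spring's own energy is
not part of the transferred work because the increment uses the
end-to-end displacement, not the spring-end displacement. For traces
storing only force magnitudes, the force is taken along the
instantaneous end-to-end unit vector (`force_mode="magnitude"`). Group
comparisons use Welch's two-sided t-test at the 1% level; two
zero-variance groups compare as p = 1 (equal means) or p = 0 (unequal).

**Force threshold.** Histogram bin width 5 pN; the Gaussian body is
fitted to bins within ±2 sd of the mode, re-selecting the window twice.
Normalized deviation per bin is (count − fit)/√max(count, 1); the
threshold is the deviation maximum among bins above mean + 1 sd, ties
toward lower force, flagged unreliable below deviation 3 (compatible
with sampling noise — a pure Gaussian sample rarely exceeds it). The
deviation maximum is taken per-bin, not on a smoothed deviation curve.

**Peaks.** The force magnitude is smoothed with a 5-frame
edge-replicating moving average; peaks are hysteresis maxima: the
series must rise ≥ 30 pN from the preceding trough to open a peak and
drop ≥ 30 pN below the running maximum to close it. Trace boundaries
are never peaks (a still-rising final segment is not a rupture). Peaks
below the threshold are discarded; an empty result is valid.

**WLC fits.** Fixed p = 3.8 Å; Lc is bracketed in (1.001, 5)×max
extension and found by bounded scalar minimisation of the squared force
residual (force-versus-extension, not versus time). The fit window runs
from the force minimum after the previous peak to the current peak
frame, filtered to strictly increasing extension, minimum 5 points.
ΔLc pools all ordered within-run pairs (never cross-run); periodicity
scores each candidate period by the fraction of ΔLc within ±10 Å of its
positive multiples, resolving score-plateau ties by minimal mean comb
residual and then toward the larger period (so a pure-2L comb, whose
members are also multiples of L, reports 2L).

**Unfolding order.** Per-repeat RMSD uses optimal superposition (SVD
with determinant correction) of the repeat's Cα/Cβ atoms; the midpoint
is the first linearly-interpolated crossing of 10 Å (ranking is stable
over thresholds 7–15 Å because the synthesized RMSD rises to 20–30 Å
within one window). Non-unfolded repeats are excluded from ranks and
reported separately. The exact Fisher test enumerates all tables with
the observed margins (DFS with feasibility pruning) and sums
multivariate-hypergeometric probabilities ≤ the observed one; above
~5e5 estimated tables or total > 200 it switches to a seeded
permutation Monte-Carlo with the (1 + hits)/(B + 1) estimate. All-zero
rows and columns are dropped first (they do not change the conditional
test). The KDE replaces each point by a fixed-width Gaussian and
renormalises on a grid spanning the data ±4 bandwidths, so the grid
integral is exactly 1 (conventional bandwidths: 20 Å × 20 pN for the
extension–force peak density, 50 kBT for work, 1.6 ns for unfolding
times).

**Contacts and binding.** Cutoffs are strict inequalities (< 8 Å Cα–Cα
with sequence separation > 3; < 5 Å any-atom for ligand binding) and
the native-binder rule is strictly > 80% of equilibration frames. The
recurrence window is 0.4 ns, span-inclusive: a run of frames whose
times span exactly 0.4 ns qualifies; alternating-frame presence never
does. The same filter is applied to binding lifetimes by default
(`recurrence_filter=False` restores the raw last-observation rule —
the two readings of "last time observed" are both available because
the binding definition is stated without the consistency clause).
Turn/helix contact classes come from the repeat-map region annotations;
the toy template labels the first two residues of each repeat "turn",
which produces intra/inter-helix classes but no turn–turn contacts at
its geometry.

## Problem sizes

The test-suite and acceptance runs use: 50 fast pulls for the work
identity; one quasi-static trace; 100 seeded WLC fits over
Lc ∈ [60, 800] Å; 20 pulls per periodicity mode; 200 pulls (plus 1000
pure-noise traces) for detection quality; 50 synthesized trajectories
for order recovery; a 500-table exact-versus-rational-enumeration
Fisher suite plus a 1000-draw calibration at 2×3/n = 120; 20 bound
trajectories for binding/unfolding rank agreement; and 12 + 12 pulls at
0.01 Å/ps for the cohort contrasts — the same run design as the study
the analyses target. Fast-speed (0.05 Å/ps) pulls are used wherever a
property is speed-independent because they are ~5× cheaper.

## What the synthetic cohorts do and do not show

Passing tests demonstrate that the *analysis stack* is correct: the
work decomposition is exact, fits recover known contour lengths,
detection recovers known ruptures, order statistics recover known
orders, lifetimes recover scripted schedules, and the exact test is
exact. They do not validate any claim about real proteins: the
generator has no atomistic forces, no solvent, no refolding, reported
rupture kinetics are two-state Bell elements with hand-placed rates,
and its unfolding-order model is a two-edge competition. In particular
the generator does not reproduce the experimental bound-versus-free
shift in the *order position of repeat 1* (with edge-limited kinetics
the N-edge/C-edge rate ratio is what it is regardless of a uniform
stabilisation), so the Fisher machinery is exercised on cohort data but
a significant bound-versus-free order difference per repeat is not a
generator guarantee. Real force data also carry correlated,
heteroscedastic noise and drift that the white reported-force noise
does not emulate; threshold selection on real data should be checked
against the unreliability flag.
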