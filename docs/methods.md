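# Methods

This note documents the models, conventions and numerical choices
behind `chelkin`, and what the synthetic-data tests do and do not show.

## Equilibrium model

Coordination species MLᵢ (i = 0…N ligands bound) are populated by
Boltzmann weights of their free-energy levels ΔGᵢ (kJ/mol, relative to
the free metal, k_B = 0.0083145 kJ mol⁻¹ K⁻¹, default T = 300 K):
nᵢ ∝ exp(−ΔGᵢ/k_BT), normalised to the total metal concentration. The
levels are interpreted as *box-equilibrium* free energies at the given
composition — the convention of surfaces reweighted from
enhanced-sampling runs of that very solution — so the solver performs
no self-consistent iteration over [L]; ligand conservation
[L] = [L₀] − Σ sᵢ[MLᵢ] only back-computes the free-ligand
concentration, and a non-positive result is an error (levels
inconsistent with the composition). The alternative convention
(standard-state constants plus mass-action iteration) is a different
model; the two can differ by up to ~kT·ln([L₀]) per step. Both level
conventions appear in published tables for these systems (e.g. an
at-concentration −17.2 kJ/mol vs a bookkeeping −29.3 kJ/mol for the
mono-coordinated Cd–en species); the presets keep the two data sets
separate and never mix them.

Surface → level projection offers Boltzmann integration over the basin
(default) and a basin-minimum mode; which one a given published figure
used is generally not stated, so both are first-class. Basins default
to "all visited cells whose rounded (ligand, water) coordinates match
the species". Offset invariance (adding a constant to the surface or
the levels changes no pK) is property-tested to 1e-10.

Monte Carlo pK errors redraw every level from N(ΔGᵢ, σᵢ) (σ = 2 kJ/mol
in the presets, the typical convergence error of such surfaces),
re-solve, and report mean/SD over ~2000 draws. Draws violating the
ligand balance are *rejected and counted*, not clipped; a rejection
fraction above 50% raises, since the result would no longer describe
the nominal composition.

Minimum free-energy paths are minimax (lowest-barrier) paths over
4-connected grid moves, computed exactly by Dijkstra with
max-composition; the returned barrier is the path's highest cell. This
is a principled stand-in for external pathway tools operating on the
same surfaces.

## Markov state model

Microstates are k-means++ clusters in the (ligand, water) coordination
plane (Lloyd to 1e-6 or 500 sweeps; above 200k frames the fit uses a
random subsample and all frames are assigned afterwards). Count
matrices use a sliding window at the chosen lag and are restricted to
the largest strongly connected component. Estimation is
maximum-likelihood row normalisation, or, with `reversible=True`
(default), the standard detailed-balance-constrained self-consistent
iteration. Note that the reversible estimator assumes equilibrium
sampling; with non-equilibrium coverage restarts (every replica started
from a grid over the species ladder) it can bias slow rates, while the
plain MLE stays unbiased under any start distribution by the Markov
property — both are exposed, and the recovery benchmarks pass with
either because their fixtures keep occupancies balanced.

Validation: implied timescales tᵢ(τ) = −τ/ln λᵢ(τ) with a plateau
detector (default 10% relative), and a Chapman–Kolmogorov test
comparing T(τ)ⁿ against a re-estimated T(nτ) through per-set survival
probabilities (default threshold 0.1).

PCCA+ uses the inner-simplex construction on the dominant
π-orthonormalised eigenvectors; memberships are clipped to [0,1] and
row-normalised, crisp assignment is by largest membership with ties
broken toward the lower-ligand-coordination macrostate, and macrostates
are ordered by mean ligand coordination so index a maps onto ML_a. The
coarse matrix is re-estimated from the macrostate-mapped trajectories
at the same lag.

MFPTs solve the first-passage linear system (I − T_QQ)m = τ·1; the
suite checks them against an explicit fundamental-matrix inverse to
1e-10 on random chains.

### Rate conversion

With γ = N_Av·V (particles per unit molar concentration) and
n_lig^eq = [L]·γ, per-box hopping rates convert to molar constants as
forward k_i = ν·γ/n_lig^eq = ν/[L] (L mol⁻¹ s⁻¹) and backward
k₋ᵢ = ν (s⁻¹). This is the unique dimensionally consistent scaling
that (a) makes k_i/k₋ᵢ = K_i and (b) recovers the input rates of a
CTMC ground truth; it also reproduces the magnitude of published
diffusion-limited k₁ values for these systems (~10¹⁰ M⁻¹s⁻¹ for
Cd–en).

For a single binding step, ν = 1/MFPT is exact. For longer ladders the
per-step inverse MFPT folds in dwell times of states behind the source
(birth–death identity: 1/MFPT(i−1→i) = a⁺ᵢ·πᵢ₋₁/Σ_{j≤i−1}πⱼ), so it
measures an *effective* rather than elementary rate; `rates_from_msm`
therefore also provides `method="generator"` — the matrix logarithm of
the coarse transition matrix, projected back onto a valid rate matrix —
which recovers elementary per-step rates. The same choice backs
`extract_bidentate_rates`. Multi-step consistency checks use the
generator route; one-step checks use the stated MFPT rule (the two
coincide there).

Bayesian errors sample each transition-matrix row from
Dirichlet(counts), push every sample through the rate computation and
report percentile intervals; coverage is verified empirically (true
rate inside the 95% interval in ≥90% of repeated synthetic
experiments).

## Chelate kinetics

The two-step scheme M + L–L ⇌ (open ring) ⇌ (closed ring) gives
K^or = k₊^or/k₋^or, K^cr = k₊^cr/k₋^cr, K₁ = K^or·K^cr and the
steady-state overall rates k_f = k₊^or k₊^cr/(k₋^or + k₊^cr),
k_d = k₋^or k₋^cr/(k₋^or + k₊^cr); K₁ = k_f/k_d is an identity and is
property-tested over ten orders of magnitude. "Rate-determining"
labels operationalise the qualitative regimes: formation is
"first-binding-limited" when k₊^cr/k₋^or > 10, dissociation
"ring-opening-limited" when k_d is within 10% of k₋^cr; everything
else is "mixed".

## Mechanism classification

Sharp cutoffs define the first shell (metal–N 3.4 Å; metal–O 3.2 Å for
Cd, 2.9 Å for Ni) and a donor entry only counts as a binding event
after ≥ 20 ps of residence; sub-residence unbound gaps are bridged and
sub-residence bound dips discarded, so brief re-crossings neither
split nor create events. Within a ±20 ps window anchored at the entry
frame: the baseline is the *mode* of the summed (water + ligand)
coordination over the pre-window; the leaving water is the first-shell
water with the latest exit inside the window that has actually left by
the window's end; "dissociative" requires exit before entry with the
total never above baseline, "associative" requires exit after entry
with at least one frame above baseline, anything else is "ambiguous"
(kept, never forced binary). The published procedure describes these
signatures verbally; the mode baseline, the latest-exit rule, and
anchoring both the classification and the ±5 ps geometry window at the
entry frame are this package's choices.

Exit geometry places the metal at the origin and the entering nitrogen
along +X; the leaving water is reduced to (parallel, perpendicular)
components, so the in-plane radius equals the metal–oxygen distance
exactly and the angle is the N–metal–O angle. The transform is rigid:
rotating all coordinates changes nothing (tested to 1e-9).

## Synthetic data

The CTMC generator emulates the replica protocol of unbiased
simulation campaigns — 200 replicas × 2 ns, coordination recorded
every 0.1 ps, starts cycled over the species ladder — via exact
Gillespie simulation of the binding network with a single metal per
box and an explicitly tracked ligand count (propensities
a₊ᵢ = kᵢ·n_L/γ, a₋ᵢ = k₋ᵢ). Frames carry Gaussian jitter (σ = 0.15)
around the integer coordination pairs so that clustering is
non-trivial. Backward rates are filled "thermoconsistently" from the
levels (k₋ᵢ = kᵢ/Kᵢ at the box equilibrium) unless given.

Box size: the kinetics fixtures use γ = 200 (single metal at 0.005 M,
30 ligands) rather than the minimal one-ion cell, because with only ~3
ligands in the box discrete-count fluctuations shift per-step
equilibrium ratios by up to ~0.6 log units — a finite-size effect, not
an estimator property; 30 ligands reduce it to ~0.02. The remaining
systematic in forward-rate recovery is the state-dependent ligand pool
(n_L = 30 − sᵢ vs the mean-field n_lig^eq), a few percent here.

Benchmark design: a rate is only recoverable if its transitions are
actually observed, so each benchmark keeps occupancies balanced and
per-box rates within ~1–10 ns⁻¹, giving O(100) events per edge under
the 200 × 2 ns protocol; the >4-order span of molar rate constants is
realised across scenarios by rescaling the time unit (identical
statistics at different magnitudes). Consequently the recovery results
demonstrate estimator correctness under adequate sampling; they do not
show that rates of rarely-visited states (the "elusive" odd
intermediates of real bidentate systems) can be extracted from
undersampled data — with missing transitions the code flags the step
("no events observed") rather than extrapolating.

The surface generator drops paraboloid basins (15 kJ/mol rise at one
basin width, default width 0.35) at the integer coordination pairs on
a 0.1-spaced grid, takes the lower envelope, and adds optional cell
noise; basin overlap is an error. Inter-basin barrier heights are set
by this curvature, not calibrated to any real system. The
binding-trace generator plants events with fixed approach/exit slopes
(0.5–0.6 Å/ps), water departure 3 ps before (dissociative) or 4 ps
after (associative) nitrogen entry, sub-residence dips as negatives,
and, in Cartesian mode, a configurable exit direction (default 90°,
per-event jitter 10°). Real trajectories have rougher distance traces,
correlated noise and ambiguous boundary events; passing these tests
shows the rules implement their definitions and tolerate 0.2 Å
Gaussian noise, not that classification of real data is error-free.

## Known limitations

* No activity-coefficient corrections; concentrations are treated as
  activities (constant ionic background assumed).
* The box-equilibrium level convention ties pK values to the simulated
  composition; comparing against standard-state constants requires the
  appropriate level set.
* PCCA+ uses the simple inner-simplex construction without the
  follow-up membership optimisation; adequate for well-separated
  metastable ladders, not for heavily overlapping spectra.
* Reversible estimation biases slow rates under non-equilibrium
  restarts (see above); use the plain MLE or longer replicas if
  occupancies are far from stationary.
* The mechanism classifier is binary-plus-ambiguous; interchange-type
  mechanisms are out of scope.
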