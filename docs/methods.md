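# Methods

This note documents the models implemented in `mcdpmrf`, the defaults and
why they were chosen, the numerical decisions that matter, and what the
synthetic experiments do and do not demonstrate.

## Diffusion-preparation gradient design

**Model.** The preparation is a fixed 50 ms block: instantaneous 90°
tip-down, two 10.3 ms adiabatic refocusing pulses centered at T/4 and 3T/4,
instantaneous 90° tip-up.  Gradients may play only between RF pulses; a
1 ms eddy-current gap separates every gradient lobe from each neighbouring
RF pulse of finite duration.  With the default instantaneous tip pulses
this leaves three free segments totalling 25.4 ms; modelling tip pulses
with nonzero duration (the `tip_duration` knob) re-introduces forbidden
windows and gaps at both ends and shortens the gradient time accordingly.
This tip-pulse treatment is the single most influential timing assumption:
with 1 ms gaps also budgeted at zero-length tips the slew-limited
achievable b-value for an M0+M1-nulled design drops structurally from
~845 to ~580 s/mm², because the first/last segments bound the phase
plateau reachable before the refocusing pulses.

**Effective gradient and constraints.** All moment and b-value bookkeeping
uses the effective gradient (polarity toggles after each refocusing
pulse).  Concomitant (Maxwell) phase instead grows with g², unaffected by
gradient polarity but refocused by the 180° pulses; for one shape played on
all three axes the lowest-order residual reduces to the signed ∫g² with
per-segment signs, and the optimizer drives it to zero when Maxwell
compensation is enabled.  Moments are nulled at t = T only.  Null
tolerances are relative: |Mₙ| ≤ 1e-6 · max|g| · Tⁿ⁺¹.

**Three-axis convention.** The waveform stores one shared shape and a unit
encoding direction; the per-axis amplitude is `shape · √3 · dᵃ`, so the
default direction (1,1,1)/√3 plays the full shape on each axis and the
total b-value is three times the single-axis value.  Amplitude and slew
limits are checked on the worst axis.

**Optimization.** Node amplitudes live on a 25.6 µs grid (four dwell
times) inside the free segments, pinned to zero at segment edges, and are
linearly interpolated to the 6.4 µs dwell raster; quadrature matrices are
assembled on the fine raster so the node problem and the played waveform
agree to quadrature refinement.  Maximizing the convex quadratic b(g) is
nonconvex; the solver is deterministic successive linear programming: each
iterate maximizes the linearized objective over the exact box/slew/moment
polytope plus the linearized Maxwell equality inside an l∞ trust region,
with an l1 exact-penalty merit rule, followed by a null-space Newton
polish that drives the Maxwell residual to ~1e-13.  Because the landscape
has distinct basins, four fixed starts are tried (all nodes at +G_max, two
mirrored patterns whose played polarity flips mid-segment — these seed the
high-b single-excursion family — and a segment-alternating pattern) and
the best feasible incumbent wins.  The defaults reproduce: b ≈ 845 s/mm²
for M0+M1+Maxwell, ≈ 1446 for M0-only, and ≈ 96 for M0+M1+M2+Maxwell
(second-moment nulling is infeasible above 500 s/mm² on this hardware, as
expected).  Scaling the optimized shape by √(b_target/b) yields the whole
b = 10–600 s/mm² preparation family with the nulls preserved exactly.

## EPG signal model and dictionary

States F±(k), Z(k) are tracked to k_max = 20 (doubling k_max changes a
fingerprint by < 1e-6; the 10–20° flips keep high-order pathways
negligible).  Per TR: RF rotation with quadratic 117° phase cycling, F0
sampled at TE with transmit-phase demodulation, relaxation, per-state
diffusion attenuation with the standard b-factors
(k² + kΔk + Δk²/3)·q²·dt for transverse and k²·q²·dt for longitudinal
states, and a unit spoiler shift.  The spoiler's physical dephasing is
q = 2π / 6 mm (one cycle across the slice), which makes readout-spoiler
diffusion present but negligible, as it should be.

Preparations are instantaneous weightings of Z0 with a perfect crusher:
inversion (efficiency 1.0, then TI = 20 ms relaxation), T2-prep
(Z0·e^(−dur/T2)), diffusion-prep (Z0·e^(−dur/T2)·e^(−b·ADC)); a b = 0
diffusion prep is exactly a T2-prep.  The within-prep EPG evolution is not
simulated.  The flip-angle train is a linear 10°→20° ramp over the 30
shots, identical in every block; the block order interleaves the
preparation multiset {IR×1, T2p33×2, T2p50×1, Dp10×2, Dp200×2, Dp400×2,
Dp600×4, none×2}; both are configuration knobs, since only the ranges and
multiplicities of the protocol are fixed.  Heartbeats are modelled as a
constant 1000 ms RR interval with a 200 ms trigger delay.

**Dictionary and compression.** Grids use MATLAB-style colon expansion;
the in-vivo grids give 28×25×28 = 19,600 tuples, 19,432 after removing
unphysical T2 > T1 entries.  Atoms are L2-normalized with norms stored.
The SVD basis rank is the smallest r whose cumulative **singular values**
(nuclear-norm fraction, the energy-ratio convention of the MRF-SVD
compression literature) reach the requested 96%.  With the default ramp
train this gives rank 5; alternative trains in the 10–20° range
(descending, constant, stepped, random) give 5–6.  The squared-singular-
value (Frobenius) convention would give rank 2–3 for every such train.
Matching in the compressed domain uses the projected atoms renormalized to
unit subspace norm — without this renormalization the argmax is biased
toward atoms with more energy inside the subspace.  Ties break toward the
lowest atom index.

## Trajectory, DCF and reconstruction

One spoke per shot (480 per slice), tiny-golden-angle order 7 (increment
180/(φ+6) = 23.6281°), 2× oversampled readouts, |k| ≤ matrix/2.  Voronoi
cell areas provide the density compensation, with duplicate center samples
sharing their cell equally and open outer cells clipped at the sampling
circle plus half a radial step; bounded interior cells use the shoelace
formula and only boundary cells go through polygon clipping.

The forward model is an exact separable non-uniform DFT (no gridding
approximation): per spoke, the contrast image is the basis-weighted
combination of the r coefficient images, multiplied by each coil map and
sampled along the spoke.  The adjoint passes a dot-product test at 1e-10.

The inversion solves min ‖Ax − y‖²_W + λR(x) with W the DCF (used purely
to precondition the normal equations — W is additionally normalized so the
preconditioned normal operator has unit spectral norm, estimated by six
deterministic power iterations) and R a locally-low-rank joint-patch
penalty: 5×5 patches, the 25 most similar patches inside a 25-pixel search
window, joint SVD across the r coefficient images, singular-value soft
threshold.  This patch regularizer is a deliberate, documented stand-in
for tensor patch-based high-dimensional denoisers.  λ = 3e-3 with a
threshold scale of 83.3 maps the penalty to ~0.25 of the peak coefficient
magnitude.  The solver runs 3 outer × 4 inner (CG) iterations from the
density-compensated adjoint as warm start.  At these small iteration
counts the dual-coupled ADMM alternation reinjects streak residuals
through the scaled dual variable and measurably degrades the estimate, so
the default (`rho = 0`) runs the decoupled limit — all data-consistency CG
iterations, then the patch prox once; any `rho > 0` enables the standard
scaled-dual alternation.  With λ = 0 and one outer iteration the solver
reduces exactly to preconditioned CG least squares and is linear in the
data.

**What limits voxelwise exactness.** Radial sampling covers only the
inscribed k-space disc: the square grid's corner frequencies are never
measured, so voxels on tissue boundaries cannot be recovered exactly by
any solver, and the out-of-subspace temporal residual of the true signal
(a few percent at rank 5–7) biases region values slightly under heavy
angular undersampling.  Multicoil acquisition partially completes the
missing encoding: the end-to-end validation therefore uses four synthetic
coils (the modelled protocol used a 16-channel array) and a deliberately
coarse matching grid (`demo_grids`) whose spacing is wide relative to the
reconstruction error; under those conditions ≥ 95–96% of in-mask voxels of
a three-sector 64×64 phantom recover their exact (T1, T2, ADC) tuple.
With the fine in-vivo grids (40 ms T1 / 3 ms T2 steps near liver values)
the same pipeline recovers ~78–80% exactly and the rest within one to two
grid steps — a documented property of subspace radial reconstruction, not
of the matching.

## Synthetic data

Phantoms are piecewise-constant label images: nine-tube relaxation and
diffusion ladders (`tubes_t1mes`, `tubes_pvp` — the PVP ladder shares
T1 = 700 ms / T2 = 40 ms and spans ADC 0.3–2.0×10⁻³ mm²/s; per-tube ADC is
configurable since no per-concentration table is assumed), a liver-like
ellipse with vessels, and the three-sector validation layout.  Coil maps
are smooth complex Gaussian profiles, deterministic per seed, with a
bounded sum-of-squares floor.  Acquisition simulation evaluates one
fingerprint per tissue (exact for piecewise-constant phantoms) and samples
every spoke with the same exact NUDFT the reconstruction uses; complex
white noise is added per sample relative to peak k-space magnitude.

Flow corruption is a first-order model: voxels with nonzero velocity
acquire the phase φ = γ(M0·x + M1·v) of the actual preparation waveform in
every diffusion-prepared block.  This is the minimal model that makes M1
nulling testable — an M0+M1-nulled preparation leaves the data bit-
identical to the static case, while an M0-only preparation of equal
b-value visibly attenuates vessel signal after reconstruction.  It does
not model intra-voxel dephasing, bulk or respiratory motion, or
eddy-current tagging.

What passing tests show: internal consistency of the whole chain
(simulation, reconstruction and matching agree on known ground truth) and
correctness of each operator against independent oracles (closed forms,
brute-force per-sample accumulations, a 500-spin Bloch simulation,
analytic ramp filters).  What they do not show: robustness to real-scanner
effects — B0/B1 inhomogeneity, slice profile, magnetization transfer, fat,
actual eddy currents and subject motion are all outside the model.

## Evaluation statistics

ROI means use circular membership by center distance.  Method comparison:
OLS fit with r² and an F-test of slope = 1 (the squared t statistic on
n−2 dof), α = 0.05.  Bland–Altman: bias, limits bias ± 1.96·SD, and a
slope-0 trend test of differences against pairwise means.  Repeatability:
CV = mean over subjects of (SD across repeats / mean) × 100, and
ICC(A,k) = (MSR − MSE) / (MSR + (MSC − MSE)/n) from the two-way ANOVA mean
squares (two-way mixed effects, absolute agreement, multiple
measurements); degenerate all-equal tables report ICC = 1 by convention.
The ICC implementation is cross-checked against an independent statistical
package in the tests.  The in-vivo agreement numbers of liver studies are
not reproducible from synthetic phantoms and are not targeted; the module
reproduces the procedures.

## Problem sizes used in the tests

The suite exercises full-size waveform optimizations (≈ 900 nodes) and the
full in-vivo dictionary (19,432 atoms × 480 points), but keeps image-domain
experiments at 32–64 matrices with 96–512 spokes and 1–4 coils, and the
"fully sampled" operator check at 512 spokes on a 32 matrix — sizes chosen
so the entire suite runs on a single CPU in minutes while leaving every
algorithmic path identical to larger runs.
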