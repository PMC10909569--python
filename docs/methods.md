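# Methods

## Signal model

A voxel is modelled as a capillary blood water compartment (volume fraction
v_bw, relaxation rate R1_b = 1/T1_b) exchanging with an extravascular tissue
water compartment (v_ew, R1_e = 1/T1_e). After continuous labelling of
duration t_L, labelled blood water arrives at the voxel at the arterial
transit time t_A with flow f, and crosses into tissue at the exchange rate
k_b = PS/v_bw. Three standard assumptions close the model: the label decays
before reaching the veins (no outflow), back-exchange of labelled water from
tissue to blood is negligible while the intravascular label dominates, and
the arterial bolus is an undispersed rectangle whose amplitude has decayed by
e^{−R1_b t_A} during transit. Under these assumptions the volume-weighted
difference magnetization ΔM = v_bw Δm_b + v_ew Δm_e has a closed form.

We write it as a divided difference. With J = k_b + R1_b, t′ = t − t_A and

    W(r) = (1 − e^{−r t′}) / r                      t_A ≤ t ≤ t_A + t_L
    W(r) = (e^{−r (t′−t_L)} − e^{−r t′}) / r        t > t_A + t_L

the signal is

    ΔM(t) = A [ W(J) + k_b · (W(R1_e) − W(J)) / (J − R1_e) ],
    A = 2 (f/6000) (M0/λ) α e^{−R1_b t_A},

zero for t < t_A. The first term is the intravascular label, the second the
label accumulated in tissue. This form makes the removable singularity at
J = R1_e explicit: when |J − R1_e| < 10⁻⁶ s⁻¹ the divided difference is
evaluated by its Taylor series −W′(R1_e) − ½(J−R1_e)W″(R1_e) − …, so the
model is smooth there to ~10⁻¹³ relative (a plain switch at machine-level
thresholds would lose ~7 digits to cancellation). The analytic sensitivity
∂ΔM/∂k_b follows by differentiating through J and k_b; at T1_e = T1_b it is
identically zero (the compartments are indistinguishable), which the
algebra reproduces exactly.

Correctness of the closed form is pinned by an independent oracle: direct
numerical integration (DOP853, rtol 10⁻¹⁰, integrated piecewise across the
bolus discontinuities) of the two compartment equations with a rectangular
inflow. Closed form and oracle agree to better than 10⁻⁶ relative over a
200-point Latin-hypercube sample of the physiological ranges; the analytic
derivative is gated against central finite differences (step 10⁻⁵ s⁻¹,
tolerance 10⁻⁴ relative).

### Units

f is held in mL blood/min/100 mL tissue at every API boundary and divided
by 6000 inside the equations (per-second units); all times are seconds,
M0 is arbitrary and everything downstream is linear in it.

## Protocol optimization

Sensitivity sweeps evaluate ∂ΔM/∂k_b at the single measurement instant
t = t_L + PLD (the acquisition is treated as instantaneous). The surface
over blood T1 ∈ [0.15, 1.65] s × PLD ∈ [0.5, 3.0] s uses 151 points per
axis (0.01 s steps in T1_b): the optima are quoted to 0.1 s, so this
over-resolves them safely. Normalization divides by the maximum *signed*
value of the anchor grid — the optimum maps to +1, and the no-contrast
blood T1 appears at ≈ −0.3, negative because without contrast the tissue
compartment relaxes *faster* than blood and exchange destroys signal.
All three sweeps (T1_b × PLD grid, T1_e leakage sweep, underlying-k_b
sweep) share one anchor: k_b = 2.65 s⁻¹, T1_b = 0.8 s, T1_e = 1.5 s,
PLD = 1.5 s.

## Fitting

The estimation problem is nonlinear least squares in (f, t_A, k_b) with all
T1 values fixed, jointly over all contrast phases (unweighted SSE; no
weighting is physically motivated since every sample carries the same noise).
Because ΔM is exactly linear in f, each local search runs over (t_A, k_b)
only and recovers f by linear projection clipped to its bounds (variable
projection): this halves the search dimension without moving any minimum.

Two configurations exist. `bounded_multistart` (default) draws n_starts =
100 start points uniformly between the bounds (f ∈ [0,200], t_A ∈ [0,2.5] s,
k_b ∈ [0,5] or [0,10] s⁻¹) from a seeded generator and keeps the lowest-SSE
solution; start points are drawn once per batch and shared across data sets.
`simplex` is the in-vivo configuration: a single unconstrained Nelder–Mead
search from (f, t_A, k_b) = (60, 1.0, 1.0). Out-of-bounds trial points in
the bounded mode are evaluated at their clipped position plus a quadratic
penalty, which permits genuine boundary minima (fits piling at k_b bounds
are a real feature of low-SNR data, not an artefact).

The optimizer itself is a batched Nelder–Mead advancing many independent
2-simplexes in lockstep on arrays (masked accept/expand/contract/shrink
steps; fixed maximum of 150–300 iterations with early exit when every
simplex has collapsed below 10⁻⁹ in parameters or 10⁻¹⁴ in normalized SSE).
The profiled objective has a compiled (numba) and a pure-numpy
implementation, cross-checked to 10⁻¹⁴ in the tests. Noise-free recovery
across 200 random ground truths is better than 0.5% in all three
parameters, so optimizer error is negligible against every tolerance used
in the studies.

## T1 error propagation

Noise-free signals are generated at the ground truth (k_b = 2.65, f = 60,
t_A = 1.2, T1_b pre/post = 1.65/0.8 s, T1_e = 1.5 s; five pre-contrast PLDs
0.9–2.1 s plus one post-contrast PLD 1.5 s) and refitted with one T1
perturbed *in the model only*, over a ±15% grid in 61 steps (0.5%), chosen
so that linear interpolation resolves the quoted thresholds to ~0.1%.
Curves are asymmetric in the perturbation sign; the reported accuracy
requirement is the tighter of the two |ε| = band crossings (both signed
crossings are returned). The headline result reproduces: blood T1 must be
known to ±1.5% (pre) / ±0.7% (post) to keep k_b within 10%, while tissue
T1 tolerates ±11%.

## Monte Carlo precision

Control and label samples are synthesized as 0.05·M0 ± ΔM/2 plus
independent zero-mean Gaussian noise of SD σ (95% background suppression;
the symmetric ΔM/2 split is bookkeeping — only the difference is ever
analysed). Pairwise subtraction gives difference signals with noise SD
σ√2. σ ∈ {0.0033, 0.0017, 0.0011} corresponds to control-image SNR
{15, 30, 45}. ROI averaging over N voxels is modelled by dividing the
noise SD by √N, which is exactly equivalent to simulating N i.i.d. voxels
and averaging, at a tiny fraction of the cost. 2500 replicates per
condition; accuracy is the relative error of the median estimate and
precision the CoV = 100·IQR/truth (linear-interpolation percentiles).

Two fitting configurations mirror the two study designs: the k_b-grid study
(25 values in [0.5, 4.0] s⁻¹) fits with k_b ∈ [0, 10] and discards fits
within 5% of those bounds before summarizing; the ROI-size feasibility
study (N = 1 / 500 / 10000 at k_b = 2.65) fits with k_b ∈ [0, 5] and
summarizes *all* fits. The latter choice is deliberate: at voxel level the
estimate distribution spans the whole fit range, and the reported ~190%
CoV equals the full bound width over the truth — any post-hoc screening
would clip it. Expected sampling error at 2500 replicates is ~±0.7
percentage points (1 SE) on the relative error of the median and a few
percent relative on CoVs, which sets the tolerances used in the acceptance
tests.

## GBCA dose planning

Blood concentration converts to blood T1 through R1_b,post(t) = R1_b,pre +
r1·c_b(t) with defaults r1 = 3.4 s⁻¹mM⁻¹ and R1_b,pre = 0.61 s⁻¹. VIFs may
be supplied as measured (t, c_b) tables or synthesized from the standard
population form (two Gaussian bolus passes plus an exponential washout
modulated by a sigmoid); fractional doses scale c_b linearly. The planner
reports the latest washout crossing of a target T1, located by monotone
cubic (PCHIP) interpolation and root bracketing; records ending before the
crossing are extended with an exponential tail fitted log-linearly to the
final quarter of the washout samples, matching the asymptotic form of the
population VIF. Published in-vivo timings depend on a measured VIF from a
different subject cohort and are *not* reproduced here; the planner is
validated against a closed-form mono-exponential washout oracle and the
qualitative dose-monotonicity pattern instead.

## Supporting T1 operations

Variable-flip-angle SPGR fitting uses S(θ) = M0 sinθ (1−E)/(1−E cosθ),
E = e^{−TR/T1}, per voxel by bounded nonlinear least squares initialized
from the linearized DESPOT1 regression (S/sinθ on S/tanθ), which also
serves as an independent cross-check. B1 inhomogeneity correction is not
applied. Blood T1 extraction follows the venous-sinus rule: seed-ROI voxels
with ≥ 20% post-contrast T1 reduction form the blood mask; T1_b,pre is the
75th percentile of the pre-contrast map in the mask, and T1_b,post is
T1_b,pre minus the 75th percentile of the pre−post difference (not the
percentile of the post map — these differ for heterogeneous ROIs).
Percentiles interpolate linearly between order statistics. The ROI SNR
estimator is mean/SD (ddof = 1) of difference values in the ROI, flagged
infinite at zero SD.

## Synthetic data

The phantom generator assigns a ground-truth parameter set to each labelled
region, renders noise-free signals per measurement (each with its phase's
blood T1), and applies the control/label noise decomposition above;
truth maps are carried alongside losslessly and all randomness flows from a
single seed. It emulates the simulation studies' conditions — uniform
regions, Gaussian noise, instantaneous readout — and deliberately omits
anatomy, motion, partial volume, dispersion and B1 effects; passing tests
therefore demonstrate correctness of the estimation pipeline, not
robustness to those real-data effects.

## Problem sizes and determinism

Default study sizes are the ones used throughout: 151–251-point sensitivity
grids, 61-point perturbation grids, 2500 Monte Carlo replicates with 100
multistarts per fit. Unit tests run reduced versions (hundreds of
replicates, coarser grids); the acceptance tests and `scripts/acceptance.py`
run the full sizes. Every stochastic path (noise, start points) is driven
by explicit seeds, and repeated runs are bit-identical.

## Known limitations

- Voxel-level k_b is not practically identifiable at clinical SNR (CoV near
  190%); regional estimates are the intended output.
- The model ignores bolus dispersion, outflow, backflow, and the dependence
  of T1_e on k_b itself; long transit times (t_A beyond the post-contrast
  PLD) reduce sensitivity and precision.
- Results hinge on accurate blood T1 values (±1% class); the package
  quantifies this dependence but cannot remove it.
- The in-vivo "unconstrained simplex" configuration can leave the
  physiological range on noisy voxels by design; the published workflow
  masks such voxels post hoc, and `fit_volume` reproduces that masking.
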