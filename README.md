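# ceasl — contrast-enhanced ASL modelling of blood–brain barrier water exchange

The blood–brain barrier (BBB) restricts passive transport between blood and
brain; its breakdown accompanies neurodegeneration, stroke and multiple
sclerosis. The rate at which *water* exchanges across the barrier,
k_b = PS / v_bw (s⁻¹), is a sensitive marker of subtle BBB damage — but it
is hard to measure with arterial spin labelling (ASL) alone, because labelled
water in blood and in tissue relax at nearly the same rate at 3 T
(T1_b ≈ 1.65 s vs T1_e ≈ 1.5 s) and the two signal components cannot be
told apart.

Contrast-enhanced ASL (CE-ASL) fixes this by injecting an intravascular
gadolinium agent that shortens the blood T1 (to ≈ 0.8 s at the optimum)
without touching the tissue T1, making the compartments separable. `ceasl`
implements the full desk-scale toolchain for this technique, for MR
physicists designing protocols and analysing multi-delay ASL data:

- **model** — the two-compartment CASL difference signal. With
  J = k_b + R1_b, t′ = t − t_A and the phase kernel
  W(r) = (1 − e^{−r t′})/r during the bolus,
  W(r) = (e^{−r(t′−t_L)} − e^{−r t′})/r after it,

  ΔM(t) = 2 (f/6000) (M0/λ) α e^{−R1_b t_A} · [ W(J) + k_b (W(R1_e) − W(J)) / (J − R1_e) ],

  plus an ODE-integration oracle for the underlying compartment equations
  and the analytic sensitivity ∂ΔM/∂k_b.
- **sensitivity** — sweeps of that sensitivity over blood T1, PLD, tissue T1
  and underlying k_b, used to choose the post-contrast operating point.
- **fit** — (f, t_A, k_b) estimation from pre+post-contrast multi-PLD data:
  seeded multistart bounded least squares (with flow profiled out by
  variable projection) or the unconstrained simplex configuration used for
  in-vivo voxel-wise maps; batched over voxels/replicates.
- **error_propagation** — systematic k_b/f/t_A biases from mis-measured T1
  values, and the inversion giving required T1 accuracy.
- **monte_carlo** — accuracy (relative error of the median) and precision
  (CoV = IQR/truth) under the control/label Gaussian noise model, with
  √N SNR scaling for ROI averaging.
- **gbca_dose** — blood concentration → blood T1 via R1_post = R1_pre + r1·c_b,
  dose scaling, and time-to-target-T1 planning on measured or population
  vascular input functions.
- **t1map** — variable-flip-angle SPGR T1 fitting (with the linearized
  DESPOT1 estimator), the venous-sinus blood-ROI T1 extraction rule, and the
  ROI SNR estimator.
- **synth** — phantoms and signal tables with known ground truth, so every
  pipeline stage is testable without any scanner data.

## Worked example

```python
import numpy as np
from ceasl import (PhysioParams, FitConfig, NoiseModel,
                   make_signal_table, fit_signal)

truth = PhysioParams(f=60, t_A=1.2, k_b=2.65)        # grey-matter values
curves, table = make_signal_table(truth=truth,
                                  noise=NoiseModel(sigma=0.0017, roi_size=500),
                                  seed=0)
res = fit_signal(curves, {"pre": 1.65, "post1": 0.8}, t1e=1.5,
                 config=FitConfig(seed=0))
print(f"f = {res.f_hat:.1f} mL/min/100mL, tA = {res.tA_hat:.3f} s, "
      f"kb = {res.kb_hat:.3f} 1/s")
```

prints

```
f = 60.2 mL/min/100mL, tA = 1.203 s, kb = 2.892 1/s
```

— the five pre-contrast PLDs (0.9–2.1 s, blood T1 1.65 s) pin flow and
transit time almost exactly, while the single post-contrast PLD (1.5 s,
blood T1 0.8 s) makes the exchange rate identifiable: at the noise level of
a 500-voxel cortical ROI with control-image SNR 30, single-draw estimates
scatter around the true 2.65 s⁻¹ with a CoV of about 30% (here +9%). See `examples/` for one short
script per capability (sensitivity analysis, T1 error budget, Monte Carlo
precision, dose planning, phantom fitting, T1 mapping), and the `ceasl`
command-line tool for file-based use.

## Scope

The package covers modelling, simulation and fitting. Image registration,
segmentation, atlas ROI extraction and B1 correction are out of scope:
volumes are expected in a common space, masks and seed ROIs are inputs.
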