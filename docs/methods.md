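# Methods

This note documents the model behind `pulsesv`, the choices made where the
design was genuinely open, and what the package's tests do and do not
demonstrate.

## The forward model

**Governing equations.** Each arterial segment is a 1-D impermeable elastic
tube carrying the cross-sectional area A(x,t) and volumetric flow Q(x,t):

    ∂A/∂t + ∂Q/∂x = 0
    ∂Q/∂t + ∂(Q²/A)/∂x + (A/ρ) ∂P/∂x = −8πν Q/A

with blood density ρ = 1060 kg/m³ and viscosity μ = 4 mPa·s (ν = μ/ρ); the
friction term corresponds to a Poiseuille velocity profile. The wall is
linearly elastic: A(P) = A_ref·(1 + D·(P − P_ref)) with P_ref = 100 mmHg, so
the distensibility D (relative area change per unit pressure) is exactly the
quantity the Bramwell–Hill relation ties to the local wave speed,
c = sqrt(A/(ρ A_ref D)) = 1/sqrt(ρD) at the reference pressure. Viscoelastic
wall behaviour is deliberately out of scope; its omission makes simulated
waves slightly less damped than in vivo ones.

**Geometry.** The generic tree has 21 segments: ascending aorta → arch (two
pieces) → thoracic → abdominal aorta (three pieces) → common iliac → femoral
on both sides, brachiocephalic/carotid/subclavian–brachial branches (the arm
truncated at the mid-upper-arm measurement site), and lumped celiac,
mesenteric and renal branches. Dimensions follow published reduced
systemic-tree conventions; every junction joins one parent to at most two
children. Measurement sites: mid-to-distal common carotid, mid-upper-arm
brachial, proximal femoral. The definition lives in
`src/pulsesv/data/generic_tree.json` and is part of the versioned package.

**Boundary conditions.** The aortic root receives the parametric inflow wave
(below). Each terminal segment ends in a three-element Windkessel
(characteristic resistance Z_c in series with R_p ∥ C_T against a fixed
outflow pressure P_v = 8 mmHg). Junctions conserve flow and share a common
static pressure.

**Numerics.** Interior nodes advance with the two-step Lax–Wendroff
(MacCormack) scheme on per-segment uniform grids (Δx ≈ 0.5 cm, Δt from a
CFL factor of 0.8 against the fastest admissible wave speed, evaluated at
250 mmHg plus a 3 m/s convective margin). Boundary nodes are closed by the
outgoing Riemann invariants u ± 2c of the linear tube law, each reducing to
a monotone scalar Newton solve (root: prescribed Q; junction: common
pressure; terminal: Windkessel pressure–flow relation). The area update of
every boundary half-cell is then re-balanced with the same time-centred face
fluxes the interior scheme uses, which makes the discrete volume budget
telescope exactly: per-beat volume conservation errors are at machine
precision (~1e-8 of the stroke volume; the acceptance bound is 0.5%).
Beats are repeated from a uniform 80 mmHg initial state until the root
pressure is periodic (relative L2 difference < 1e-3 between consecutive
beats, max 20; the inverse loop tightens this to 1e-4 / 30 beats so that
beat-truncation noise stays well below its matching tolerances). The time
stepping is numba-compiled; one forward run of the default tree takes
roughly 0.1–0.3 s on one CPU core.

The Windkessel mean-pressure identity, (mean root pressure − P_v) =
R_total × (mean inflow), holds to ~1.9% on the default tree. The residual is
real physics of the nonlinear model, not discretization: conduit friction
plus the pulsatile convective (Bernoulli-type) mean pressure drop along the
tapering aorta; it persists when the viscosity is reduced and when the grid
is refined.

## The inflow wave

One beat has period 60/HR. Systole lasts `T_sys = K_SYS · sqrt(60/HR)` with
K_SYS = 0.31 s^1/2, a square-root-of-period law calibrated so that the
cohort-mean heart rate of 66 bpm gives 296 ms. The systolic shape is fixed:
a sinusoidal rise to the peak at F_PEAK·T_sys (F_PEAK = 0.412, placing the
peak at ~122 ms for HR 66) followed by a half-cosine decay to zero; diastolic
flow is identically zero. The template's normalized area is exactly 2/π, so

    SV = q_max · T_sys · 2/π

holds analytically and the stroke volume is exactly linear in q_max. The
reference peak is Q_MAX_REF = 450 mL/s (≈84 mL at HR 66); `s_Q` scales it.

## Observables

* **Brachial SBP/DBP** — max/min of the final-beat pressure at the brachial
  site.
* **Model cfPWV** — the transit time is the difference of the wave-foot
  times at the femoral and carotid sites; the distance is the difference of
  the root→site path lengths (the subtracted-distance convention of
  sequential carotid/femoral tonometry). Feet are located by the
  intersecting-tangent construction: the intersection of the horizontal
  through the beat's diastolic minimum with the maximum-upstroke tangent.
  The tangent is fitted by weighted least squares over the region where the
  25 Hz low-passed derivative exceeds 80% of its peak. A point tangent at
  the single steepest sample proved ill-posed on quasi-linear upstrokes
  (the derivative plateaus and its argmax can hop tens of milliseconds);
  the regression tangent varies smoothly with the waveform and preserves
  the affine invariance of the construction.

## The inverse estimator

Residuals are the relative errors of (brSBP, brDBP, cfPWV) against the
measurements, equally weighted; the scalar objective is their sum of
squares. The optimizer is a Levenberg–Marquardt-damped Gauss–Newton
iteration in log-parameter space with a forward finite-difference Jacobian
(relative step 1e-2), projection onto the bounds [0.2, 5], and adaptive
damping; it typically converges in 3–5 iterations (13–20 forward runs,
a few seconds per subject). A result is flagged converged when
|ΔSBP|, |ΔDBP| ≤ 0.5 mmHg and |ΔPWV| ≤ 0.05 m/s — measurement-precision
equality — but iteration continues to an objective of 1e-9 so that the
reported SV is the interior optimum, not a point on the tolerance-box
boundary (stopping at first entry made the estimate depend on the approach
path by up to ±3%).

The warm start is physics-informed: `s_R` from the Windkessel identity at an
assumed 70 mL stroke volume, `s_Q` from the same assumed volume, and `s_C`
from the path-averaged theoretical wave speed via the empirical inverse
`s_C0 = (0.92 · PWV_theoretical / PWV_measured)^2.65`. The 0.92 factor and
the 2.65 exponent are package calibrations: the extracted foot-to-foot speed
runs about 8% below the segmental average (feet travel at diastolic
pressure, where the linear tube law makes waves slower) and varies as
s_C^(−0.38) rather than the Bramwell–Hill −1/2, because wave-shape changes
move the fitted feet.

## Calibration of the generic tree

The study's tree and its supplementary adjustment rules are not published,
so the generic model's free constants are declared calibrations, fixed
against in-paper worked values and never adjusted per subject:

| Constant | Value | Role |
|---|---|---|
| total peripheral resistance | 0.95 mmHg·s/mL | cohort-mean MAP over cohort-mean flow |
| terminal compliance total | 0.40 mL/mmHg | diastolic decay; split pro rata to terminal flow fractions |
| aortic areas | ×0.85 of conventional values (ascending kept) | pulse-pressure-per-volume of the trunk |
| terminal Z_c | 1.5 × tube characteristic impedance | terminal reflection magnitude |
| aging factors at 75 y | 0.70 (ascending+arch), 0.80 (rest of aorta) | cfPWV age gradient |
| outflow pressure P_v | 8 mmHg | diastolic floor |
| reference anatomy | 170 cm, 70 kg, DuBois BSA | anatomy scaling |

Anchors: the cohort-mean forward run (84 mL at HR 66, age 49) must produce
brachial pressures inside the cohort envelope (it gives 131/64 mmHg) while
satisfying the Windkessel identity within 2%, and the inverse estimate for
the published virtual diastolic-dysfunction subject must land near its
published value (it gives 83.9 mL against 80). Aging is applied to the whole
aortic trunk with proximal emphasis — stiffening only the ascending
aorta/arch would barely move the carotid–femoral transit-time difference,
because both paths share those segments.

## The synthetic cohort generator

`statistical` mode draws each variable per age decade from truncated normals
(±3 SD, plus decade bounds on age) whose defaults are the study population's
age-stratified means and SDs — cfPWV rising from 6±1 to 10±2 m/s and SV
falling from 92±26 to 68±11 mL across decades — with brSBP forced above
brDBP + 10 mmHg. It reproduces marginal distributions and the decade
structure, not the full covariance of real physiology, and its SV column is
drawn, not computed.

`forward_model` mode draws demographics the same way, then draws true
scalings (log-normal, σ = 0.18, clipped to [0.4, 2.5]), runs the forward
model, and stores the simulated triplet as the "measured" columns and the
true inflow integral as `SV_ref_mL`. These subjects have a known right
answer by construction, which is what makes the flagship recovery test
meaningful: it demonstrates that the inverse machinery inverts the forward
model (identifiability + optimization), not that the model matches any real
population.

## What passing tests do and do not show

The paper-scale validation (n = 144 against MRI; r = 0.83, nRMSE 13.8%,
bias 1.5 mL) requires the original clinical dataset and is out of reach
here. The tests show: exact physics invariants of the solver; sub-percent
recovery of true SV for model-generated subjects across decades;
reproduction of the published virtual-subject estimate within 10%; and
exact arithmetic of the statistics layer. They do not show accuracy on real
humans.

## Known limitations

* **Identifiability is not strict everywhere.** At some operating points
  (e.g. low heart rate with high resistance) two parameter sets reproduce
  the observable triplet to machine precision: a compensation family
  (s_C·λ, s_Q·λ, s_R/λ) leaves MAP, the diastolic time constant and
  pulse-pressure-per-volume unchanged, and the foot-to-foot extraction
  breaks it only weakly. The physics-informed warm start selects the
  physiological branch in all tested cohorts; users probing extreme
  subjects can verify with restarts via `InverseConfig(init_scalings=...)`.
* **The triplet→SV mapping is model-specific.** The reduced tree was
  calibrated to the published virtual subject; at cohort-typical operating
  points it maps measured triplets to lower SV than the original
  103-segment model would. Estimates on real (non-model-generated) subjects
  inherit this bias.
* Elastic (not viscoelastic) walls; fixed inflow shape for all ages; no
  cerebral or coronary circulation; gender is accepted but geometry-neutral
  by default; measurement noise and device timing offsets are not modelled.
* The statistical cohort mode imposes no within-subject covariance beyond
  decade structure (e.g. no height–weight correlation).
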