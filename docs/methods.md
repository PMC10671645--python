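# Methods

## Model

The body is approximated by 12 tissue compartments and 3 blood pools joined
by the circulation; each tissue is resolved into four well-stirred
subcompartments (residual blood cells TC, residual plasma TP, extracellular
water EW, intracellular water IW), each blood pool into plasma and cells.
States are concentrations (mg/L); amounts are recovered as V·C. All
exchange is linear:

* passive permeation across adjacent interfaces (TC↔TP, TP↔EW, EW↔IW, and
  cells↔plasma within each circulating pool), driven by the *free* (unbound
  and unionized) concentration difference, J = PS·(C_a fu_a fi_a − C_b fu_b fi_b);
* unidirectional transporter fluxes on the cell membrane only
  (EW→IW uptake, IW→EW efflux), J = CL·C_source·fu_source;
* first-order metabolism available in every subcompartment including the
  circulating pools, J = CL_met·C·fu.

Note the deliberate asymmetry: the unionized fraction fi enters the passive
flux only; transporter and metabolic fluxes use fu alone. The flux laws are
implemented literally in that form.

The circulation follows the usual topology: arterial blood perfuses all
tissues except the lung; pancreas, spleen, and gut drain into the portal
vein, which joins the hepatic artery to perfuse the liver; all other
tissues and the liver drain into venous blood, which perfuses the lung,
which feeds the arterial pool. Blood flow is split into plasma and
blood-cell streams by the hematocrit (0.45): Q_tc = Hct·Q, Q_tp = (1−Hct)·Q
— the split is not stated for flows in the source material, and treating
flowing blood as homogeneous is the single consistent choice.

Assembled over the 12·4 + 3·2 = 54 states this gives dC/dt = A·C + f(t)
with a constant rate matrix. Mass balance holds algebraically: for every
column j, Σ_i V_i·A[i,j] = −CL_met(j)·fu(j), so with no metabolism anywhere
the system is closed, A annihilates the uniform vector, and the exact
equilibrium after any dose is a uniform concentration — Kp = 1 in every
tissue and Vdss = 1.000 L/kg at density 1 kg/L. This identity is used as a
construction check in the test suite, not merely as a convention.

### Dosing

IV doses enter the venous plasma: a bolus as C_vp(0) = dose/V_vp, an
infusion as a constant mass rate (running for the whole horizon unless a
stop time is given). An oral dose enters the *gut intracellular water* with
the analytic first-order forcing Dose·Ka·e^(−Ka·t); first-pass through
portal vein and liver emerges from the network, so no bioavailability
parameter exists. A depot-state formulation of the oral dose is provided
purely as a solver cross-check and agrees with the analytic forcing to
better than 1e-9 (relative) in the tests.

### Derived quantities

C_tissue is the amount-weighted mean over the four subcompartments;
Kp(t) = C_tissue/C_vp uses venous plasma as the accessible surrogate of
systemic plasma; Vd(t) = (total amount in body)/(C_vp·BW) in L/kg. The
plain reading of the Vd definition lists venous, arterial, and tissue
amounts only; the implementation *includes the portal-vein blood* by
default because only then is the closed-system null case exactly 1 L/kg —
the omission would bias every Vd by ≈ V_portal/BW ≈ 0.004 L/kg. The literal
variant is available via `include_portal=False`.

### Pseudo-steady state

After a single dose to an open system, Vd(t) plateaus once all compartments
decay with the common terminal slope. Detection scans the output grid for
the earliest time after which (a) the log-slopes of the 12 tissue
concentrations agree with the venous-plasma slope within 1e-3 relative (or
1e-4 1/h absolute, which covers closed/steady systems whose slopes approach
zero), and (b) the relative drift of Vd stays below 1e-4 per hour; Vdss is
read at the end of the horizon. Because the model is linear, the terminal
state is also available in closed form — the dominant eigenmode of A for a
single dose, the stationary solve A·C = −f for constant infusion, and the
particular solution −(A + Ka·I)⁻¹·g when oral absorption is slower than the
dominant decay (flip-flop). The simulated and closed-form Vdss agree within
0.5% for every converged grid scenario in the tests; this dual route is the
package's primary internal validity check.

## Numerical choices

* Integrator: `scipy.integrate.solve_ivp` BDF with the exact constant
  Jacobian; rtol 1e-9, atol 1e-12 mg/L. Output on a log-spaced grid
  (default 300 points from 1e-3 h) so both the first minutes and the
  terminal phase are resolved.
* For scenario runs the horizon is chosen from the spectral gap between the
  two slowest modes (14/gap, clipped to [30, 600] h for single doses;
  1000 h for infusion and slow absorption; 20 h suffices for the closed
  null case), and the absolute tolerance is lowered to sit ~8 decades below
  the expected terminal concentration so that late-time slopes are not
  corrupted by the solver floor. Trajectory values in [−atol, 0) are
  clamped to zero; anything more negative raises.
* Trajectory oracle: the matrix exponential (augmented-matrix form for
  forced regimens), agreeing with the integrator to 1e-6 relative across
  the full 14-decade decay in the tests.
* Eigen-based closed forms warn on near-degenerate or significantly complex
  dominant eigenpairs; none of the study scenarios triggers this.

## Physiology parameterization

The reference body is 70 kg / 300 L/h cardiac output at density 1 kg/L,
shipped as `data/human_70kg.csv` (columns: tissue, V_total_L,
V_residual_blood_L, V_ew_L, V_iw_L, Q_blood_L_per_h; the liver row carries
the hepatic-artery flow, the lung row the cardiac output). Residual blood
is split 45/55 into cells/plasma; IW is defined as the remainder
V_total − V_residual − V_ew so that subcompartment volumes tile the body
exactly (solids are folded into IW — required for the exact closed-system
null case). Rounding slack up to 0.5% of body weight is absorbed by
rescaling muscle IW.

The original study's per-tissue table could not be recovered from the
source text; the shipped table was reconstructed **once** from the standard
literature the study cites: reference-male organ volumes and flow fractions
of cardiac output (ICRP/Brown-style compilations), rat vascular-space
fractions for residual blood, and standard extracellular-water fractions.
Tissue flows were rescaled proportionally (×1.081) so the venous return
balances the 300 L/h cardiac output exactly, muscle volume closes the 70 kg
total, and the circulating blood (5.6 L total minus residual) was split
venous:arterial 2:1 with a 0.25 L portal vein. No entry was adjusted
afterwards.

### Consequences for quantitative comparison

The reconstruction reproduces the published low-to-moderate-extraction
results closely — the closed-system null case exactly; hepatic-metabolism
Vdss cells such as liver-IW CL/Q ∈ {0.1, 1} (1.14/1.49 vs printed
1.12/1.49); the worked-example partition coefficients (lung 1.0006 vs
1.0005, kidney 1.0033 vs 1.003); infusion with hepatic IW clearance (0.979
vs 0.98). It does **not** reproduce the cells whose value is amplified by
proximity of the dominant eigenvalue to the slow-tissue pole, where Vdss
behaves like 1/(pole − λ) and modest differences in slow-tissue
volume-to-flow ratios blow up. Computed vs printed:

| Scenario (IV bolus unless noted) | computed | printed |
|---|---|---|
| permeability ladder PS/Q = 0.01 / 0.1 / 1 / 10 / 100, CL_IW = Q | 0.54 / 1.76 / 4.33 / 3.25 / 3.02 | 0.23 / 4.59 / 5.45 / 5.41 / 5.41 |
| same, IV infusion | 0.14 / 0.17 / 0.25 / 0.27 / 0.27 | 0.22 / 0.25 / 0.33 / 0.35 / 0.36 |
| liver residual-plasma CL = 10·Q_liver | 3.07 | 4.57 |
| residual-plasma CL = Q, all tissues | 13.39 | 36.97 |
| efflux transporter CL = Q, PS = Q, CL_IW = Q | 1.98 | 2.38 |
| uptake transporter CL = Q, PS = 0.1·Q, CL_IW = Q | 57.1 | 71.9 |

All *directional* results — bolus Vdss increasing with metabolism while
infusion Vdss decreases, residual-blood metabolism outweighing tissue
metabolism, uptake-above-none-above-efflux for single doses, saturation of
the permeability effect above PS ≈ Q — hold, and the internal
simulation-vs-closed-form agreement is at the 0.5% level throughout, so the
discrepancies are attributable to the input table, not the solver.

Two qualitative differences follow from the same root:

* Under the reconstructed physiology the dominant decay constant slightly
  exceeds 1 1/h in a few high-clearance scenarios, so "fast" oral
  absorption (Ka = 1 1/h) is genuinely mildly flip-flop there and its Vdss
  does not exactly equal the bolus value; results carry a `flip_flop` flag.
* At infusion steady state with intracellular metabolism present, an uptake
  transporter *lowers* Vdss at low permeability in this model: pushing drug
  into the eliminating compartment raises whole-body extraction more than
  it raises storage (IW balance: C_iw/C_ew = (PS + CL_up)/(PS + CL_met)
  while the tissue inflow deficit grows with CL_met·C_iw). The published
  grid reports uptake raising Vdss for every route. The same mechanism
  promotes the uptake fold to the top of the infusion Sobol ranking,
  statistically tied with the plasma↔EW permeability fold.

## What-if grids

Folds resolve per tissue against its total blood flow Q = Q_tp + Q_tc (for
the liver, hepatic artery + portal vein = 82.7 L/h here). The permeability
fold scales TP↔EW and EW↔IW jointly — supported by the cross-grid identity
that the permeability ladder at PS/Q = 1 equals the all-tissue IW
metabolism cell at CL/Q = 1, which the implementation asserts to 1e-6.
The TC↔TP membrane (and cells↔plasma in circulating pools) stays at
1000 L/h, i.e. effectively instant equilibration, unless overridden. The
metabolism grids use a baseline PS of 1×Q on both membranes (not printed in
the source; inferred from the same cross-grid identity). "Low"/"high"
permeability in the transporter grid are 0.1×Q and 1×Q; the transporter
fold is 1×Q in all 12 tissues.

## Global sensitivity analysis

Eight fold parameters (metabolic clearance per subcompartment ×4, the two
membranes, uptake, efflux) are sampled log-uniformly over one decade either
side of a baseline of 1% of tissue blood flow. The source material states
the baseline inconsistently (1% in its methods, 10% in its results); the
methods value is the default and the config exposes it. Sampling uses a
scrambled Sobol sequence (scipy.stats.qmc); indices use the Saltelli-2010
estimator for S1 and the Jansen estimator for ST, with 95% bootstrap
confidence half-widths (200 resamples). One independent design per dosing
route; 1000 base samples → 10 000 model evaluations per route. Each
evaluation resolves Vdss in closed form from an affine reassembly
A0 + Σ p_i·B_i of the rate matrix (exactness of the decomposition is
asserted in the tests), so a full panel takes seconds. Vd(t) indices on a
coarse time grid are available from the same eigendecompositions; only the
scalar Vdss endpoint is part of the standard panels. Reported S1/ST are
clipped to [0, 1] with raw estimator values kept alongside.

## Synthetic toy bodies

`make_toy_body` draws balanced miniature physiologies (liver + lung + gut +
n generic tissues) that keep the portal→liver topology so the liver and
portal equations are always exercised; all flow balances and the density
identity hold exactly for every seed. They emulate the *structure* of the
full body, not human magnitudes: volumes and flows are uniform draws, so
passing toy-body tests demonstrates correctness of the bookkeeping and
solvers, not physiological realism. Real-data features deliberately absent
everywhere: nonlinear (saturable) transport or metabolism, plasma-protein
binding and ionization gradients (fu = fi = 1 in all study scenarios),
lymphatic return, endothelial/organelle subcompartments, and mechanistic
oral absorption — slow absorption is a bare first-order Ka = 0.01 1/h.

## Known limitations

* The physiology table is a reconstruction; pole-amplified grid cells carry
  large quantitative uncertainty (table above) even though every internal
  cross-check is tight.
* Vdss for slow oral absorption is reported together with t_pss rather than
  asserted as converged: under flip-flop kinetics the plateau is shallow
  and horizon-sensitive.
* The pseudo-steady-state detector requires a trajectory that actually
  reaches slope agreement within the horizon; it raises (rather than
  extrapolates) otherwise.
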