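# Methods

## Model structure and assumptions

The simulator represents the eye–brain–body fluid system as a hydraulic
circuit solved at steady state. Time dependence is deliberately absent:
cardiac pulsatility, postural transients and tissue remodelling are
outside scope, as is active blood-flow autoregulation — vessel calibers
respond only passively, through the transmural-pressure dependence of the
collapsible segments. The two eyes are assumed identical, so one eye is
represented and the ophthalmic-artery supply and cavernous-sinus drainage
carry a factor of two.

Compartments and unknowns (31 node pressures, mmHg):

* **brain** — intracranial arteries (I), capillaries (C), venous sinuses
  (S), brain tissue/interstitium (B), ventricular CSF (F) and an
  extraventricular CSF compartment (T) that bridges to the optic-nerve
  subarachnoid space (the retrolaminar tissue pressure equals P_T);
* **eye** — inlet (ophthalmic artery), the four-segment central retinal
  artery and vein, and three parallel vascular beds (retina, choroid,
  ciliary body), each an arteriole–capillary–venule chain whose
  compartments are split into two half-resistances around a mid-pressure
  node; plus the aqueous chamber whose pressure is the IOP;
* **boundaries** — central arterial and venous pressures P_A, P_V; the
  episcleral veins and the ocular venous output coincide with the venous
  sinus pressure P_S.

Sources: CSF production Q_CF is extracted from the cerebral capillaries
and injected into the ventricular compartment (an internal transfer);
aqueous secretion J_secr enters the eye from outside the tracked blood
volume; the uveoscleral outflow J_uv leaves to the zero-pressure
reference. Global conservation therefore reads
Q_A + 2 J_secr = Q_SV + Q_TV + 2 J_uv at any converged state.

Constitutive laws: hydraulic Ohm's law with Poiseuille resistances for
rigid segments; Starling–Landis filtration across the blood–brain barrier
(coefficients K_CB, σ_CB) and across the ciliary capillary wall
(ultrafiltration J_uf); a two-branch collapsible-tube (Starling-resistor)
law for all venous segments, with the distension-only form for the central
retinal artery, whose transmural pressure stays positive in the operating
regime; trabecular drainage through the pressure-dependent resistance
R_tm = R0 (1 + κ(IOP − P_evp)) and saturating uveoscleral drainage
J_uv = k1·IOP/(k2 + IOP).

As printed in its source, the transmural pressure of the last
(intraocular) arterial segment uses the downstream node pressure rather
than the segment midpoint; this is implemented literally, with a
configuration switch (`cra4_midpoint`) selecting the midpoint convention
instead. Both venule half-resistances of a bed are evaluated at the same
transmural pressure P_i,v − IOP, the single formula given for them.

## Units

Internally everything is mmHg / ml / min. Viscosities quoted in mmHg·s
are divided by 60 on load; aqueous quantities quoted per microlitre are
scaled by 10³ at the parameter boundary. Brain blood flows are of order
10³ ml/min while aqueous flows are of order 10⁻³ ml/min; a single unit
system prevents silent factor-of-1000 errors where they meet.

## Calibration and the audited profile

The published parameter tables do not close the model. Two quantities are
derived by the model's own calibration procedure:

* **Venous compartment geometry.** Venous blood volumes of the ciliary
  and choroidal beds are assumed proportional to their reference flows
  relative to the retina (V_i = (Q̄_i/Q̄_r) V_rv, with
  V_rv = A_r,v·L_v the retinal anchor), giving lengths L_i = V_i/A_i.
  The areas A_i,v are then obtained by imposing that the Starling
  resistance, evaluated at the reference transmural pressure
  P̄_i,v − 15 mmHg, equals the Ohm's-law venule resistance implied by the
  reference pressures and flows (a bracketed scalar root solve; the
  round-trip is exact to better than 1e-8 relative). Applied to the
  retina itself, the procedure yields A_r,v ≈ 2.37·10⁻⁴ cm², not the
  printed 1.55·10⁻⁴ cm²: with the shared elastic moduli, the printed area
  would give a venule resistance several times the value the reference
  pressure column implies. The audited profile therefore calibrates all
  three beds; the printed areas remain available under the
  `literal-table5` profile.

* **Central coupling edges.** The printed central-artery and central-vein
  resistances (101.5 and 407.99 mmHg·min/ml) are inconsistent by five
  orders of magnitude with the printed ~1 l/min central flows. The
  audited profile replaces the two composite edges with Ohm's-law values
  derived from the reference operating point:
  (P_A − P̄_I)/Q̄_A = 9.666·10⁻³ and (P̄_S − P_V)/Q̄_SV = 2.339·10⁻³
  mmHg·min/ml.

`eyebrain0d audit` quantifies every node imbalance and Ohm's-law residual
of the reference tables. Three inconsistencies are documented and
accepted rather than repaired: the ventricular node does not balance
(the printed ventricular-interstitial shunt Q_FB = 42.42·10⁻³ ml/min is
incompatible with the printed equal P_F and P_B, so Q_FB is treated as a
solver output); the ciliary branch resistances give Q_cl ≈ 132 µl/min
versus the printed 135.7 µl/min (a ~3% gap); and the flow column is
rounded independently of the pressure column at the 0.1–0.3% level.
Under the audited profile the solved Earth steady state reproduces every
reference pressure within 0.8% and every reference flow within 3%
(except Q_FB, which the solve correctly sends to ≈ 0).

## Lamina cribrosa surrogate

The radial compressive stress P_LC exerted by the lamina cribrosa on the
translaminar vessel segments is represented by a clamped quadratic
surface P_LC = max(0, c0 + c1·IOP + c2·CSFp + c3·IOP² + c4·IOP·CSFp +
c5·CSFp²), standing in for a full 3-D nonlinear elastic computation. The
coefficients are a first-class configuration block. The shipped default,
P_LC = max(0, 0.25·(IOP² − 21²)) mmHg, is calibrated to three anchors:
zero stress (and zero gradient) at the physiological operating point;
essentially zero stress across the whole pre-collapse range of the
fluid-shift scenarios (IOP ≲ 21 mmHg), so the stress stays flat over a
wide range of oncotic pressures and then rises sharply; and a rise steep
enough that the translaminar vein segment is crushed shortly *after* the
intraocular venules collapse, making the central-vein collapse the last
event of the cascade. The default carries no CSFp dependence — the
operating range of CSFp in these scenarios is narrow — and every
scenario output downstream of a collapse onset is sensitive to this
surrogate; users with a fitted stress surface should supply their own
coefficients.

## Scenarios

Earth uses the baseline boundary pressures and an intact barrier. Head-
down tilt (θ = 6°) raises both central pressures by the hydrostatic
column G·sinθ; G = ρgH is not fixed by any printed constant (the
atrium-to-head distance H is never specified), so it is a configuration
scalar. The default G = 24 mmHg (ρ ≈ 10³ kg/m³, H ≈ 0.31 m) was chosen
so that the tilted IOP at physiological oncotic pressure lands near the
reported ≈ 17.5 mmHg; tilt results scale directly with this choice.
Microgravity (M0/M1/M2) zeroes the hydrostatic offsets and the central
venous pressure; M1 and M2 additionally weaken the blood–brain barrier
(K_CB = 0.1164, σ_CB = 0.5714 and K_CB = 0.1330, σ_CB = 0.5).

Fluid-shift severity enters through the blood oncotic pressure π_c:
Δπ_p = π_c − π_ah with π_ah = 0, and Δπ_CB = π_c − π_B with π_B = 4 mmHg
fixed so that π_c = 25 mmHg reproduces the baseline difference of
21 mmHg. The default sweep descends from 25 to 18.5 mmHg in 0.05 mmHg
steps; perfusions are normalized per bed against the Earth π_c = 25
solution.

## Numerics

The 31 Kirchhoff balances are solved by a damped Newton iteration:
central-difference Jacobian (forward differences are too inaccurate near
a pinned collapsed venule, where the tube-law curvature is set by
buckling pressures k_p of order 0.01–0.1 mmHg), step cap of 5 mmHg,
line search on the least-squares merit with convergence judged on the
residual infinity norm (tolerance 1e-9 ml/min), and iterates confined to
|P| < 10³ mmHg — the last excludes a spurious attractor in which a fully
pinched-off venule leaves its mid-node pressure unbounded between two
infinite resistances.

The tube law is continuous but not differentiable at zero transmural
pressure, which defeats plain Newton exactly at a collapse transition.
Each solve therefore runs an active-set loop: the branch
(distended/collapsed) of each of the seven switchable elements is frozen,
the smooth frozen system is solved, and elements whose transmural-
pressure sign disagrees with the assumed branch are flipped before
re-solving from the converged point. Both branches coincide at the kink,
so the loop terminates; a dead band of 1e-9 mmHg around zero treats the
exactly-critical case as branch-indifferent. In the rare event that the
frozen solve still stalls (directly at a transition), a bounded
trust-region least-squares pass followed by a Powell-hybrid polish
finishes the point.

Sweeps warm-start each oncotic-pressure point from the previous solution
and insert intermediate points recursively when a step fails: past a
collapse onset the branch is nearly vertical in π_c (the collapsed
venules pin their transmural pressures within ~0.01 mmHg of zero, so
state changes concentrate in a narrow π_c window). Because the kink
creates a narrow fold with briefly coexisting distended and deep-collapse
solutions, onsets are defined — and the onset bisection evaluates — along
the branch swept *downward* in π_c; ascending and descending sweeps agree
to ~1e-10 wherever no transition is crossed, and the collapse flag is
strict (Δp_t = 0 counts as open). The onset bisection localizes each
sign change to 1e-3 mmHg. The full four-scenario experiment (524 steady
states plus all onset searches) runs in a few seconds.

## Behaviour at the default configuration

On Earth at π_c = 25 the model reproduces the reference operating point
(see the audit bounds above). Over the sweeps, ICP and IOP both rise
monotonically as π_c falls, ICP linearly to better than R² = 0.98 before
any collapse; the barrier-weakened cases raise ICP far more than IOP. The
collapse cascade begins with the ciliary venules (π_c* ≈ 19.8–19.9 mmHg
across scenarios), the choroidal venules follow within ≲ 0.06 mmHg, and
the prelaminar central-vein segments are crushed ≈ 0.5 mmHg later — in
head-down tilt consistently at slightly lower π_c (later) than in
microgravity. Retinal perfusion shows the passive plateau (within 5% of
baseline above the vein-collapse onset), a transient overshoot while the
parallel beds collapse, and a sharp drop once the vein itself is crushed.

One reference behaviour is *not* reproduced: collapse of the postlaminar
(retrobulbar) central-vein segments shortly after the choroid. Their
external pressure is the extraventricular CSF pressure, which rises only
to ~14–16 mmHg at π_c = 18.5 in any scenario, while the segments'
intraluminal pressures stay near 19–21 mmHg; driving P_T to the ~19 mmHg
needed would require π_c far below the swept range. With the printed
brain and coupling constants this clause is unreachable; only M2 shows a
marginal postlaminar collapse at π_c ≈ 18.67 mmHg, below the prelaminar
onset. The corresponding acceptance test is left failing deliberately
rather than weakened.

## Known limitations

* Steady state only; no pulsatility, no autoregulation, no jugular
  collapsibility, no lymphatic/glymphatic drainage.
* The lamina stress surface is a surrogate; collapse-cascade timing
  below the ciliary onset inherits its calibration.
* The head-down-tilt hydrostatic coefficient G is a calibration choice,
  not a measured constant.
* Single-branch continuation: the narrow fold at each collapse
  transition implies coexisting solutions over ~0.01 mmHg windows of
  π_c; no bifurcation or multistability analysis is attempted.
* The venule areas of the audited profile absorb any error in the shared
  elastic moduli; they are effective, not anatomical, quantities.
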