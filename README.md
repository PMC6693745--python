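# eyebrain0d

A steady-state lumped-parameter (0-D) simulator of the coupled circulation
of fluids in the eyes and the brain — blood, cerebrospinal fluid (CSF),
interstitial fluid and aqueous humor — embedded in a minimal central
circulation. It is written for computational physiologists and vision
researchers studying how cephalad fluid shifts (long head-down tilt,
spaceflight / SANS) move intraocular pressure (IOP), intracranial pressure
(ICP) and ocular perfusion, and as a virtual lab for the IOP–CSFp–blood
pressure interactions relevant to glaucoma.

## The model

The physiological system is a hydraulic network solved at steady state.
Pressure-driven flow between compartments follows the hydraulic Ohm's law

    Q_ij = (P_i − P_j) / R_ij,        R = 8πμL / A²   (Poiseuille),

transcapillary filtration follows the Starling–Landis equation

    Q_ij = K_ij [ (P_i − P_j) − σ_ij (π_i − π_j) ],

and every venous segment of the eye (retinal, choroidal and ciliary
venules; the four segments of the central retinal vein) is a **Starling
resistor** whose resistance depends on the transmural pressure
Δp_t (intraluminal minus external):

    R(Δp_t) = R₀ (1 + Δp_t/(k_p k_L))⁻⁴          for Δp_t > 0  (distension)
    R(Δp_t) = R₀ (1 − Δp_t/k_p)^(4/3)            for Δp_t ≤ 0  (collapse)

with k_L = 12A/(πh²) and k_p = E h³ π^(3/2) / (12(1−ν²) A^(3/2)).
Intraocular vessels are loaded by the IOP; retrobulbar segments of the
central retinal artery/vein by the extraventricular CSF pressure; the
translaminar segments by the radial compressive stress P_LC of the lamina
cribrosa, represented by a configurable quadratic surface P_LC(IOP, CSFp).
The IOP itself is an unknown of the system, set by the aqueous humor
balance J_uf + J_secr = J_tm + J_uv (ultrafiltration + active secretion =
trabecular + uveoscleral drainage).

Kirchhoff current laws at the 31 unknown-pressure nodes close a nonlinear
algebraic system, solved by a damped Newton iteration with an active-set
treatment of the piecewise tube law. Fluid-shift severity is swept through
the blood oncotic pressure π_c ∈ (18.5, 25) mmHg in five environments:
Earth, 6° head-down tilt (LHDT), and microgravity with an intact (M0) or
weakened (M1, M2) blood–brain barrier.

## Worked example

```python
from eyebrain0d import default_parameters, make_scenario, solve_steady_state

params = default_parameters()                      # audited profile
earth = solve_steady_state(params, make_scenario("EARTH", pi_c=25.0))
print(f"IOP  = {earth.state.IOP:.3f} mmHg")
print(f"ICP  = {earth.state.P_F:.3f} mmHg (ventricular CSF)")
print(f"Q_r  = {earth.flows.Q_r*1e3:.2f} ul/min")

lhdt = solve_steady_state(params, make_scenario("LHDT", pi_c=21.7),
                          guess=earth.state)
print(f"LHDT pi_c=21.7: IOP = {lhdt.state.IOP:.3f} mmHg, "
      f"ICP = {lhdt.state.P_F:.3f} mmHg")
```

prints

```
IOP  = 14.956 mmHg
ICP  = 11.199 mmHg (ventricular CSF)
Q_r  = 41.37 ul/min
LHDT pi_c=21.7: IOP = 19.358 mmHg, ICP = 14.890 mmHg
```

The Earth steady state reproduces the published physiological operating
point (IOP ≈ 15 mmHg, ICP ≈ 11.2 mmHg, retinal / choroidal / ciliary
perfusion ≈ 41 / 368 / 132 µl/min). Under head-down tilt at a reduced
oncotic pressure the headward fluid shift raises both IOP and ICP; pushing
π_c below ≈ 19.8 mmHg collapses the ciliary and choroidal venules and the
simulator tracks the resulting nonlinear IOP rise and perfusion
redistribution (`eyebrain0d.scenarios.run_experiment` produces the full
sweep tables and the collapse-onset report).

A command-line interface wraps the same library:

```bash
eyebrain0d baseline                      # Earth steady state, CSV export
eyebrain0d sweep --scenario M2 --pic-min 18.5 --pic-max 25 --step 0.05
eyebrain0d collapse --scenario LHDT      # venous collapse onsets
eyebrain0d audit                         # consistency audit of the
                                         # reference tables
```

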