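# Methods

## Physical model

The simulator reproduces a desk-scale computational study of
radiofrequency ablation in liver tissue whose electrical conductivity has
been raised locally by infusing a conductive fluid (normal saline or a
dilute gold-nanoparticle colloid) into a spherical zone around the
electrode. Two domains are modelled, both 2D axisymmetric:

* **tissue model** — a cylinder of radius 10 cm and height 16 cm with a
  3-cm active metal tip (radius 0.75 mm) centred axially, an insulated
  trocar shaft above it, and an optional doped sphere of 2, 3 or 4 cm
  diameter centred on the tip midpoint;
* **agar phantom** — a cylinder of radius 5 cm and height 11 cm with the
  active tip spanning 40–70 mm and a 4-cm sphere at the centre, used for
  electrical characterization only.

### Electrical problem

At 500 kHz the quasi-static approximation holds and the potential solves
∇·(σ∇V) = 0 with V fixed on the (equipotential) metal tip and V = 0 on all
outer boundaries (the dispersive electrode); the symmetry axis is a
natural no-flux boundary. Impedance is the applied voltage over the
discrete flux through the electrode node set, which agrees with the
power-based value V²/P to round-off by Green's identity. Joule heat
σ|∇V|² is deposited per element.

### Thermal problem

The heat balance uses the enthalpy method: ∂(ρh)/∂t = ∇·(k∇T) + Q with a
piecewise-linear ρh(T) whose slope is ρc below 99 °C, h_fg·C on the
99–100 °C vaporization window and ρ_g c_g above. Numerical values:
h_fg = 2.257·10⁶ J/kg × 958 kg/m³ (water at 100 °C), water content
C = 0.68, and ρ_g c_g defaulting to the liquid value (a continuation; the
choice matters little because the desiccated conductivity suppresses
further heating above 100 °C). Perfusion is zero (ex vivo).

### Electrical conductivity of heated tissue

σ(T) = σ_ref·e^{0.015(T−37)} up to 99 °C (a +1.5 %/°C rise), then a linear
drop of two orders of magnitude across the 99–100 °C window, latched
irreversibly on the running per-element peak temperature (desiccated
tissue does not rehydrate). The drop-across-the-window form is the
standard way the two-orders-of-magnitude desiccation at 100 °C is
implemented in this modelling tradition; placing the whole drop strictly
above 100 °C delays the impedance rise by roughly a further 10 % of the
roll-off time. Two documented readings of the temperature coefficient were
tested and rejected against the published roll-off behaviour: a
*decreasing* conductivity (the literal "impedance increases +1.5 %/°C"
phrasing) produces roll-off in ~45 s instead of ~457 s at 50 V, and a
linear (1 + 0.015·ΔT) rise moves both roll-off times and diameters away
from the published values; the exponential increasing form is the default.

### Damage and lesion metrics

The Arrhenius integral Ω(t) = A∫exp(−Eₐ/R·T(τ))dτ uses A = 7.39·10³⁹ s⁻¹,
Eₐ = 2.557·10⁵ J/mol as printed in the source material (the canonical
liver pair in the wider literature has Eₐ = 2.577·10⁵; switching changes
lesion diameters by under 5 %). Temperatures are held in °C everywhere and
converted to kelvin only inside the integrand, which is accumulated
trapezoidally per node from t = 0 with no cutoff temperature. The
coagulation zone is the Ω = 4.6 isoline (99 % cell-death probability)
extracted by linear interpolation on the triangulation at roll-off time;
the axial diameter A is the z-extent of the contour set, the transverse
diameter B twice its maximal radial extent, sphericity A/B, and volume the
revolved contour integral ∮πr²dz.

### Electrode cooling

The applicator is internally water-cooled (8 °C). The original model
section never states the thermal boundary condition at the electrode
wall, yet the long 50-V roll-off times require strong cooling. The default
here is a fixed 8 °C (Dirichlet) wall over the metal tip; a convective
alternative −k∂T/∂n = h(T − T_cool) with h configurable (a
laminar-flow estimate for this coolant channel gives h ≈ 2 400 W/m²K) is
exposed in the run configuration. This choice is the single largest source
of quantitative mismatch: the Dirichlet wall reproduces the 50-V roll-off
times to within ~20 % but over-predicts lesion diameters by 25–50 %, while
the convective wall reproduces diameters and the short 70/90-V roll-offs
well but shortens the 50-V roll-off by ~30 %. No cooling strength
reconciles both regimes, so the simpler Dirichlet default is kept and the
residual disagreement reported as is.

### Doped-tissue properties

Saline raises conductivity by 215·(0.009·C) S/m for an infused volume
fraction C; the AuNP colloid by 0.071 S/m per weight-percent (calibrated
at 500 kHz, 10-nm particles). Density and volumetric heat capacity mix
linearly in the dispersed-phase volume fraction Φ_D, and thermal
conductivity follows Maxwell–Eucken. For the AuNP colloid Φ_D counts only
the solid gold: the default constant 5.415·10⁻⁶ per unit C reproduces the
published property table (the first-principles value from the colloid
composition is ~4 % lower and is available as an option). For saline the
published table keeps all thermal columns at tissue values — the fluid's
ρ, c and k are within a few percent of tissue — and the composed
properties follow the table rather than applying the mixture rules with
Φ = C (which would raise c by up to 1.7 % at C = 10 %). Only σ changes
appreciably in either case.

## Numerics

* **Meshing** — tensor-product grids in (r, z), geometrically graded from
  0.1–0.2 mm at the electrode surface to 3–6.5 mm in the far field
  (refinement levels 1–4), with grid nodes snapped onto the doped-sphere
  interface so region boundaries are conforming polylines; quads split
  along the shorter diagonal; element regions assigned by centroid, ties
  resolved toward the more conductive region.
* **FEM** — P1 triangles with 2πr volume weighting; one-point radial
  quadrature (exact for elementwise-constant coefficients); ring-weighted
  lumped mass; sparse LU solves.
* **Time stepping** — backward Euler, default Δt = 0.1 s at reference
  resolution; each step solves the nonlinear enthalpy balance
  H(T) + Δt·K·T = H(T_old) + Δt·F by semismooth Newton with a backtracking
  line search (the piecewise-linear nodal enthalpy makes this an
  active-set-like iteration that is robust across the latent plateau and
  conserves h_fg·C exactly). Undamped Picard variants cycle on the plateau
  and are not used.
* **Coupling** — explicit alternation: the potential problem is resolved
  each step with σ(T) from the current temperature and desiccation state.
* **Roll-off** — first crossing of 100 Ω by linear interpolation of the
  impedance trace; a configuration whose initial impedance already exceeds
  the threshold is rejected.

### Desk-scale problem sizes

Verification and sweep runs use deliberately small discretizations chosen
once for this desk-scale study: refinement level 1 (~2 500 nodes) with
Δt = 0.5 s for the transient sweeps in the test suite, level 2 with
Δt = 0.25 s for the headline reproduction script, and level 3 for pure
impedance solves. Convergence checks bound the residual discretization
error: impedance moves < 1 % between levels 2 and 3, and roll-off time
< 2 % under time-step halving at level 3.

## Synthetic data

The phantom measurement generator draws Gaussian samples around the four
reported group means/SDs (agar 322.4 ± 2.7 Ω; +NaCl 1 wt% 213.6 ± 2.4;
+NaCl 1.5 wt% 177.5 ± 4.1; +AuNPs 1 wt% 185.9 ± 6.2; n = 10), reproducible
under a fixed seed. It emulates measurement dispersion only — no drift,
electrode-placement variability or phantom-to-phantom geometry variation —
so passing tests show correct statistical plumbing, not robustness to
real-world artefacts. The sweep-grid generator enumerates the full
9 dopant settings × 3 zone sizes × 3 voltages study; the bench-experiment
summary table ships as a comparison fixture only and never feeds the
model.

## Known limitations and discrepancies

* The published phantom characterization is internally inconsistent with
  its printed geometry: with the stated dimensions and all outer
  boundaries grounded, the forward impedance at the reported
  conductivities is uniformly ~25 % below the reported measurements
  (across all four groups by the same multiplicative factor), and
  consequently inverting the measured impedances yields conductivities
  ~25 % below the reported ones. The solver itself is verified to 0.03 %
  against the closed-form concentric-shell resistance. The checks against
  the measured phantom values are therefore expected to fail at their 5 %
  tolerance, while round-trip inversion, ordering and monotonicity checks
  all pass. The tissue-model impedances are unaffected (reproduced within
  3–5 %).
* With the default cooling wall the coupled runs reproduce roll-off times
  within ~2–22 % but over-predict lesion diameters by 25–50 % (see the
  cooling discussion above); the corresponding reproduction checks at
  15 % tolerance fail for three of six quantities and are left failing
  deliberately.
* Dopant distribution is an idealized uniform sphere; no saline
  rehydration of desiccated tissue, no perfusion, no pulsed or
  impedance-controlled protocols, and no 3D or frequency-dependent
  effects.
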