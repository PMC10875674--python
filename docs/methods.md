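# Methods

## Scope and model

`xylokin` models the earliest stages of gas-phase β-D-xylopyranose
pyrolysis with two reversible mass-action networks built entirely from
tabulated inputs: per-species standard thermochemistry (Δ_f H° and S°
at 298.15 K, C_p on a 300–1500 K grid) and per-reaction Arrhenius
parameters fitted over 300–1000 K. Model 1 contains the ten parallel
initial channels of the pyranose ring (ring opening to open-chain
xylose; two ring contractions to dihydroxytetrahydrofuran-carbaldehyde
isomers; seven site-specific dehydrations to anhydroxylopyranose
isomers). Model 2 contains ring opening plus the four consumption
channels of open-chain xylose (dehydration, cyclization to
xylofuranose, retro-aldol C–C fission, isomerization to xylulose).
All forward steps are unimolecular; every reaction is reversible.

Assumptions: ideal gas, high-pressure-limit kinetics, thermostatted
reactor (temperature is prescribed, never solved from an energy
balance), all species in the gas phase including the sugars, and
first-order mass action with thermodynamically consistent reverse
rates. Pressure-dependent falloff, transport, condensed-phase physics
and secondary chemistry beyond the tabulated reactions are out of
scope.

## Thermochemistry

NASA-7 polynomials are fitted per species: the quartic C_p/R is an
unweighted least squares over the seven grid points, and the a₆/a₇
coefficients are then fixed so H(298.15 K) and S(298.15 K) reproduce
the tabulated anchors exactly. A genuinely independent high-range
polynomial is not identifiable from seven C_p points (the high range
would be underdetermined once continuity is imposed), so one
coefficient set serves both ranges of the two-range convention
(t_low = 298.15 K, t_mid = 1000 K, t_high = 2000 K); continuity at
t_mid is then exact by construction. The C_p grid ends at 1500 K, so
evaluation beyond it is polynomial extrapolation and warns; the
packaged simulations never exceed 1100 K. Maximum C_p fit residuals
are below 0.6 J/mol/K across the 46-species set.

The standard-state pressure is 1 atm (101325 Pa), matching the
convention of the tabulated data; equilibrium constants follow as
K_p = exp(−Δ_r G°/RT) and K_c = K_p (p°/RT)^Δn in mol/m³ units.
Internal cross-checks: the ring-opening reaction gives
Δ_r H°(298.15) = 18.30 kJ/mol and Δ_r G°(673.15) = 11.5 kJ/mol from
the fitted polynomials versus 12.1 kJ/mol from the direct quantum
thermochemistry the tables were reduced from — the ~0.6 kJ/mol gap is
the C_p-integration path difference; the AXP₁ dehydration gives
Δ_r G°(673.15) = −51.05 versus −51.1 kJ/mol tabulated.

The stoichiometric formula of ADX (anhydroxylopyranose from the
xylofuranose route) is printed as C5H4O4 in the source table but must
be C5H8O4 to balance B1 → ADX + H2O; the fixture retains the printed
value beside the corrected one and the loader applies the correction
by default. ADX appears in no packaged reaction, so simulations are
unaffected.

## Formation enthalpies by atomization

Δ_f H°(M, 298.15 K) = Σ n_X Δ_f H°(X) − Δ_at H°(M) with atomic
references H = 217.998, C = 716.881, O = 249.229 kJ/mol. The
spin–orbit correction 0.35 n_C + 0.93 n_O kJ/mol is *subtracted*
(corrected values are more negative). The per-atom constants are used
exactly as printed even though the tabulated corrected-minus-
uncorrected differences imply slightly finer underlying values
(±0.03 kJ/mol per row). Benchmark statistics are MUE = mean |v−r| and
RMSD = sqrt(mean (v−r)²); RMSD ≥ MUE always.

## TST rate constants

k(T) = κ(T)·(m‡/m)·(σ/σ‡)·(k_BT/h)·(Z‡/Z)·exp(−E₀/RT), with E₀ the
ZPE-inclusive barrier, Z the RRHO partition functions (translation per
unit volume, rigid rotor without the symmetry number — the σ ratio is
an explicit factor with an override hook — and ZPE-referenced harmonic
oscillators), and harmonic frequencies and the ZPE scaled by 0.970.
Enantiomer numbers default to 1.

κ(T) is the asymmetric 1-D Eckart transmission coefficient: the
Boltzmann average of the analytic transmission probability normalized
by the classical step function, which includes nonclassical reflection
(κ can dip toward 1 from above at high T). The quadrature is adaptive
(scipy QUADPACK) in reduced energy u = E/k_BT from max(0, V₁−V₂)/k_BT
to u(V₁) + max(50, 10·hcν̃/k_BT), split at the barrier top, relative
tolerance 1e−8; the transmission probability is evaluated in log space
(cosh/sinh arguments reach several hundred for these barriers). The
implementation was validated to machine precision against an
independent direct-formula quadrature, approaches 1 as ν̃ → 0 or
T → ∞, and matches the Wigner estimate 1 + (hcν̃/k_BT)²/24 within 15%
in the mild-tunneling regime (≲ 3 quanta); in deep tunneling (e.g.
1000 cm⁻¹ at 300 K) the truncated Wigner expansion underestimates κ
substantially, as expected.

Quasi-harmonic entropies use Grimme's damping
w(ν̃) = 1/(1 + (ν̃₀/ν̃)⁴) with ν̃₀ = 100 cm⁻¹ to interpolate each
mode between harmonic-oscillator and free-rotor entropy (free-rotor
moment capped with B_av = 10⁻⁴⁴ kg·m²). They serve thermochemistry
only; the rate expression stays purely RRHO, mirroring the split in
the workflow the tables come from. Arrhenius fits are ordinary least
squares of ln k on 1/T (variance-stabilizing for multiplicative
noise), by default on the 29-point grid 300–1000 K in 25 K steps; the
reported RSS is ln-space. The RSS column of the source table is kept
for provenance but is not comparable (its definition/units are
unstated there).

## Reactor and reverse rates

The state vector is species moles n_i plus per-reaction extents ξ_j,
integrated with LSODA at rtol = 1e−8, atol = 1e−20:
dn_i/dt = V Σ_j ν_ij r_j, dξ_j/dt = V r_j, with
r_j = k_f Π C^ν(react) − k_r Π C^ν(prod) and V = (Σn_i)RT/P recomputed
continuously. Integrating moles (not fractions) makes element
conservation a direct check (observed drift < 1e−14 relative), and
co-integrating extents gives solver-accurate integrated fluxes.
Reverse coefficients are evaluated pointwise as k_r(T) = k_f(T)/K_c(T)
at every right-hand-side call — exact detailed balance is prioritized
over the speed of a refit at this problem size (≤ 12 species).

Output points are log-spaced in time for isothermal runs (resolving
the fast initial transient) and 1 K-spaced for ramps. Ramps default to
20 K/min — the rate attached to the published temperature-programmed
profiles — with 30 K/min (stated in the same source's methods text)
available as a parameter; ramp runs start at 400 K, where
decomposition is negligible, and end at 1100 K. The TGA onset is the
first temperature at which the parent's consumed fraction crosses a
threshold, linearly interpolated; a never-reached threshold returns
NaN with a warning.

With the packaged ring-opening parameters (A = 2.53·10¹² s⁻¹,
E_a = 181.8 kJ/mol), 1% consumption on a 20 K/min ramp occurs near
592 K; the published account places the visible onset near 670 K,
which with these parameters corresponds to tens of percent conversion.
The package reports what the rate parameters imply.

## Flux analysis and branching

Net extents ξ_j at the end of a run apportion consumption at a species
node: each channel's net flux in the node-consuming direction (reverse
direction for reactions that produce the node), floored at zero,
normalized over channels. Fractions are non-negative and sum to 1.

The endpoint matters and is a parameter:

* *Initial competition* (model 1): the published "nearly 99% ring
  opening" describes the kinetically controlled branching of the
  parent. Because ring opening is reversible and mildly endergonic
  (K_p ≈ 0.2 at 773 K) while the dehydrations are slow but strongly
  exergonic, net fluxes at long times are equilibrium-dominated and no
  longer reflect that competition. The package therefore uses a
  10%-conversion endpoint for this analysis; the result (R1 share
  99.998% at 773.15 K) is insensitive to the choice anywhere inside
  the kinetic window (roughly < 90 s at 773 K).
* *Xylose repartition* (model 2): integrated to 99% parent conversion
  (≈ 3.6 s at 773.15 K), C–C fission carries 99.7% of net xylose
  consumption, isomerization 0.25%, cyclization 0.04%, and the
  reverse ring opening zero net flux. The published flux diagram
  instead annotates 57/11/4/26% for these channels; those values are
  not reachable from the packaged rate and thermochemical tables under
  any endpoint or gross/net convention we examined (the 26% return
  flux alone would need K_c for ring opening ~60× smaller than the
  tabulated thermochemistry gives), and they also sit oddly against
  the same source's isothermal profiles, which show all products
  except the fission pair orders of magnitude down. The package
  reports the self-consistent numbers its inputs imply.

DOT export writes one edge per consuming channel with percentage
labels, deterministically ordered.

## Synthetic data

Generators (all deterministic under a seed, via numpy's PCG64):
random NASA-7 species with monotonically increasing C_p in
20–500 J/mol/K built by integrating a non-negative cubic (so the
fitter can be checked by round trip); Arrhenius samples with optional
log-normal noise exp(ε), ε ~ N(0, σ_ln); and toy networks (A→B, A⇌B,
A→B→C) with flat C_p and shared formulas so Δ_r C_p = 0, making the
fabricated K_p temperature-independent and the textbook closed forms
exact in the constant-pressure reactor. These emulate clean,
noise-free kinetics; they do not emulate model-form error (missing
reactions, falloff, surface chemistry), so passing toy tests validates
the numerics, not the chemistry, of real systems.

## Known limitations

* Thermochemistry is only as good as the seven-point C_p grids; no
  statistical-mechanics C_p(T) is computed.
* The Eckart correction is 1-D; multidimensional tunneling,
  variational TST and hindered-rotor partition functions are not
  implemented.
* The mechanisms stop at the first/second decomposition generation;
  furfural and the other terminal products of the full cascade are
  present in the thermochemistry table but not in the kinetic models.
* Published flux-diagram branching percentages for the xylose node are
  not reproduced by the packaged inputs (see above); users comparing
  against that diagram should be aware the discrepancy lies in the
  inputs' internal consistency, not the integrator.
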