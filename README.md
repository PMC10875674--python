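# xylokin

Thermokinetic analysis of β-D-xylopyranose fast pyrolysis.

Hemicellulose is one of the three major components of lignocellulosic
biomass, and β-D-xylopyranose (the pyranose ring form of the pentose
sugar xylose) is a standard model monomer for its essential chemical
structure. Under fast-pyrolysis conditions the ring opens to acyclic
D-xylose, which then partitions among dehydration, cyclization,
retro-aldol C–C fission and isomerization channels that lead to key
bio-oil compounds (furfural, glycolaldehyde, anhydroxylopyranose,
dihydrofuranone). `xylokin` packages the gas-phase thermochemistry and
high-pressure-limit rate parameters of this system as machine-readable
fixtures and provides the full modeling chain on top of them, for
researchers building or auditing kinetic models of biomass pyrolysis.

## What the package computes

* **Species thermochemistry** — NASA-7 polynomials fitted to tabulated
  Δ_f H°(298.15 K), S°(298.15 K) and C_p(300–1500 K) for the 46-species
  set, with exact anchors: C_p/R = a₁ + a₂T + a₃T² + a₄T³ + a₅T⁴ and
  the standard H(T), S(T) closed forms. Reaction quantities follow as
  ΔX = Σν·X and K_p = exp(−Δ_r G°/RT), K_c = K_p·(p°/RT)^Δn (p° = 1 atm).
* **Formation enthalpies by atomization** — Δ_f H°(M) = Σn_X·Δ_f H°(X) −
  Δ_at H°(M) with ATcT atomic references and per-atom spin–orbit
  corrections (0.35 kJ/mol per C, 0.93 per O), plus MUE/RMSD benchmark
  statistics.
* **TST rate constants** — k(T) = κ(T)·(m‡/m)·(σ/σ‡)·(k_BT/h)·(Z‡/Z)·
  exp(−E₀/RT) with RRHO partition functions (frequencies and ZPE scaled
  by 0.970), the asymmetric 1-D Eckart transmission coefficient κ(T)
  (tunneling and nonclassical reflection), Grimme-damped quasi-harmonic
  entropies for thermochemistry, and Arrhenius fitting/evaluation
  (ln k vs 1/T).
* **Kinetic models** — the two published reversible mechanisms: R1–R10
  (initial xylopyranose decomposition: ring opening, two ring
  contractions, seven dehydrations) and R1 + R11–R14 (subsequent xylose
  chemistry). Reverse rate coefficients are evaluated pointwise as
  k_r = k_f/K_c, so detailed balance is exact at every temperature.
* **0-D reactor** — constant-pressure ideal-gas batch reactor with
  prescribed temperature (isothermal, or a linear ramp emulating a TGA
  experiment), stiff-integrated on species moles with per-reaction
  extents co-integrated.
* **Flux analysis** — net integrated reaction fluxes, per-node branching
  ratios, and DOT flux-diagram export.

## Worked example

The formation-enthalpy benchmark (kJ/mol) from the packaged table:

```
$ xylokin hf-bench
comparison                       n     MUE    RMSD
uncorrected vs ATcT              6    6.35    7.50
SO-corrected vs ATcT             6    5.10    6.19
uncorrected vs SO-corrected     46    4.50    4.74
```

The first two rows compare the atomization-based enthalpies of the six
species with Active Thermochemical Tables references (H2O, ethenol,
acetaldehyde, CO, formaldehyde, glycolaldehyde) before and after the
spin–orbit correction — the correction buys ~1.2 kJ/mol of accuracy for
free. The last row is the size of the correction itself over all 46
species.

Branching at the xylose node of the second kinetic model, from an
isothermal 773.15 K, 1 atm run started from pure xylopyranose and
integrated to 99% conversion:

```
$ xylokin flux --model model2 -T 773.15
branching at node 'xylose' (773.15 K, endpoint 99% xylopyranose conversion):
  R1      0.000 %
  R11     0.000 %
  R12     0.042 %
  R13    99.712 %
  R14     0.246 %
```

With these rate parameters the retro-aldol C–C fission (R13, to
glycolaldehyde-enol + glyceraldehyde) is both the fastest xylose sink
(k ≈ 990 s⁻¹ at 773 K) and a deep thermodynamic sink (K_c ≈ 3·10⁴
mol/m³), so it carries nearly all of the net flux; the cyclization (R12)
and isomerization (R14) products re-equilibrate with xylose, and the
reverse ring opening carries no *net* flux. See `docs/methods.md` for
how this relates to the published flux diagram.

Library use mirrors the CLI:

```python
>>> import xylokin as xk
>>> poly = xk.fit_nasa7(xk.load_species_table()["xylopyranose"])
>>> poly.cp(673.15), poly.h(673.15), poly.s(673.15)
(301.04, -791.22, 589.57)   # J/mol/K, kJ/mol, J/mol/K
```

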