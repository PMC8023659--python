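# chelafix

Force-field evaluation and additive correction of ATP·Mg²⁺ coordination
free energies.

## The problem

The bioactive form of ATP is its magnesium chelate. In solution two
chelation geometries dominate: bidentate **C2** coordination (Mg²⁺ bound
by β- and γ-phosphate oxygens) and tridentate **C3** (α, β and γ). They
are nearly isoenergetic but separated by a high electrostatic barrier, so
unbiased molecular dynamics essentially never samples transitions — and
popular force fields disagree *qualitatively* about which mode is
favoured. `chelafix` implements the full analysis chain used to quantify
and correct this bias:

1. **Structure mining** — extract ATP·Mg²⁺ instances from PDB files,
   apply the selection rules (no second divalent cation within 8 Å; Mg²⁺
   within 3 Å of a phosphate oxygen) and classify each instance into the
   seven coordination permutations over {α, β, γ}.
2. **PCA landscapes** — superpose the six-atom Mg–triphosphate tail
   (Pα, O3α, Pβ, O3β, Pγ, Mg²⁺), fit a coordinate PCA, and build density
   maps and free-energy surfaces F = −kT ln ρ over the leading
   eigenvector projections and over the α–β–γ phosphate angle.
3. **Alchemy** — construct the reduced-charge intermediate
   (Mg⁺⁰·⁵ with the removed +1.5 e spread uniformly over the 13
   triphosphate atoms), flat-bottom coordination restraints, and a
   λ-schedule spaced to equalize neighbour phase-space overlap.
4. **MBAR** — solve the multistate Bennett acceptance ratio equations

   f_i = −ln Σₙ exp(−u_in) / Σₖ Nₖ exp(f_k − u_kn)

   over all extended-ensemble states, reweight samples into the native
   ensemble, compose thermodynamic cycles, and attach moving-block
   bootstrap uncertainties.
5. **Correction** — fit the additive offset that, added to every computed
   ΔG(C3→C2) of a set of protein·ATP complexes, maximizes agreement of the
   sign rule (ΔG + offset > 0 ⇒ C3) with the crystallographically observed
   modes; apply it to solution free energies and to ensemble weights
   (C2 frames, defined by Mg–Pα > 3.75 Å, reweighted by exp(−offset/kT)).

Because running microseconds of MD is out of reach on a desktop, the
package ships a first-class synthetic layer: idealized ATP·Mg²⁺ structures
for every coordination mode, a surrogate extended-ensemble sampler with
Hamiltonian replica exchange and an *exact* quadrature oracle for every
state free energy, and ΔG-vs-label datasets with known injected bias.

## Worked example

```python
import numpy as np
from chelafix import (SurrogateSpec, default_state_chain,
                      sample_surrogate_ensemble, solve_mbar,
                      free_energy_difference, generate_deltaG_dataset,
                      fit_offset, corrected_solution_dg)

# 21 lambda states + restrained C2/C3 native end states, replica exchange
spec = SurrogateSpec()
archive = sample_surrogate_ensemble(spec, default_state_chain(spec),
                                    n_per_state=2000, seed=1)
result = solve_mbar(archive.matrix())
dg = free_energy_difference(result, "C3@0.0000", "C2@0.0000", kT=0.59616)
print(f"surrogate dG(C3->C2) = {dg:+.2f} kcal/mol")

# offset correction on a 30-complex dataset with +6.1 kcal/mol bias
records, _ = generate_deltaG_dataset(30, true_bias=6.1, seed=1)
fit = fit_offset(records)
print(f"fitted offset = {fit.mean_offset:+.2f} kcal/mol "
      f"({fit.n_correct}/{fit.n_total} modes correct)")
print(f"corrected dG  = {corrected_solution_dg(6.4, fit.mean_offset):+.2f}")
```

Output:

```
surrogate dG(C3->C2) = -0.03 kcal/mol
fitted offset = -6.18 kcal/mol (30/30 modes correct)
corrected dG  = +0.22
```

The surrogate's two wells are symmetric by construction, so the exact
ΔG(C3→C2) is 0; the estimate above deviates by sampling noise only (the
test suite checks it against the exact quadrature value within three
bootstrap standard errors). The fitted offset recovers the injected
−6.1 kcal/mol bias, and all 30 synthetic binding modes are predicted
correctly after correction.

A full pipeline run (`simulate → mbar → landscape → correct → report`)
is one call:

```sh
chelafix run --config demo.yml     # or: run_pipeline(demo_config("out"))
```

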