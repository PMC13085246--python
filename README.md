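# corehole2

Second-order core-level ionization potentials: perturbative **CVS-IP-CIS(D)**
and iterative **CVS-IP-ADC(2)** with density fitting, spin-opposite scaling
and double-hybrid second-order corrections, on top of a pluggable SCF /
integral backend — verified end to end against a dense spin-orbital
brute-force oracle.

## The problem

X-ray photoelectron spectroscopy measures core binding energies — the energy
to remove an electron from a deep 1s (K-edge) orbital, hundreds of eV for C,
N, O, F. Koopmans' theorem (`ω = −ε_K`) misses orbital relaxation and
correlation by many eV, while coupled-cluster treatments are expensive for
application-sized molecules. Second-order methods hit a sweet spot, *if* the
core-level problem is made tractable by the **core-valence separation
(CVS)**: couplings between core-hole and valence-hole configurations are
neglected a priori, so the equations are solved entirely within the small
active-core subspace.

## The methods

With active-core orbitals `I, K`, inactive occupied `i, j, k`, virtuals
`a, b`, and density-fitted integrals
`(pq|rs) = Σ_P J_pq^P J_rs^P`, `J^P = Σ_Q I^Q (V^-1/2)_QP`:

* **IP-CIS:** `ω_K = −ε_K` (for Hartree–Fock *and* Kohn–Sham references —
  XC contributions enter only through the reference orbitals).
* **CVS-IP-CIS(D):** a non-iterative second-order correction

  ```
  ω_K^(D) = Σ_Ija V_{I,ja}^K (2c_{I,ja} − c_{Ia,j})
          + Σ_Ija V_{Ia,j}^K (2c_{Ia,j} − c_{I,ja})
  V_{I,ja}^K = −Σ_Q J_IK^Q J_ja^Q ,   V_{Ia,j}^K = −Σ_Q J_Ia^Q J_jK^Q
  c = V / (ε_I + ε_j − ε_a + ω),  evaluated once at ω = −ε_K
  ```

  equal to the diagonal, frequency-independent second-order self-energy at
  the Koopmans pole (the ΔMP2 view).
* **CVS-IP-ADC(2):** the same contraction folded into an ω-dependent
  effective Jacobian `A(ω) c = ω c`, diagonalized self-consistently; the
  doubles denominators use the ionization energy of the current iteration.
* **Spin scaling:** every second-order term splits into opposite-spin
  (`Σ V·c`) and same-spin (`Σ V·(c − c′)`) channels scaled by `(c_os, c_ss)`:
  `(1, 1)` plain, `(1.3, 0)` SOS, or a double-hybrid functional's
  correlation-mixing coefficients from a user-editable registry.

No array with two virtual indices is ever built, so the memory footprint is
`O(n_aux · n_occ · max(n_occ, n_virt))` and the rate-determining contraction
scales as `N_act N_inact N_virt N_aux`.

The library never computes atomic-orbital integrals: an SCF backend adapter
(a pyscf adapter ships; any engine can be registered) or a serialized
**reference bundle** of named float64 arrays supplies orbital energies and
MO-basis DF blocks, so every algorithm runs and is tested without a
quantum-chemistry engine.

## Worked example

Generate a seeded synthetic system (1 active core near −10 Eh, 3 inactive
occupied, 3 virtuals, 4 auxiliary channels), save it as a bundle, and solve
both methods:

```
$ corehole2 fixture --sizes 1,3,3,4 --seed 5 --out syn.bundle
bundle for sizes (1, 3, 3, 4), seed 5 written to syn.bundle

$ cat job.yaml
method: adc2
scaling: sos
bundle: syn.bundle
output: report.json

$ corehole2 run job.yaml
method: adc2   scaling: c_os=1.3 c_ss=0 (SOS)
reference: HF
 orb       eps/Eh     omega/Eh   omega/eV   corr/eV  iter  conv
   0    -9.938999     9.934819     270.34     -0.11     3   yes
full-precision report written to report.json
```

Reading the table: orbital 0 is the active core with ε = −9.938999 Eh; its
Koopmans ionization energy would be 9.938999 Eh, and the self-consistent
SOS-scaled second-order fold-in lowers it by 0.11 eV to ω = 9.934819 Eh
(270.34 eV), converged in 3 macro iterations. The same bundle run with
`method: cis-d` gives the one-shot perturbative value instead.

In Python, the same computation is three calls:

```python
from corehole2 import generate_fixture, resolve_scaling, solve_adc2

system = generate_fixture((1, 3, 3, 4), seed=5)
states = solve_adc2(system.reference(), system.partition(), system.df,
                    resolve_scaling("sos"))
print(states[0].omega, states[0].omega_ev)   # 9.934819... Eh, 270.34... eV
```

Benchmark tables (molecule, element, computed_eV, reference_eV) are
summarized with `corehole2 stats table.csv --separations`, which prints
ME/MAE/SD/RMSE/MAX/span plus the same-element peak-separation analysis
(MRE, MARE, SD of relative errors).

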