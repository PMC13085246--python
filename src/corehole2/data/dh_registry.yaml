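# Double-hybrid functional registry.
#
# Each entry resolves a `dh:<name>` method tag into the spin-resolved
# second-order correlation mixing coefficients applied to the perturbative
# or iterative ionization correction, plus the reference-functional settings
# (exchange mixing, base functional) forwarded to the SCF backend when the
# KS reference is built.  Coefficients are transcribed from the cited
# primary sources; edit or extend freely.
#
# Fields:
#   c_os             opposite-spin second-order coefficient (dimensionless)
#   c_ss             same-spin second-order coefficient (dimensionless)
#   exchange_mixing  fraction of exact exchange in the reference functional
#   base_functional  semilocal functional underlying the hybrid
#   citation         provenance of the transcribed numbers

B2PLYP:
  c_os: 0.27
  c_ss: 0.27
  exchange_mixing: 0.53
  base_functional: BLYP
  citation: "Grimme, J. Chem. Phys. 124, 034108 (2006): a_c = 0.27, a_x = 0.53"

PBE0-2:
  c_os: 0.5
  c_ss: 0.5
  exchange_mixing: 0.7937005259840998
  base_functional: PBE
  citation: "Chai & Mao, Chem. Phys. Lett. 538, 121 (2012): c_PT2 = 1/2, c_x = 2^(1/3)/2"

SOS0-PBE0-2:
  c_os: 0.65
  c_ss: 0.0
  exchange_mixing: 0.7937005259840998
  base_functional: PBE
  citation: >-
    SOS0 variant of PBE0-2: opposite-spin-only second order with the PBE0-2
    mixing 1/2 scaled by the standard SOS factor 1.3 (c_os = 0.65); entry
    derived from the SOS0 convention, adjust against the primary source if a
    different opposite-spin coefficient is preferred.
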