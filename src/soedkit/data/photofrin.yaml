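# Bundled Photofrin photophysical parameter sets.
#
# Units: epsilon cm^-1 uM^-1; wavelength nm; beta, delta, A in uM; sigma uM^-1;
# xi cm^2 mW^-1 s^-1; lifetimes in s; k6 s^-1; k7 uM^-1 s^-1; k2 uM^-1 s^-1;
# g uM/s.
#
# The singlet-oxygen lifetime stored in each kinetic set is the directly
# measured value at [A] = 0.  The azide-titration rate constants (k6, k7) are
# kept in a separate record because the measured tau_Delta (9.4 us) and the
# titration intercept 1/k6 (8.77 us) disagree by ~7% — both are experimental
# results and the package does not silently reconcile them.  tau_R = 1/k6 is
# stored explicitly where the luminescence model needs it.

parameter_sets:
  in_vitro_632:
    # Water/Intralipid phantom, 632 nm CW excitation.
    epsilon: 0.0035
    wavelength: 632.0
    Phi_Delta: 0.56
    beta: 11.9
    delta: 25.0
    sigma: 6.6e-5
    xi: 10.3e-3
    tau_Delta: 9.4e-6
    tau_t: 0.43e-6
    tau_R: 8.7719298245614e-6   # 1/k6, k6 = 1.14e5 s^-1
    k2: 1.3e4
    A: 0.0

  in_vitro_523_meoh:
    # MeOH solution, 523 nm pulsed excitation (luminescence experiments).
    epsilon: 0.0089
    wavelength: 523.0
    Phi_Delta: 0.64
    beta: 11.9
    delta: 25.0
    sigma: 6.6e-5
    xi: 24.8e-3
    tau_Delta: 9.4e-6
    tau_t: 0.43e-6
    tau_R: 8.7719298245614e-6
    k2: 1.3e4
    A: 0.0

  in_vivo_632:
    # Tissue, 632 nm CW treatment light.
    epsilon: 0.0035
    wavelength: 632.0
    Phi_Delta: 0.20
    beta: 11.9
    delta: 33.0
    sigma: 7.6e-5
    xi: 3.7e-3
    tau_Delta: 1.6e-7
    tau_t: 1.5e-6
    tau_R: 8.7719298245614e-6
    k2: 1.3e4
    g: 0.7

  in_vivo_523:
    # Tissue, 523 nm pulsed light; xi is the literature 632 nm value scaled
    # by the extinction-coefficient ratio (stored as printed: 8.99e-3, even
    # though 3.7e-3 * 0.0089/0.0035 = 9.41e-3 — the discrepancy is flagged
    # in the docs, not resolved).
    epsilon: 0.0089
    wavelength: 523.0
    Phi_Delta: 0.20
    beta: 11.9
    delta: 33.0
    sigma: 7.6e-5
    xi: 8.99e-3
    tau_Delta: 1.6e-7
    tau_t: 1.5e-6
    tau_R: 8.7719298245614e-6
    k2: 1.3e4
    g: 0.7

azide_titration:
  # Linear fit of 1/tau_Delta vs azide concentration for Photofrin in MeOH.
  k6: 1.14e5     # s^-1 (intercept)
  k7: 235.0      # uM^-1 s^-1 (slope)
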