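# Default comparison scenario: 1.4-cm spherical tumor in a 9-cm soft-tissue
# head phantom, treated at a shallow and a deep position.
range_model:
  alpha: 0.0022        # cm / MeV^p, water
  p: 1.77
  density: 1.1         # g/cm^3, soft tissue
tumor:
  radius: 0.71         # cm
  volume: 1.5          # cm^3
  density: 1.1         # g/cm^3
phantom:
  radius: 9.0
  density: 1.1
  mass_fractions: {C: 0.20, H: 0.10, O: 0.65, N: 0.05}
cases:
  - name: shallow
    depth_interval: [1.6, 3.0]
  - name: deep
    depth_interval: [10.0, 11.3]
n_peaks: 12
calibration: mcnpx-like   # or geant4-like
ppm_list: [100, 1000]
proton_baseline:
  edep_mev_per_g: 14.0   # per proton, in-tumor
  flux: 0.5              # protons / cm^2 s
  cf_mrem_h: 2.5         # mrem/h per unit proton flux, E < 60 MeV
  q: 1.45
  w_f: 5.0
physics:
  pbft_e_dep_mev: 8.67   # three-alpha channel, per reaction
  ncept_e_dep_mev: 2.3   # alpha (1.5) + Li-7 (0.8), per capture
  quality_heavy: 20.0
cross_section_fixture: b11_p_3alpha.tsv
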