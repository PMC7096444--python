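# ICRP Publication 21 (1973) neutron flux-to-dose-rate conversion factors,
# standard tabulation as distributed with general-purpose transport codes.
# columns: E_MeV	CF_mrem_h_per_unit_flux
2.5e-8	3.67e-3
1.0e-7	3.67e-3
1.0e-6	4.46e-3
1.0e-5	4.54e-3
1.0e-4	4.18e-3
1.0e-3	3.76e-3
1.0e-2	3.56e-3
1.0e-1	2.17e-2
5.0e-1	9.26e-2
1.0	1.32e-1
2.5	1.25e-1
5.0	1.56e-1
7.0	1.47e-1
10.0	1.47e-1
14.0	2.08e-1
20.0	2.27e-1
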