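# borondose

Analytic, desk-scale comparison of two boron-based dose-enhancement schemes
in proton therapy:

- **fusion channel** — proton capture on boron-11 releasing three alpha
  particles (folded against a tabulated cross-section over 0.6–40 MeV);
- **neutron-capture channel** — capture of secondary thermal neutrons on
  boron-10 (folded against a 1/v cross-section law).

Monte Carlo particle transport is replaced by calibrated synthetic
generators: a Bragg–Kleeman range-energy law with an analytic spread-out
Bragg peak, a track-length estimate of the in-tumor proton slowing-down
spectrum, and a three-group (thermal / epithermal / fast) secondary-neutron
field pinned to reference group fluxes at two depths.  Everything is
deterministic — spectra and dose rates are pure functions of their
configuration.

## Layout

| module | contents |
| --- | --- |
| `borondose.grids` | energy grids (uniform and logarithmic), binned spectra, TSV I/O |
| `borondose.spectra` | range-energy model, SOBP designer, proton/neutron spectrum generators |
| `borondose.xs` | cross-section tables, 1/v capture law, group collapse |
| `borondose.rates` | tumor/phantom specs, boron inventories, the folding engine, percent-increase statistic |
| `borondose.dosimetry` | excess equivalent dose, proton baseline chains, ICRP-21 neutron group doses, capture-competition estimator |
| `borondose.pipeline` | scenario configuration (YAML), comparison driver, report emission |
| `borondose.cli` | `borondose` command-line interface |
| `borondose/data/` | packaged fixtures: fusion cross-section table, ICRP-21 conversion factors, default scenario |

## CLI

```sh
# synthetic proton + neutron spectra for every scenario case (TSV)
borondose spectra --out spectra_out

# fold a spectrum against a cross-section table (prints mb cm^-2 s^-1)
borondose fold --spectrum spectra_out/proton_shallow.tsv --xs b11.tsv

# excess equivalent dose rate from a reaction-rate channel (EGy/s)
borondose dose --rate 1.09e-6 --edep 2.3

# full comparison: baselines, both excess channels, out-of-field neutron doses
borondose compare --config myscenario.yaml --out comparison_out
```

Without `--config` the packaged default scenario is used (shallow 1.6–3 cm
and deep 10–11.3 cm cases, 100 and 1000 ppm loadings, MCNPX-like neutron
calibration).  `compare` writes per-case JSON/CSV dose reports plus
`comparison_summary.csv` with one row per depth × loading and columns
`case, depth_hi_cm, ppm, proton_gy_s_edep, proton_sv_s_icrp,
proton_gy_s_icrp, pbft_excess_egy_s, ncept_excess_egy_s,
neutron_{thermal,epithermal,fast}_sv_s, boron_capture_fraction`.

## Conventions worth knowing

- Spectra store per-bin (width-integrated) fluxes; the folding sum is a
  plain discrete sum of per-bin flux × cross-section with no extra
  bin-width factor.
- Cross-section tables are lin-lin interpolated and return zero outside
  their validity range (with a warning above it).
- The MeV→J constant is the rounded 1.6e-13 so published arithmetic
  reproduces digit for digit; ICRP factors are mrem/h per unit flux,
  converted with 1 mrem/h = 1e-5 Sv / 3600 s.
- The percent-increase statistic is defined relative to the deeper
  (larger) rate.
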