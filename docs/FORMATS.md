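# File formats

All tabular data are plain CSV with mandatory headers; binary and vendor
formats are out of scope. JSON results carry `schema_version` (currently 1).

## Trace CSV

Two-channel binned photon counts, written by `io.write_trace` /
`fccs-kin simulate`:

```
time_s,green_counts,red_counts
0.0,3,12
0.001,1,9
...
```

A metadata sidecar `<file>.csv.meta.json` records `bin_width_s`,
`duration_s`, `seed` and a full echo of the simulation configuration
(geometry, species, realized particle numbers, time step). `io.read_trace`
reconstructs the bin width from the sidecar, or from the time column when
the sidecar is absent.

## Correlation-curve CSV

```
lag_s,G,G_err
2e-05,1.92,0.05
...
```

`G_err` is NaN when no per-lag errors were estimated. The sidecar stores
the curve kind (`auto_green`, `auto_red`, `cross`) and estimator settings
(`estimator`, `m`, `levels`, `n_segments`).

## CCP tables

| kind       | required columns | optional       |
|------------|------------------|----------------|
| timecourse | `t_s, ccp`       | `L_conc_M`, `ccp_err` |
| titration  | `L_conc_M, ccp`  | `ccp_err`      |
| decay      | `t_s, ccp`       | `ccp_err`      |

Readers reject files with missing required columns, naming the column.

## Fit-result JSON

`io.fit_result_to_json` serialises either a correlation fit
(`type: CorrFitResult`: G0, tau_D, s, errors, covariance, flags) or a
kinetic fit (`type: KineticResults`: model name, equation, params, bse,
covariance, nobs, ssr, converged, flags).

## Affinity record JSON (`fccs-kin analyze --out`)

```json
{
 "ligand": "L^DNA", "pore": "NP-O^DNA",
 "Kd_M": 1.44e-09, "Kd_err": 9.1e-11,
 "kon_M1s1": 2.7e5, "kon_err": 1.8e-11,
 "koff_s1": 3.9e-4, "koff_err": 2.5e-5,
 "provenance": {"Kd": "fitted", "k_on": "fitted", "k_off": "derived-via-closure"},
 "schema_version": 1
}
```

## Experiment config YAML

Blocks `geometry`, `species` (list of NP / L / NP.L), `kinetics`,
`simulation`. Every quantity field carries a unit suffix, converted to SI
on load; unknown suffixes are rejected with an error naming the field.

```yaml
geometry: {w_xy_nm: 250, w_z_um: 1.25, f_ov: 0.6}
species:
  - {name: NP,   c_nM: 1.3, D_um2_per_s: 11,  q_red_kcps: 300}
  - {name: L,    c_nM: 0.5, D_um2_per_s: 100, q_green_cps: 3e4}
  - {name: NP.L, c_nM: 0.0, D_um2_per_s: 11,  q_green_cps: 3e4, q_red_kcps: 300}
kinetics: {k_on_per_M_per_s: 2.7e5, k_off_per_s: 3.9e-4}
simulation: {duration_s: 50, bin_width_ms: 0.02}
```

Recognised suffixes: concentrations `M, mM, uM, nM, pM`; times
`s, ms, us, min, h`; lengths `m, um, nm`; diffusion `m2_per_s,
um2_per_s`; rates `per_s, per_M_per_s`; brightness `cps, kcps`.
Unit-free fields: `name, label, seed, f_ov, s, n_red_labels, ...`.
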