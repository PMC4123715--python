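# File formats

## Sweep table (`*.tsv`)

One file per sweep. Leading metadata lines, then a tab-separated table:

```
# channel = shaker_like
# seed = 0
# protocol = gv_step_-20mV
# leak_nS = 0.05
# noise_sd_pA = 0.5
# v_rev_mV = 0.0
# n_channels = 1000
# gamma_ref_pS = 10.0
# gamma_q10 = 1.5
time_s	voltage_mV	current_pA	temperature_C
0	-100	-4.8369	24
0.0005	-100	-5.1126	24
...
```

Rules enforced by the reader (violations raise a parse error naming the
file and line): all four columns present; `time_s` strictly increasing;
metadata lines of the form `# key = value` (typed per a known-key table,
otherwise int/float/str inferred). Writers emit 12 significant digits, so
a write→read round trip preserves series to better than 1e−9 relative and
metadata exactly. Families are written as numbered files
(`sweep_000.tsv`, …) plus an `index.tsv` listing sweep number, step
voltage and filename, and a `manifest.json`.

## Channel config (`*.yaml`)

```yaml
channel_name: shaker_like
kind: allosteric            # or: two_state
units: {energy: J/mol, entropy: "J/(mol*K)"}
J: {dH: 88000.0, dS: 373.8033223724, z: 5.1}   # omit for two_state
L: {dH: 418000.0, dS: 1340.0, z: 0.0}
D: 1.0e4                                        # omit for two_state
csi: {v_half: -60.0, q: 3.2}                    # optional
n_channels: 1000
gamma_ref: 10.0             # pS at 22 °C
gamma_q10: 1.5
ion_in: [K, 130.0]          # species, mM
ion_out: [K, 130.0]
```

- `units.energy`: `J/mol`, `kJ/mol` or `kcal/mol`; `units.entropy`:
  `J/(mol*K)`, `kJ/(mol*K)` or `cal/(mol*K)` (`·` also accepted).
- Any scalar may instead carry an inline tag: `dH: "100 kcal/mol"`.
- Unknown keys, unknown unit tags, negative D, and missing required keys
  (`channel_name`, `kind`, `L`; plus `J`/`D` for `allosteric`) are errors.

## Protocol config (`*.yaml`)

```yaml
name: heat_minus60
sample_interval_ms: 10.0
temperature: [24.0, 0.3]    # start °C, rate °C/s — or a constant: 24.0
segments:
  - {kind: hold, v_start: -100, v_end: -100, duration_ms: 500}
  - {kind: hold, v_start: -60,  v_end: -60,  duration_ms: 80000}
```

Segment kinds: `hold`, `step` (both constant-voltage), `ramp` (linear
from `v_start` to `v_end`). Durations are positive; `hold`/`step` require
`v_start == v_end`.

## Results tables

Tab-separated with units in the header row (e.g. `v_half_mV`, `q_e0`,
`dH_kJ_per_mol`), one row per fit or measurement; free-text context lines
prefixed with `#`. Every generating run writes a `manifest.json` with the
config hash, seeds, file inventory, package version and timestamp.
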