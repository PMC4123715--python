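# Heat-gated TRP-like channel: a single enthalpy-driven pore transition with
# weak voltage dependence, used standalone as a two-state model.
channel_name: trpv1_like
kind: two_state
units: {energy: J/mol, entropy: "J/(mol*K)"}
L: {dH: 510000.0, dS: 1580.0, z: 0.76}
n_channels: 1000
gamma_ref: 10.0
gamma_q10: 1.5
ion_in: [Na, 130.0]
ion_out: [Na, 130.0]
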