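# Strongly coupled Kv channel: steep voltage-sensor transition (z = 5.1 e0)
# obligatorily coupled (D = 1e4) to an enthalpy-rich pore opening.
# J.dS is set so the fitted G-V half-activation voltage is -54.2 mV at 24 C.
channel_name: shaker_like
kind: allosteric
units: {energy: J/mol, entropy: "J/(mol*K)"}
J: {dH: 88000.0, dS: 373.8033223724, z: 5.1}
L: {dH: 418000.0, dS: 1340.0, z: 0.0}
D: 1.0e4
n_channels: 1000
gamma_ref: 10.0
gamma_q10: 1.5
ion_in: [K, 130.0]
ion_out: [K, 130.0]
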