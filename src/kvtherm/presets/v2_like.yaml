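# Heat-deactivated variant: the pore transition of ilt_like with both
# enthalpy and entropy sign-flipped, so heating closes the open pore.
channel_name: v2_like
kind: allosteric
units: {energy: J/mol, entropy: "J/(mol*K)"}
J: {dH: 88000.0, dS: 328.1618983733, z: 5.1}
L: {dH: -418000.0, dS: -1340.0, z: 0.0}
D: 5.0
n_channels: 1000
gamma_ref: 10.0
gamma_q10: 1.5
ion_in: [K, 130.0]
ion_out: [K, 130.0]
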