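# Named parameter presets: maximal-conductance overrides (nS) applied to
# the standard cell.  Each preset encodes the parameterization used by one
# of the reference reproductions shipped with the package (rheobase /
# strength-duration, f-I, impalement phase diagram, adaptation knockouts,
# notch / sag / rebound experiments).
standard: {}
fig3b: {M: 20.0, A: 15.0}
fig3c: {}
fig4: {M: 30.0, KCa: 70.0, A: 80.0, leak: 2.0}
fig5: {leak: 0.5}
fig6: {Na: 400.0, Kd: 3000.0, CaL: 1.2, M: 40.0, KCa: 60.0, A: 80.0, H: 1.0, leak: 2.0}
fig8a: {M: 10.0, KCa: 10.0, A: 90.0, leak: 0.0}
fig8b: {A: 5.0, leak: 0.1}
fig8c: {Na: 200.0, Kd: 2000.0, CaL: 1.2, M: 20.0, KCa: 20.0, A: 20.0, H: 1.0, leak: 2.0}
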