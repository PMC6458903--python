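# Alpha-tuned prior parameterization of the six-node CMC network
# (log-scaling deviations; node order lV1, rV1, lSPL, rSPL, lMFG, rMFG;
#  tau order: superficial pyramidal, interneuron, stellate, deep pyramidal).
tau:
- 2.17
- 2.94
- 3.81
- 0.66
g1:
- -0.39
- -0.05
- -0.33
- 0.18
- -0.14
- -0.03
g2:
- -0.33
- 0.22
- 0.84
- 0.73
- 0.42
- -0.08
g3:
- -0.05
- -0.05
- -0.23
- -0.54
- -0.31
- -1.67
s: -0.63
a_fwd:
- 0.0
- 0.0
- 0.0
- 0.0
a_bwd:
- 0.0
- 0.0
- 0.0
- 0.0
a_lat:
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
noise_alpha_u: 0.0
noise_beta_u: 0.0
noise_alpha_n: 0.0
noise_beta_n: 0.0
L:
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
- 0.0
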