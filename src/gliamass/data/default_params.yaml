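# Reference parameter values of the neuron-astrocyte mass model.
# Flat symbol names; units noted inline.
params:
  # neural compartment
  A: 3.25       # mV, average excitatory synaptic gain
  B: 22.0       # mV, average inhibitory synaptic gain
  a: 100.0      # 1/s, reciprocal excitatory PSP time constant
  b: 50.0       # 1/s, reciprocal inhibitory PSP time constant
  e0: 2.5       # 1/s, half the maximum discharge rate
  v0: 6.0       # mV, basic excitability threshold
  r: 0.56       # 1/mV, sigmoid stiffness
  C1: 135.0     # P  -> P' connectivity
  C2: 108.0     # P' -> P  connectivity
  C3: 33.75     # P  -> I  connectivity
  C4: 33.75     # I  -> P  connectivity
  G: 40.0       # direct P -> P feedback gain
  # glial compartment
  W: 53.6       # µM/s, glutamate release-flux amplitude
  Z: 53.6       # µM/s, GABA release-flux amplitude
  w1: 90.0      # 1/s
  w2: 33.0      # 1/s
  z1: 90.0      # 1/s
  z2: 33.0      # 1/s
  VG_ne: 0.5    # µM/s, neuronal glutamate uptake
  VG_ae: 4.5    # µM/s, astrocytic glutamate uptake
  s_g: 6.0      # µM, glutamate-uptake threshold
  r_g: 0.9      # 1/µM, glutamate-uptake stiffness
  Vgamma_ae: 2.0   # µM/s, astrocytic GABA uptake
  Kgamma_ae: 8.0   # µM
  Vgamma_ne: 5.0   # µM/s, neuronal GABA uptake
  Kgamma_ne: 24.0  # µM
  VG_c: 9.0     # 1/s, astrocytic glutamate degradation
  Vgamma_c: 9.0 # 1/s, astrocytic GABA degradation
  # astrocytic feedback
  v_G: 30.0     # µM, glutamate feedback threshold
  r_G: 0.15     # 1/µM
  mG_P: 2.5     # mV, glutamate feedback gain on P
  mG_I: 1.0     # mV, glutamate feedback gain on I
  v_gamma: 25.0 # µM, GABA feedback threshold
  r_gamma: 0.12 # 1/µM
  m_gamma: 1.0  # mV, GABA feedback gain on P
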