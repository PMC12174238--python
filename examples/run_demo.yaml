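# Demo workflow config: a glass-microsphere unilobar case with a 5% lung
# shunt, Poisson count noise, and default SPECT/PET blur.  Run with:
#   voxdose90 run --config examples/run_demo.yaml --out scratch/demo
seed: 1
phantom:
  true_TN: 3.75
  perfused_fraction: 0.625
  net_activity_GBq: 2.35
  lung_shunt_true: 0.05
  device: glass
noise: poisson
counts_per_GBq: 1.0e6
disease: metastasis
lung_mass_kg: 1.0
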