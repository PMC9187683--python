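# Demo: synthetic 6 MeV electron-beam measurement, full analysis chain.
#   cherenkov-polarimetry run --config examples/demo_6mev.yaml --out scratch/demo
beam: 6MeV
seed: 1
scenario:
  n_frames: 5
  n_background_frames: 5
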