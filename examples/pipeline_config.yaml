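# Example pipeline configuration.
# Generate matching input files first:  meioflow simulate --out-dir samples --seed 1
experiment_id: demo
gate_variant: quality_rfp_gfp      # or rfp_gfp_only
output_dir: demo_out
seed: 1

samples:                           # FCS or per-event CSV; roles drive the fit
  - {path: samples/sim-l1.csv, role: control_zero}   # pure background, s = 0
  - {path: samples/sim-l2.csv, role: pure_one}       # pure RFP cells, s = 1
  - {path: samples/sim-l3.csv, role: unknown}        # spiked, s estimated
  - {path: samples/sim-l4.csv, role: unknown}
  - {path: samples/sim-l5.csv, role: unknown}

# Every threshold defaults to the published values and is overridable per
# channel (cuts must be re-determined for each cytometer).
threshold_overrides:
  fluorescence:
    # FITC.A: [560, 10000]
    # PE.CF594.A: [1000, 10000]
  quality:
    # SSC.H: [450, 3500]

# channel_aliases:                 # merged over the built-in dash->dot map
#   "FL2-A": "PE.CF594.A"

optimizer: {n_starts: 10, seed: 1}

# Optional: paired detected-RFP proportions for the recovery regression
# comparison:
#   path: paired_detections.csv    # columns: label, reference, thresholding
#   percent: true
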