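# Full demonstration run: simulated aging cohorts at the scale of the
# training/testing cohorts the pipeline is designed for (600 train, 550
# test), default C grid, KSG k=3. Run with:
#   brainage-mi run --config demo.yaml
out_dir: run
simulate: true
n_train: 600
n_test: 550
c_grid: [0.1, 1.0, 10.0, 100.0]
epsilon: 0.1
bias_mode: out_of_fold
k: 3
uncorrected_mi: true
combine_volumes: false
run_subgroup: true
seed: 20
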