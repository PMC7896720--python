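# Demo pipeline run: synthetic temporal pair with undersplit loci plus
# a diverged control pair, filtered through the four-dataset cascade.
# Run with:  radqc run-all --config configs/demo.yaml --seed 1
out_dir: results/demo_run
seed: 1
geno_sim:
  n_pops: 4
  n_per_pop: 40
  n_loci: 2000
  target_fst: [0.0, 0.0, 0.04, 0.04]
  frac_undersplit: 0.04
  undersplit_pops: [0]
  undersplit_latent_freq_range: [0.35, 0.95]
filter_steps: []
fis_pair: [POP1, POP2]
run_four_datasets: true
run_pca: true
run_exact_tests: true
fst_distribution_pairs:
  - [POP1, POP2]
  - [POP3, POP4]
fst_subsample_n: 30
make_plots: true
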