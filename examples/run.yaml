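# Scaled-down demonstration run; a production analysis would use
# n_iterations: 120000, burn_in: 20000, thin: 10 on the full data.
output_dir: demo_run
seed: 9
simulation:
  n_founder_sires: 25
  n_generations: 2
  daughters_per_sire: 8
  n_herds: 10
  n_year_seasons: 3
  n_chromosomes: 3
  markers_per_chromosome: 40
  n_qtl: 15
gibbs:
  n_iterations: 1500
  burn_in: 400
  thin: 2
reweight_rounds: 4
window_size: 10
n_top_windows: 10
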