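# A small end-to-end run: simulate a WT baseline and three mutant replicates,
# then trim, map, profile, and compare. All analysis constants are defaulted
# (2 adapter mismatches, 23-30 nt inserts, 500 RPM filter, 0.6/1.6 RE bands).
out_dir: run_out
baseline: wt
seed: 1
simulate:
  n_transposons: 20
  length_range: [500, 1500]
  genome_length: 80000
  seed: 1
  libraries:
    - {id: wt,  preset: wt-ovary, seed: 11, n_pirna_reads: 20000, n_background_reads: 2000, n_junk_reads: 200}
    - {id: kg1, preset: kg-ovary, seed: 21, n_pirna_reads: 20000, n_background_reads: 2000, n_junk_reads: 200,
       reduced_ids: [TE001, TE002, TE003]}
    - {id: kg2, preset: kg-ovary, seed: 22, n_pirna_reads: 20000, n_background_reads: 2000, n_junk_reads: 200,
       reduced_ids: [TE001, TE002, TE003]}
    - {id: kg3, preset: kg-ovary, seed: 23, n_pirna_reads: 20000, n_background_reads: 2000, n_junk_reads: 200,
       reduced_ids: [TE001, TE002, TE003]}
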