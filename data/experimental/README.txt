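Experimental datasets for the In(3LR) inversion analyses
=========================================================

This directory is where the published experimental tables are expected by
the full reanalysis (they are not bundled here):

  in3lr_165_counts.tsv, in3lr_190_counts.tsv, in3lr_269_counts.tsv,
  control_counts.tsv
      Recombination pattern-count tables in the pattern TSV format (header
      row of marker names ve..ca, then one row per binary pattern over the
      7 intervals with its offspring count).

  chr3_inversion_sterility.tsv
      Sterility table for the 30 chromosome-3 inversions with columns
      inversion_id, I_morgans, rho, observed_sterility.

With these files in place, the same fits run via the command line, e.g.:

  perinv compare --data data/experimental/in3lr_190_counts.tsv \
      --layout data/layouts/in3lr_190.yaml --restarts 100 --seed 1 --out results/190

Without them, synthetic datasets with the same geometry and parameter
regime can be generated with `perinv simulate` or perinv.scenarios.
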