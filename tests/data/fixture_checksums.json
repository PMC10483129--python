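{
  "sha256": "9174e55830973107b65700b77c83ef5474ab23d6f3de134a275805cd26c12aa8",
  "shape": [
    600,
    50
  ],
  "n_cells": 600,
  "n_components": 3,
  "latent_dim": 2,
  "n_genes": 50,
  "seed": 0,
  "zero_fraction": 0.587367,
  "total_counts": 985656
}
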