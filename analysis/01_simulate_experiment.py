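#!/usr/bin/env python
"""Generate the synthetic starvation experiment used by the later steps.

Writes the fixture TSVs (counts, annotation, sample metadata, ground truth)
under scratch/fixture/ — they are bulky intermediates; every later step can
also regenerate them from the seed.  Prints the basic shape of the dataset.
"""

from pathlib import Path

from spikeseq import SynthConfig, simulate_experiment, write_fixture

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "scratch" / "fixture"


def main() -> None:
    config = SynthConfig()
    matrix, truth = simulate_experiment(config, seed=SEED)
    paths = write_fixture(OUT, matrix, truth)
    print(f"simulated experiment (seed {SEED}):")
    print(f"  genes: {len(matrix.chromosomal_genes)} chromosomal "
          f"+ {len(matrix.plasmid_features)} spike-in features")
    print(f"  samples: {list(matrix.sample_ids)}")
    depths = truth.sample_truth["depth"]
    print(f"  depths: {depths.min():,} - {depths.max():,} reads")
    steady = matrix.steady_samples
    rrna = matrix.annotation["rna_class"].str.startswith("rRNA")
    share = (
        matrix.counts.loc[rrna, steady].sum().sum()
        / matrix.counts.loc[matrix.chromosomal_genes, steady].sum().sum()
    )
    print(f"  rRNA read share at steady state: {share:.3f}")
    print("wrote:", ", ".join(str(p) for p in paths.values()))


if __name__ == "__main__":
    main()
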