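"""Generate the synthetic study inputs every downstream analysis consumes.

Emulates the study's data layout: a chromatophore proteome with a
spectral-count table over yellow/red/brown samples (loading distorted by
the factors 1/2.2/1.8), layer-thickness measurement lists (cytoplasm
116 ± 102 nm, n = 292; membrane 71 ± 14 nm, n = 237), a pH-titration
absorbance series over pH 1.9–8.9, and an expanding-disc movie whose fill
color follows the thin-film model.  Ground truth is written next to every
dataset.
"""

import argparse
from pathlib import Path

import numpy as np

from chromatophore import io as cio
from chromatophore.synthetic import (
    MovieConfig,
    make_count_table,
    make_layer_measurements,
    make_movie,
    make_proteome,
    make_titration_series,
)

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int = 1, out: Path = ROOT / "results" / "synthetic") -> None:
    out.mkdir(parents=True, exist_ok=True)

    proteome = make_proteome(50, seed=seed)
    cio.write_fasta(proteome, out / "proteome.fasta")

    rng = np.random.default_rng(seed)
    abundance = rng.dirichlet(np.ones(len(proteome)))
    table, truth = make_count_table(
        proteome,
        abundance,
        depths={"yellow": 10_000, "red": 10_000, "brown": 10_000},
        loading_multipliers={"yellow": 1.0, "red": 2.2, "brown": 1.8},
        seed=seed,
    )
    table.to_csv(out / "counts.csv")
    np.savetxt(out / "true_abundance.txt", truth["abundances"])

    cyto = make_layer_measurements(116.0, 102.0, n=292, seed=seed)
    memb = make_layer_measurements(71.0, 14.0, n=237, seed=seed + 1)
    np.savetxt(out / "cytoplasm_layers_nm.txt", cyto, fmt="%.2f")
    np.savetxt(out / "membrane_layers_nm.txt", memb, fmt="%.2f")

    series = make_titration_series(pk=5.0, a_acid=0.15, a_base=1.0,
                                   n_points=30, noise_sd=0.017, seed=seed)
    np.savetxt(out / "titration.csv",
               np.column_stack([series.ph, series.absorbance]),
               delimiter=",", header="pH,absorbance_430nm", comments="")

    stack, colors = make_movie(MovieConfig(seed=seed, n_frames=20,
                                           max_areal_expansion=1.6,
                                           noise_sd=2.0))
    np.save(out / "movie_frames.npy", stack.frames)
    np.savetxt(out / "movie_true_colors.csv", colors, delimiter=",")

    print(f"synthetic inputs written to {out}")
    print(f"  proteome: {len(proteome)} proteins")
    print(f"  counts:   totals {table.sum(axis=0).to_dict()}")
    print(f"  layers:   cytoplasm mean {cyto.mean():.1f} nm, "
          f"membrane mean {memb.mean():.1f} nm")
    print(f"  movie:    {stack.frames.shape[0]} frames")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    main(seed=args.seed)
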