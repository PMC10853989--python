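#!/usr/bin/env python
"""Exploratory 2-D latent manifolds, one per ROI mask.

Fits a bottleneck-2 autoencoder to each mask's standardized block using
ALL samples (exploratory mode — not the leakage-guarded CV path) and
writes class-colored scatter plots with axes clipped to [-15, 15].
GBM and MET should form separable clouds; LYM typically does not.
"""
import argparse
from pathlib import Path

import numpy as np

from radlatent._seeds import derive_seed
from radlatent.cohort import read_cohort
from radlatent.latent import TrainConfig, manifold_2d
from radlatent.pipeline import _exploratory_blocks
from radlatent.preprocessing import ImputationStrategy


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--cohort", type=Path,
                        default=Path("results/analysis/cohort"))
    parser.add_argument("--max-epochs", type=int, default=150)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path,
                        default=Path("results/analysis/manifolds"))
    args = parser.parse_args()

    cohort = read_cohort(args.cohort)
    blocks = _exploratory_blocks(cohort, ImputationStrategy("mean"))
    args.out.mkdir(parents=True, exist_ok=True)
    for mi, mask in enumerate(cohort.masks):
        res = manifold_2d(
            blocks[mask],
            TrainConfig(max_epochs=args.max_epochs,
                        seed=derive_seed(args.seed, "manifold", mi)),
            labels=cohort.labels,
            out_png=str(args.out / f"manifold_{mask}.png"),
            out_csv=str(args.out / f"manifold_{mask}.csv"),
            title=f"{mask} (exploratory fit on all data)")
        gap = np.linalg.norm(
            res.coords[cohort.labels == "GBM"].mean(axis=0)
            - res.coords[cohort.labels == "MET"].mean(axis=0))
        print(f"{mask}: GBM-MET centroid gap in 2-D latent space = {gap:.2f}")
    print(f"wrote manifolds to {args.out}")


if __name__ == "__main__":
    main()
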