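#!/usr/bin/env python
"""Fermentation statistics: normalised titres, control comparisons, trends.

Normalises protein to dry weight and organic acids to depleted glucose,
runs pairwise pooled-variance t-tests of every mutant x dose cell against
the MA70.15 progenitor, and fits the protein-vs-acid trend curves over
strain x dose means (degree 2 for citric acid, linear for oxaloacetate).
"""

import argparse
from pathlib import Path

from mycoscreen import pipeline


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/titres"))
    parser.add_argument("--control", default="MA70.15")
    parser.add_argument("--alpha", type=float, default=0.05)
    args = parser.parse_args()

    config = pipeline.PipelineConfig(
        out_dir=str(args.out),
        fermentation_path=str(args.data / "fermentation.csv"),
        control_strain=args.control,
        alpha=args.alpha,
    )
    _normalized, comparisons, trends = pipeline.run_titres(config)

    n_sig = int(comparisons["significant"].sum())
    print(
        f"{len(comparisons)} mutant-vs-{args.control} t-tests "
        f"(no multiplicity correction), {n_sig} significant at alpha {args.alpha}"
    )
    starred = comparisons[comparisons["significant"]]
    for (strain, dose), group in starred.groupby(["strain", "dox_ug_ml"]):
        variables = ", ".join(
            v.split("_per_")[0].replace("_mg", "").replace("_g", "")
            for v in group["variable"]
        )
        print(f"  {strain} at {dose} ug/ml Dox: {variables}")
    for row in trends.itertuples(index=False):
        print(f"{row.pair}: degree {row.degree}, R^2 = {row.r_squared:.2f}")


if __name__ == "__main__":
    main()
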