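#!/usr/bin/env python
"""Multi-query co-expression screen: which genes track all six queries?

Builds the Spearman network (cutoff 0.5) around the six TCA/Golgi query
genes, intersects their neighbourhoods, and scores the intersection against
the planted ground truth from step 01. Writes the intersection gene list,
per-gene query support and the evaluated edges to results/screen/.
"""

import argparse
from pathlib import Path

from mycoscreen import pipeline


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/screen"))
    parser.add_argument("--cutoff", type=float, default=0.5)
    args = parser.parse_args()

    config = pipeline.PipelineConfig(
        out_dir=str(args.out),
        matrix_path=str(args.data / "expression.tsv"),
        annotations_path=str(args.data / "annotations.tsv"),
        spearman_cutoff=args.cutoff,
    )
    result, _ = pipeline.run_screen(config)
    print(
        f"{result.intersection_size} genes co-expressed with all "
        f"{len(result.query_genes)} queries at cutoff {args.cutoff}"
    )
    for query, neighbours in sorted(result.per_query_neighbors.items()):
        print(f"  {query}: {len(neighbours)} neighbours")

    truth_path = args.data / "nexus_truth.txt"
    if truth_path.exists():
        planted = set(truth_path.read_text().split())
        recovered = result.intersection & planted
        contamination = result.intersection - planted
        print(
            f"planted-module recovery: {len(recovered)}/{len(planted)} "
            f"({100 * len(recovered) / len(planted):.1f}%), "
            f"{len(contamination)} non-planted gene(s) in the intersection"
        )


if __name__ == "__main__":
    main()
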