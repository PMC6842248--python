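#!/usr/bin/env python
"""GO over-representation of the screen's intersection gene list.

Tests every GO term hit by the candidate list against the annotated-genome
background (hypergeometric upper tail, Benjamini-Hochberg FDR) and reports
terms at q <= 0.05. With the step-01 inputs the planted TCA-cycle and Golgi
vesicle terms should dominate the report.
"""

import argparse
from pathlib import Path

from mycoscreen import enrichment


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--screen", type=Path, default=Path("results/screen"))
    parser.add_argument("--out", type=Path, default=Path("results/enrichment"))
    parser.add_argument("--q", type=float, default=0.05)
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    candidates = set(
        (args.screen / "intersection_genes.txt").read_text().split()
    )
    annotations = enrichment.AnnotationSet.from_tsv(args.data / "annotations.tsv")
    results = enrichment.enrich(candidates, annotations, q_threshold=args.q)
    table = enrichment.results_table(results)
    table.to_csv(args.out / "enrichment.csv", index=False)

    reported = table[table["reported"]]
    print(
        f"{len(candidates)} candidates against {annotations.n_universe} annotated "
        f"genes: {len(table)} terms tested, {len(reported)} at q <= {args.q}"
    )
    for row in reported.head(10).itertuples(index=False):
        print(
            f"  {row.term_id}: {row.k}/{row.n} candidates vs {row.K}/{row.N} "
            f"genome, p = {row.p_value:.3g}, q = {row.q_value:.3g}"
        )


if __name__ == "__main__":
    main()
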