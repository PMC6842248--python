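#!/usr/bin/env python
"""Generate the synthetic study inputs every later analysis step consumes.

Writes to results/data/: an expression compendium (1050 genes x 155
cultivation conditions, one planted 50-gene TCA/Golgi nexus module), a flat
gene->GO annotation table with the module's terms planted, three binary
culture images with ground-truth shape tables and a strain/dose manifest,
and a shake-flask fermentation table following the study's qualitative
dose-response pattern.
"""

import argparse
from pathlib import Path

import imageio.v3 as iio
import pandas as pd

from mycoscreen import synthetic


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=Path("results/data"))
    args = parser.parse_args()
    out = args.out
    out.mkdir(parents=True, exist_ok=True)

    matrix, annotations, module, queries = synthetic.nexus_screen_scenario(args.seed)
    matrix.to_tsv(out / "expression.tsv")
    annotations.to_csv(out / "annotations.tsv", sep="\t", header=False, index=False)
    (out / "nexus_truth.txt").write_text(
        "\n".join(sorted(set(module.member_genes) - set(queries))) + "\n"
    )
    print(
        f"expression: {matrix.n_genes} genes x {matrix.n_conditions} conditions, "
        f"planted module of {len(module.member_genes)} genes "
        f"(queries {', '.join(queries)})"
    )

    image_dir = out / "images"
    image_dir.mkdir(exist_ok=True)
    manifest_rows = []
    strains = [synthetic.CONTROL_STRAIN, "TC4.4", "TC5.5"]
    for i in range(3):
        spec = synthetic.example_image_spec(seed=args.seed + i)
        image, truth = synthetic.render_culture_image(spec)
        name = f"culture_{i + 1:02d}.png"
        iio.imwrite(image_dir / name, image)
        truth.to_csv(image_dir / f"culture_{i + 1:02d}_truth.csv", index=False)
        manifest_rows.append(
            {
                "file": name,
                "strain": strains[i],
                "dox_ug_ml": synthetic.DEFAULT_DOX_LEVELS[i],
                "pixel_size_um": spec.pixel_size_um,
            }
        )
        print(f"{name}: {len(truth)} objects ({truth['size_class'].value_counts().to_dict()})")
    pd.DataFrame(manifest_rows).to_csv(out / "image_manifest.csv", index=False)

    table = synthetic.generate_fermentation_table(
        synthetic.example_dose_response_spec(seed=args.seed)
    )
    table.to_csv(out / "fermentation.csv", index=False)
    print(
        f"fermentation: {len(table)} rows, strains "
        f"{sorted(table['strain'].unique())}, doses {sorted(table['dox_ug_ml'].unique())}"
    )


if __name__ == "__main__":
    main()
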