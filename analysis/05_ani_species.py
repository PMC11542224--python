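"""Pairwise ANI/AF and species assignment at the ANI>=95%, AF>=60% rule."""

from pathlib import Path

import pandas as pd

from erosym.pipeline import load_dataset
from erosym.relatedness import all_pairs_ani, species_clusters

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    for name in ("independent", "codiversification"):
        data = load_dataset(RESULTS / "datasets" / name)
        res = all_pairs_ani(data.genomes)
        pd.DataFrame(
            [
                {
                    "genome_a": r.genome_a, "genome_b": r.genome_b,
                    "ani": round(r.ani, 3), "af": round(r.af, 2),
                }
                for r in res
            ]
        ).to_csv(RESULTS / f"ani_{name}.tsv", sep="\t", index=False)
        species = species_clusters(
            res, genome_ids=sorted(g.genome_id for g in data.genomes)
        )
        pd.DataFrame(
            sorted(species.items()), columns=["genome_id", "species_id"]
        ).to_csv(RESULTS / f"species_{name}.tsv", sep="\t", index=False)
        n_sym_species = len(
            {s for g, s in species.items() if g.startswith("sym_")}
        )
        print(
            f"[{name}] {len(set(species.values()))} species among "
            f"{len(species)} genomes; symbionts split into {n_sym_species} species"
        )


if __name__ == "__main__":
    main()
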