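#!/usr/bin/env python
"""Generate the synthetic study: NF / NT / Setd2OE ChIP tracks across four
developmental stages plus replicated expression counts, with the planted
truth tables used by every later step.

Writes gene models, counts, truth, and the config under results/data/.
"""

import dataclasses
from pathlib import Path

from ntchrom import io
from ntchrom.pipeline import dump_summary
from ntchrom.simulate import SimulationConfig, simulate_expression, simulate_genome, simulate_tracks

OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main(seed: int = 0) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=seed)
    genome, genes, truth = simulate_genome(cfg)
    tracks = simulate_tracks(cfg, truth)
    counts = simulate_expression(cfg, truth)

    io.write_gene_models(genes, OUT / "gene_models.tsv")
    counts.to_csv(OUT / "expression_counts.tsv", sep="\t")
    truth.expression.to_csv(OUT / "truth_genes.tsv", sep="\t")
    for (cond, stage), m in truth.marks.items():
        m.to_csv(OUT / f"truth_marks_{cond}_{stage}.tsv", sep="\t")
    dump_summary(dataclasses.asdict(cfg), OUT / "config.json")

    n_cat = (truth.expression["category"] != "none").sum()
    print(f"simulated {len(genes)} genes on {genome.total_length / 1e6:.0f} Mb, "
          f"{len(tracks)} ChIP tracks, {counts.shape[1]} expression samples")
    counts_by_cat = {k: int(v) for k, v in truth.expression["category"].value_counts().items()}
    print(f"planted {n_cat} category genes ({counts_by_cat})")


if __name__ == "__main__":
    main()
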