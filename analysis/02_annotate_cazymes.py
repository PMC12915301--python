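#!/usr/bin/env python
"""Annotate CAZyme genes: families, EC numbers and substrates.

Runs domain-hit filtering/overlap resolution, the four-rule EC cascade and
substrate matching on the simulated community, compares against the
generator's ground truth, and writes per-rule and per-substrate summaries
to results/.
"""

from collections import Counter
from pathlib import Path

import pandas as pd

from cazymeta.pipeline import run_study
from cazymeta.simulate import generate, scenario_estuary
from cazymeta.substrates import substrate_census

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    study = generate(scenario_estuary(SEED, n_genomes_per_habitat=25, noise_free=True))
    result = run_study(study)
    ledger = study.ledger
    truth = ledger.cazyme_gene_ids()
    fam_ok = sum(1 for g in truth if result.annotations.get(g) and result.annotations[g].families == ledger.genes[g].families)
    ec_ok = sum(1 for g in truth if result.annotations.get(g) and result.annotations[g].ec_numbers == ledger.genes[g].ec_numbers)
    sources = Counter(a.ec_source.value for a in result.annotations.values())
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    pd.DataFrame(
        [{"ec_source": k, "n_genes": v} for k, v in sorted(sources.items())]
    ).to_csv(out / "ec_sources.tsv", sep="\t", index=False)
    census = substrate_census(result.annotations, study.gene_genome, study.genome_habitat)
    census.to_csv(out / "substrate_census.tsv", sep="\t", index=False)
    print(f"{len(result.annotations)} CAZyme genes annotated "
          f"({100 * fam_ok / len(truth):.1f}% family agreement with planted truth, "
          f"{100 * ec_ok / len(truth):.1f}% EC agreement)")
    print("EC evidence routes:", dict(sources))
    print(f"substrate census covers {census['substrate'].nunique()} categories; "
          "tables in results/ec_sources.tsv and results/substrate_census.tsv")


if __name__ == "__main__":
    main()
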