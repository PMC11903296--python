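#!/usr/bin/env python
"""Generate the synthetic study inputs used by the downstream analyses.

Produces, with fixed seeds: a 2,000-protein synthetic proteome (FASTA), a
DIA-style quant report for the three HeLa:yeast mix compositions, and a
two-cell-type single-cell dataset (21 hPS-like + 12 TE-like cells + 3
blanks). Bulky raw artifacts go to scratch/data/; a compact description of
what was generated is written to results/simulation_summary.json.
"""

import json
from pathlib import Path

from scpbench.io import write_fasta, write_quant_report, melt_matrix, QuantReport
from scpbench.simulate import (
    HELA_YEAST_MIXES,
    simulate_cells,
    simulate_mix,
    simulate_proteome,
)

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "data"
RESULTS = ROOT / "results"
SEED = 20240901


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    RESULTS.mkdir(exist_ok=True)

    proteome = simulate_proteome(2000, seed=SEED)
    write_fasta(proteome, DATA / "target_proteome.fasta")

    mix_report, mix_truth = simulate_mix(
        HELA_YEAST_MIXES, {"human": 1500, "yeast": 500}, n_replicates=3, seed=SEED
    )
    write_quant_report(mix_report, DATA / "mix_report.tsv")
    mix_truth.to_json(DATA / "mix_truth.json")

    cells, annotation, cell_truth = simulate_cells(
        {"hPS": 21, "TE": 12}, n_proteins=1500, n_de_proteins=75,
        effect_size_log2=1.0, blank_count=3, seed=SEED,
    )
    long = melt_matrix(cells)
    long["condition"] = annotation.loc[long["run_id"], "cell_type"].to_numpy()
    write_quant_report(QuantReport(long), DATA / "cells_report.tsv")
    annotation.reset_index().to_csv(DATA / "cells.tsv", sep="\t", index=False)
    cell_truth.to_json(DATA / "cells_truth.json")

    summary = {
        "seed": SEED,
        "proteome": {"n_proteins": len(proteome),
                     "n_residues": proteome.total_residues()},
        "mix": {
            "conditions": {c: m for c, m in HELA_YEAST_MIXES.conditions.items()},
            "n_report_rows": len(mix_report),
            "n_proteins": {"human": 1500, "yeast": 500},
            "n_replicates": 3,
        },
        "cells": {
            "n_cells": {"hPS": 21, "TE": 12}, "blanks": 3,
            "n_proteins": 1500, "n_de_proteins": 75, "effect_size_log2": 1.0,
        },
    }
    (RESULTS / "simulation_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(f"proteome: {len(proteome)} proteins, {proteome.total_residues():,} residues")
    print(f"mix report: {len(mix_report):,} rows across 9 runs")
    print(f"single cells: {cells.shape[0]} proteins x {cells.shape[1]} samples")
    print(f"raw data under {DATA}, summary in {RESULTS / 'simulation_summary.json'}")


if __name__ == "__main__":
    main()
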