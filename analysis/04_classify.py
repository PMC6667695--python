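"""Dependence filtering and six-group allocation.

Restricts to genes significantly LPS-upregulated >= 4-fold in wild-type,
keeps those significantly changed in at least one pairwise genotype
comparison (MK2- and/or MK2/3-dependent), and allocates each to one of the
six regulatory groups via the 20% relation triple.
"""
import json
from pathlib import Path

import pandas as pd

from mkpatterns.classify import classify_all
from mkpatterns.reporting import read_gene_matrix, read_sample_sheet, write_table

RESULTS = Path("results")


def main() -> None:
    samples = read_sample_sheet(RESULTS / "data" / "samples.tsv")
    gm = read_gene_matrix(RESULTS / "gene_matrix.tsv", samples)
    frames, summaries = [], {}
    for t in (120, 360):
        assignments, summary = classify_all(gm, t)
        frames.append(assignments)
        summaries[str(t)] = summary
        print(f"t={t} min: {summary['n_wt_upregulated']} wt-upregulated >=4-fold, "
              f"{summary['n_dependent']} MK-dependent, {summary['n_assigned']} allocated "
              f"({summary['n_unclassified']} unclassified); group %: {summary['group_percent']}")
    write_table(pd.concat(frames, ignore_index=True), RESULTS / "assignments.tsv")
    (RESULTS / "proportions.json").write_text(json.dumps(summaries, indent=2), encoding="utf-8")


if __name__ == "__main__":
    main()
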