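"""LPS-responsiveness calls and Venn partitions per genotype.

For each genotype and timepoint, tests every gene's LPS samples against the
genotype's untreated baseline (pooled-variance t-test, p < 0.05) and
partitions the responsive sets into a three-way Venn.  Also counts genes
that respond only when MK2 (or MK2 and MK3) is deleted.
"""
import json
from pathlib import Path

from mkpatterns.reporting import percent, read_gene_matrix, read_sample_sheet, write_table
from mkpatterns.responsiveness import (
    call_all,
    knockout_only_responsive,
    responsive_gene_set,
    venn_by_timepoint,
)

RESULTS = Path("results")


def main() -> None:
    samples = read_sample_sheet(RESULTS / "data" / "samples.tsv")
    gm = read_gene_matrix(RESULTS / "gene_matrix.tsv", samples)
    calls = call_all(gm)
    write_table(calls, RESULTS / "responsiveness_calls.tsv")
    venns = venn_by_timepoint(calls)
    n = len(gm.genes)
    report = {}
    for t, v in venns.items():
        sets = {
            g: responsive_gene_set(calls[(calls["time_min"] == t) & (calls["genotype"] == g)])
            for g in ("wt", "MK2KO", "MK23KO")
        }
        ko_only = knockout_only_responsive(sets["wt"], sets["MK2KO"], sets["MK23KO"])
        report[str(t)] = {**v, "knockout_only": len(ko_only)}
        print(f"t={t} min: responsive of {n} genes — "
              + ", ".join(f"{g} {v[f'{g}_total']} ({percent(v[f'{g}_total'], n)}%)"
                          for g in ("wt", "MK2KO", "MK23KO"))
              + f"; union {v['union']}; knockout-only {len(ko_only)}")
    (RESULTS / "venn.json").write_text(json.dumps(report, indent=2), encoding="utf-8")


if __name__ == "__main__":
    main()
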