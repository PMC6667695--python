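"""Probe intensities -> normalized gene matrix.

Floors raw intensities at 5, quantile-normalizes across all arrays,
restricts to known-function probes, collapses multi-probe genes to the
probe with the highest wild-type LPS induction, and expresses every gene
relative to its untreated wild-type mean.
"""
import logging
from pathlib import Path

from mkpatterns.preprocess import preprocess_pipeline
from mkpatterns.reporting import read_annotation, read_probe_matrix, read_sample_sheet, write_table

DATA = Path("results/data")


def main() -> None:
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
    matrix = read_probe_matrix(DATA / "probe_matrix.tsv")
    samples = read_sample_sheet(DATA / "samples.tsv")
    annotation = read_annotation(DATA / "annotation.tsv")
    gm = preprocess_pipeline(matrix, samples, annotation)
    write_table(gm.to_frame(), Path("results") / "gene_matrix.tsv", index=True)
    print(f"{len(matrix)} probes -> {len(gm.genes)} genes; "
          "values are ratios to the untreated wild-type mean -> results/gene_matrix.tsv")


if __name__ == "__main__":
    main()
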