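"""Generate the emulated study dataset.

Simulates the array design (3 genotypes x untreated + LPS 2 h / 6 h x 4
replicates) with 2,000 genes: 50 per regulatory group I-VI, 300
genotype-independent LPS responders, the rest unresponsive.  Writes the
probe matrix, sample sheet, annotation and ground truth under
results/data/.
"""
from pathlib import Path

from mkpatterns.reporting import write_table
from mkpatterns.simulate import SimulationConfig, generate_dataset

OUT = Path("results/data")


def main() -> None:
    config = SimulationConfig(seed=7)
    sim = generate_dataset(config)
    OUT.mkdir(parents=True, exist_ok=True)
    write_table(sim.probe_matrix.reset_index(), OUT / "probe_matrix.tsv")
    write_table(sim.samples, OUT / "samples.tsv")
    write_table(sim.annotation, OUT / "annotation.tsv")
    write_table(sim.truth, OUT / "truth.tsv")
    n_annot = int((sim.annotation["known_function"] == 1).sum())
    print(f"simulated {len(sim.probe_matrix)} probes ({n_annot} annotated to "
          f"{len(sim.truth)} genes) x {sim.probe_matrix.shape[1]} arrays -> {OUT}/")


if __name__ == "__main__":
    main()
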