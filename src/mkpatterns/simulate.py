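"""Synthetic single-channel microarray generator with planted regulatory programs.

Emulates the design of the LPS time-course study the pipeline analyzes:
three genotypes (wt, MK2KO, MK2/3-double-KO), an untreated baseline plus two
LPS timepoints (120 and 360 min), four independent replicate arrays per
condition, probes mapping 1-3 per gene with a pool of unannotated probes,
multiplicative per-array scale effects and log-normal measurement noise.

Each gene carries a regulatory program: one of the six genotype-dependence
groups (I-VI), a genotype-independent LPS response ("null_responsive"), or
no response at all.  The planted multipliers are the recovery target for the
downstream classification pipeline.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import GENOTYPES, GROUPS, validate_sample_sheet

log = logging.getLogger(__name__)

PROGRAM_GROUPS: tuple[str, ...] = GROUPS + ("null_responsive", "nonresponsive")

# Default LPS-induction multipliers (wt, MK2KO, MK23KO), applied at both
# timepoints.  Each pairwise ratio that defines a group's pattern sits well
# beyond the 20% relation threshold, so recovery failures indicate pipeline
# bugs rather than borderline effects.
DEFAULT_MULTIPLIERS: dict[str, tuple[float, float, float]] = {
    "I": (8.0, 2.0, 1.5),
    "II": (4.0, 10.0, 10.0),
    "III": (8.0, 2.0, 8.0),
    "IV": (4.0, 10.0, 4.0),
    "V": (8.0, 8.0, 2.0),
    "VI": (4.0, 4.0, 10.0),
    "null_responsive": (6.0, 6.0, 6.0),
    "nonresponsive": (1.0, 1.0, 1.0),
}


@dataclass(frozen=True)
class RegulatoryProgram:
    """Planted LPS-induction multipliers per genotype and timepoint."""

    group: str
    induction: Mapping[str, Mapping[int, float]]

    def multiplier(self, genotype: str, time_min: int) -> float:
        return self.induction[genotype][time_min]


def default_program(group: str, timepoints: tuple[int, ...] = (120, 360)) -> RegulatoryProgram:
    """The canonical program for a group, with the default multipliers at
    every LPS timepoint.

    Raises ``ValueError`` for an unknown group name.
    """
    if group not in DEFAULT_MULTIPLIERS:
        raise ValueError(f"unknown regulatory group: {group!r}")
    wt, mk2, mk23 = DEFAULT_MULTIPLIERS[group]
    induction = {
        "wt": {t: wt for t in timepoints},
        "MK2KO": {t: mk2 for t in timepoints},
        "MK23KO": {t: mk23 for t in timepoints},
    }
    return RegulatoryProgram(group=group, induction=induction)


@dataclass
class SimulationConfig:
    """Study-design and noise parameters for :func:`generate_dataset`.

    Defaults reproduce the emulated study: 2,000 genes of which 50 per
    group I-VI are genotype-dependently regulated, 300 respond to LPS
    independently of genotype, and the rest are unresponsive; 4 replicate
    arrays per condition; LPS at 120 and 360 min against a shared untreated
    baseline per genotype.
    """

    n_genes: int = 2000
    genes_per_group: dict[str, int] = field(default_factory=lambda: {g: 50 for g in GROUPS})
    n_null_responsive: int = 300
    probes_per_gene: tuple[int, int] = (1, 3)
    fraction_unannotated_probes: float = 0.3
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    probe_efficiency_sd_log2: float = 0.3
    noise_sd_log2: float = 0.15
    array_scale_sd_log2: float = 0.2
    replicates: int = 4
    timepoints: tuple[int, ...] = (120, 360)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = set(self.genes_per_group) - set(GROUPS)
        if unknown:
            raise ValueError(f"genes_per_group contains unknown groups: {sorted(unknown)}")
        if self.n_planted + self.n_null_responsive > self.n_genes:
            raise ValueError(
                f"planted counts ({self.n_planted} grouped + "
                f"{self.n_null_responsive} null-responsive) exceed n_genes={self.n_genes}"
            )
        for name in ("baseline_log2_sd", "probe_efficiency_sd_log2", "noise_sd_log2", "array_scale_sd_log2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2 (the t-test needs within-group variance)")
        if not (0 <= self.fraction_unannotated_probes < 1):
            raise ValueError("fraction_unannotated_probes must be in [0, 1)")
        lo, hi = self.probes_per_gene
        if lo < 1 or hi < lo:
            raise ValueError("probes_per_gene must be a range (lo, hi) with 1 <= lo <= hi")

    @property
    def n_planted(self) -> int:
        return sum(self.genes_per_group.get(g, 0) for g in GROUPS)

    @property
    def n_nonresponsive(self) -> int:
        return self.n_genes - self.n_planted - self.n_null_responsive


@dataclass
class SimulatedDataset:
    """The generator's output bundle: the raw probe matrix, its annotation
    and sample sheet, and the planted ground truth (one row per gene)."""

    probe_matrix: pd.DataFrame
    annotation: pd.DataFrame
    samples: pd.DataFrame
    truth: pd.DataFrame


def design_sample_sheet(replicates: int = 4, timepoints: tuple[int, ...] = (120, 360)) -> pd.DataFrame:
    """Sample sheet for the emulated design: per genotype, one shared
    untreated baseline condition plus one LPS condition per timepoint."""
    rows = []
    for genotype in GENOTYPES:
        for rep in range(1, replicates + 1):
            rows.append((f"{genotype}_untr_r{rep}", genotype, "untreated", 0, rep))
        for t in timepoints:
            for rep in range(1, replicates + 1):
                rows.append((f"{genotype}_LPS{t}_r{rep}", genotype, "LPS", t, rep))
    samples = pd.DataFrame(rows, columns=["sample_id", "genotype", "treatment", "time_min", "replicate"])
    validate_sample_sheet(samples)
    return samples


def generate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a probe-level dataset with planted regulatory programs.

    Intensity model, per probe and sample::

        intensity = baseline(gene) * induction(genotype, treatment, time)
                    * efficiency(probe) * scale(array) * 2**N(0, noise_sd_log2)

    Untreated samples use induction 1; unannotated probes carry
    baseline-only signal.  Deterministic for a fixed config (the seed is
    part of the config).
    """
    rng = np.random.default_rng(config.seed)
    samples = design_sample_sheet(config.replicates, config.timepoints)
    n_samples = len(samples)

    # gene-level assignments: grouped genes first, then null-responsive,
    # then the unresponsive remainder
    groups: list[str] = []
    for g in GROUPS:
        groups += [g] * config.genes_per_group.get(g, 0)
    groups += ["null_responsive"] * config.n_null_responsive
    groups += ["nonresponsive"] * config.n_nonresponsive
    gene_ids = [f"Gene{i:05d}" for i in range(1, config.n_genes + 1)]
    programs = {g: default_program(g, config.timepoints) for g in PROGRAM_GROUPS}

    baselines = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, config.n_genes)
    lo, hi = config.probes_per_gene
    probes_per_gene = rng.integers(lo, hi + 1, config.n_genes)
    n_annot = int(probes_per_gene.sum())
    efficiencies = 2.0 ** rng.normal(0.0, config.probe_efficiency_sd_log2, n_annot)

    f = config.fraction_unannotated_probes
    n_unannot = int(round(n_annot * f / (1.0 - f)))
    unannot_baselines = 2.0 ** rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_unannot)

    n_probes = n_annot + n_unannot
    probe_ids = [f"P{i:06d}" for i in range(1, n_probes + 1)]
    gene_of_probe = np.repeat(np.arange(config.n_genes), probes_per_gene)

    # per-sample multiplier matrix on the gene level
    mult = np.ones((config.n_genes, n_samples))
    for j, row in enumerate(samples.itertuples(index=False)):
        if row.treatment == "LPS":
            col = np.array(
                [programs[g].multiplier(row.genotype, row.time_min) for g in PROGRAM_GROUPS]
            )
            group_index = np.array([PROGRAM_GROUPS.index(g) for g in groups])
            mult[:, j] = col[group_index]

    clean = np.empty((n_probes, n_samples))
    clean[:n_annot, :] = (
        baselines[gene_of_probe, None] * mult[gene_of_probe, :] * efficiencies[:, None]
    )
    clean[n_annot:, :] = unannot_baselines[:, None]

    scales = 2.0 ** rng.normal(0.0, config.array_scale_sd_log2, n_samples)
    noise = rng.normal(0.0, config.noise_sd_log2, (n_probes, n_samples)) if config.noise_sd_log2 > 0 else 0.0
    intensities = clean * scales[None, :] * 2.0 ** noise

    probe_matrix = pd.DataFrame(intensities, index=pd.Index(probe_ids, name="probe_id"),
                                columns=samples["sample_id"].tolist())

    annotation = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "gene_symbol": [gene_ids[g] for g in gene_of_probe] + [""] * n_unannot,
            "accession": [f"NM_{i:06d}" for i in gene_of_probe + 1]
            + [f"XR_{i:06d}" for i in range(1, n_unannot + 1)],
            "known_function": [1] * n_annot + [0] * n_unannot,
        }
    )

    eff_by_gene: list[str] = []
    offset = 0
    for k in probes_per_gene:
        eff_by_gene.append(",".join(f"{e:.6g}" for e in efficiencies[offset : offset + k]))
        offset += k
    truth = pd.DataFrame(
        {
            "gene": gene_ids,
            "group": groups,
            "induction_wt": [programs[g].induction["wt"][config.timepoints[0]] for g in groups],
            "induction_MK2KO": [programs[g].induction["MK2KO"][config.timepoints[0]] for g in groups],
            "induction_MK23KO": [programs[g].induction["MK23KO"][config.timepoints[0]] for g in groups],
            "baseline": baselines,
            "n_probes": probes_per_gene,
            "probe_efficiencies": eff_by_gene,
        }
    )

    log.info(
        "simulated %d probes (%d annotated) x %d samples; %d grouped, %d null-responsive, %d unresponsive genes",
        n_probes, n_annot, n_samples, config.n_planted, config.n_null_responsive, config.n_nonresponsive,
    )
    return SimulatedDataset(probe_matrix=probe_matrix, annotation=annotation, samples=samples, truth=truth)
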