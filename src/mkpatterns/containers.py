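"""Shared containers and study-design vocabulary.

The study design is a 3-genotype (wild-type, MK2 knockout, MK2/3 double
knockout) x (untreated + LPS at 2 h and 6 h) x replicate layout of
single-channel microarrays.  Everything downstream addresses samples
through the sample sheet, so the query helpers live here.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

GENOTYPES: tuple[str, ...] = ("wt", "MK2KO", "MK23KO")
TREATMENTS: tuple[str, ...] = ("untreated", "LPS")

#: Fixed regulatory groups; exemplar gene naming follows the field's usage.
GROUPS: tuple[str, ...] = ("I", "II", "III", "IV", "V", "VI")
GROUP_EXEMPLAR: dict[str, str] = {
    "I": "Il10-type",
    "II": "Il12b-type",
    "III": "Ifnb1-type",
    "IV": "Cxcl3-type",
    "V": "Hdc-type",
    "VI": "Cxcl9-type",
}

SAMPLE_SHEET_COLUMNS = ("sample_id", "genotype", "treatment", "time_min", "replicate")


def validate_sample_sheet(samples: pd.DataFrame) -> None:
    """Check the sample sheet contract: required columns, known levels,
    unique (genotype, treatment, time_min, replicate), untreated at time 0."""
    missing = set(SAMPLE_SHEET_COLUMNS) - set(samples.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    bad_geno = set(samples["genotype"]) - set(GENOTYPES)
    if bad_geno:
        raise ValueError(f"unknown genotypes in sample sheet: {sorted(bad_geno)}")
    bad_treat = set(samples["treatment"]) - set(TREATMENTS)
    if bad_treat:
        raise ValueError(f"unknown treatments in sample sheet: {sorted(bad_treat)}")
    untreated = samples[samples["treatment"] == "untreated"]
    if (untreated["time_min"] != 0).any():
        raise ValueError("untreated samples must have time_min = 0")
    key = samples[["genotype", "treatment", "time_min", "replicate"]]
    if key.duplicated().any():
        raise ValueError("duplicate (genotype, treatment, time_min, replicate) rows")
    if samples["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids")


def select_samples(
    samples: pd.DataFrame,
    genotype: str | None = None,
    treatment: str | None = None,
    time_min: int | None = None,
) -> list[str]:
    """Sample ids matching the given design cells (None = any)."""
    mask = pd.Series(True, index=samples.index)
    if genotype is not None:
        mask &= samples["genotype"] == genotype
    if treatment is not None:
        mask &= samples["treatment"] == treatment
    if time_min is not None:
        mask &= samples["time_min"] == time_min
    return samples.loc[mask, "sample_id"].tolist()


@dataclass
class GeneMatrix:
    """Gene x sample expression table with probe provenance.

    ``values`` is indexed by gene symbol; ``probe_of_gene`` records which
    probe was chosen to represent each gene at collapse time.  After
    :func:`mkpatterns.preprocess.normalize_to_untreated_wt` the values are
    ratios to the untreated wild-type mean (that mean is 1 per gene).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    probe_of_gene: pd.Series = field(default_factory=lambda: pd.Series(dtype=object))

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("gene index contains duplicates")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def to_frame(self) -> pd.DataFrame:
        """Values with the provenance probe id as a leading column (the
        on-disk layout)."""
        out = self.values.copy()
        out.insert(0, "probe_id", self.probe_of_gene.reindex(self.values.index))
        return out
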