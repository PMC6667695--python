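"""Readers, writers, percentage/scatter computations, and the end-to-end
pipeline driver.

All tabular artifacts are UTF-8 tab-delimited text with a header row; JSON
summaries sit alongside.  ``run_pipeline`` chains
simulate -> preprocess -> responsiveness -> dependence classification ->
reports and writes a machine-readable manifest of the run.
"""
from __future__ import annotations

import json
import logging
import math
import sys
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import __version__
from .containers import GeneMatrix, validate_sample_sheet
from .classify import classify_all
from .preprocess import preprocess_pipeline
from .responsiveness import call_all, knockout_only_responsive, responsive_gene_set, venn_by_timepoint
from .simulate import SimulationConfig, generate_dataset

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# small report arithmetic

def percent(numerator: int, denominator: int) -> int:
    """Integer percentage, rounded half away from zero (the convention the
    reported gene-fraction percentages follow)."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0 or numerator > denominator:
        raise ValueError("numerator must be in [0, denominator]")
    return int(math.floor(100.0 * numerator / denominator + 0.5))


def scatter_coords(ratio_wt_vs_mk2ko: float, ratio_mk23ko_vs_mk2ko: float) -> tuple[float, float]:
    """Scatter-plot coordinates for one gene.

    x = log2(MK23KO / MK2KO expression ratio); y = -log2(wt / MK2KO ratio),
    so 0 means no difference, negative y means lower expression in MK2KO
    than wt, and positive x means higher expression in MK23KO than MK2KO.
    """
    if ratio_wt_vs_mk2ko <= 0 or ratio_mk23ko_vs_mk2ko <= 0:
        raise ValueError("ratios must be positive")
    return math.log2(ratio_mk23ko_vs_mk2ko), -math.log2(ratio_wt_vs_mk2ko)


def scatter_table(assignments: pd.DataFrame) -> pd.DataFrame:
    """Scatter coordinates for every assigned gene, from the pairwise
    relative levels in a classification table."""
    coords = [
        scatter_coords(r.level_wt_vs_MK2KO, 1.0 / r.level_MK2KO_vs_MK23KO)
        for r in assignments.itertuples(index=False)
    ]
    out = assignments[["gene", "time_min", "group"]].copy()
    out["x_log2_MK23KO_vs_MK2KO"] = [c[0] for c in coords]
    out["y_log2_wt_vs_MK2KO"] = [c[1] for c in coords]
    return out


# ---------------------------------------------------------------------------
# tab-delimited I/O

def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, encoding="utf-8")


def read_probe_matrix(path: str | Path) -> pd.DataFrame:
    """Read a probe x sample intensity TSV (first column probe_id).

    GEO series-matrix-style files are accepted: lines starting with '!'
    are skipped.
    """
    df = pd.read_csv(path, sep="\t", comment="!", index_col=0, encoding="utf-8")
    df.index.name = "probe_id"
    if df.isna().any().any():
        raise ValueError(f"missing values in probe matrix {path}")
    if df.index.duplicated().any():
        raise ValueError(f"duplicate probe ids in {path}")
    return df


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", encoding="utf-8")
    validate_sample_sheet(samples)
    return samples


def read_annotation(path: str | Path) -> pd.DataFrame:
    annot = pd.read_csv(path, sep="\t", encoding="utf-8", keep_default_na=False,
                        dtype={"probe_id": str, "gene_symbol": str, "accession": str})
    required = {"probe_id", "gene_symbol", "accession", "known_function"}
    missing = required - set(annot.columns)
    if missing:
        raise ValueError(f"annotation missing columns: {sorted(missing)}")
    if annot["probe_id"].duplicated().any():
        raise ValueError("duplicate probe ids in annotation")
    return annot


def read_gene_matrix(path: str | Path, samples: pd.DataFrame) -> GeneMatrix:
    """Read a gene matrix TSV written by :meth:`GeneMatrix.to_frame`."""
    df = pd.read_csv(path, sep="\t", index_col=0, encoding="utf-8")
    provenance = df.pop("probe_id") if "probe_id" in df.columns else pd.Series(dtype=object)
    return GeneMatrix(values=df, samples=samples, probe_of_gene=provenance)


def heatmap_table(assignments: pd.DataFrame) -> pd.DataFrame:
    """Three-column heat-map layout: per gene the relative level and star of
    each pairwise genotype comparison, ordered by wt-vs-MK2KO level."""
    cols = ["gene", "time_min",
            "level_wt_vs_MK2KO", "star_wt_vs_MK2KO",
            "level_wt_vs_MK23KO", "star_wt_vs_MK23KO",
            "level_MK2KO_vs_MK23KO", "star_MK2KO_vs_MK23KO",
            "group"]
    return assignments[cols].sort_values("level_wt_vs_MK2KO", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# configuration

PIPELINE_DEFAULTS: dict[str, Any] = {
    "alpha": 0.05,
    "min_fold": 4.0,
    "threshold": 0.2,
    "floor": 5.0,
    "collapse_timepoint": 120,
    "level": "treated",
    "fdr": False,
    "seed": 0,
}


def load_config(path: str | Path | None) -> dict[str, Any]:
    """Load a flat key-value YAML config; CLI flags override these, and
    both override the defaults."""
    import yaml

    cfg = dict(PIPELINE_DEFAULTS)
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError("config must be a flat key-value mapping")
        cfg.update(user)
    return cfg


# ---------------------------------------------------------------------------
# pipeline driver

def run_pipeline(config: Mapping[str, Any], outdir: str | Path) -> dict[str, Any]:
    """Execute the full analysis and write the report bundle into ``outdir``.

    The config either names input files (``matrix``, ``samples``,
    ``annotation``) or contains ``simulate: true`` plus SimulationConfig
    overrides under ``sim_*`` keys.  Returns the run manifest (also written
    as ``manifest.json``).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = dict(PIPELINE_DEFAULTS)
    cfg.update(config)
    if cfg["alpha"] >= 1.0:
        log.warning("alpha=%g is degenerate: every gene will be called responsive", cfg["alpha"])

    stages: dict[str, Any] = {}
    if cfg.get("simulate"):
        sim_kwargs = {k[4:]: v for k, v in cfg.items() if k.startswith("sim_")}
        sim_kwargs.setdefault("seed", cfg["seed"])
        if "probes_per_gene" in sim_kwargs:
            sim_kwargs["probes_per_gene"] = tuple(sim_kwargs["probes_per_gene"])
        if "timepoints" in sim_kwargs:
            sim_kwargs["timepoints"] = tuple(sim_kwargs["timepoints"])
        sim = generate_dataset(SimulationConfig(**sim_kwargs))
        matrix, samples, annotation = sim.probe_matrix, sim.samples, sim.annotation
        write_table(matrix.reset_index(), outdir / "probe_matrix.tsv")
        write_table(samples, outdir / "samples.tsv")
        write_table(annotation, outdir / "annotation.tsv")
        write_table(sim.truth, outdir / "truth.tsv")
        stages["simulate"] = {"n_probes": len(matrix), "n_samples": matrix.shape[1],
                              "n_genes": len(sim.truth)}
    else:
        matrix = read_probe_matrix(cfg["matrix"])
        samples = read_sample_sheet(cfg["samples"])
        annotation = read_annotation(cfg["annotation"])
        stages["load"] = {"n_probes": len(matrix), "n_samples": matrix.shape[1]}

    gm = preprocess_pipeline(matrix, samples, annotation,
                             floor=cfg["floor"], collapse_timepoint=cfg["collapse_timepoint"])
    write_table(gm.to_frame(), outdir / "gene_matrix.tsv", index=True)
    stages["preprocess"] = {"n_genes": len(gm.genes), "n_samples": gm.values.shape[1]}

    timepoints = sorted(set(samples.loc[samples["treatment"] == "LPS", "time_min"]))
    calls = call_all(gm, timepoints=timepoints, alpha=cfg["alpha"], fdr=cfg["fdr"])
    write_table(calls, outdir / "responsiveness_calls.tsv")
    venns = venn_by_timepoint(calls)
    n_genes = len(gm.genes)
    venn_report = {
        str(t): {
            **v,
            "percent_of_analyzed": {
                g: percent(v[f"{g}_total"], n_genes) for g in ("wt", "MK2KO", "MK23KO")
            },
            "knockout_only": len(
                knockout_only_responsive(
                    responsive_gene_set(calls[(calls["time_min"] == t) & (calls["genotype"] == "wt")]),
                    responsive_gene_set(calls[(calls["time_min"] == t) & (calls["genotype"] == "MK2KO")]),
                    responsive_gene_set(calls[(calls["time_min"] == t) & (calls["genotype"] == "MK23KO")]),
                )
            ),
        }
        for t, v in venns.items()
    }
    (outdir / "venn.json").write_text(json.dumps(venn_report, indent=2), encoding="utf-8")
    stages["responsiveness"] = {
        str(t): int(sum(v[f"{g}_total"] for g in ("wt", "MK2KO", "MK23KO"))) for t, v in venns.items()
    }

    all_assignments, summaries = [], {}
    for t in timepoints:
        assignments, summary = classify_all(
            gm, t, alpha=cfg["alpha"], threshold=cfg["threshold"],
            min_fold=cfg["min_fold"], level=cfg["level"],
        )
        all_assignments.append(assignments)
        summaries[str(t)] = summary
    assignments = pd.concat([a for a in all_assignments if len(a)], ignore_index=True) \
        if any(len(a) for a in all_assignments) else pd.DataFrame()
    write_table(assignments, outdir / "assignments.tsv")
    if len(assignments):
        write_table(heatmap_table(assignments), outdir / "heatmap.tsv")
        write_table(scatter_table(assignments), outdir / "scatter.tsv")
    (outdir / "proportions.json").write_text(json.dumps(summaries, indent=2), encoding="utf-8")
    stages["classification"] = {t: s["n_dependent"] for t, s in summaries.items()}

    manifest = {
        "package": "mkpatterns",
        "version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": cfg["seed"],
        "thresholds": {
            "alpha": cfg["alpha"],
            "min_fold": cfg["min_fold"],
            "relation_threshold": cfg["threshold"],
            "floor": cfg["floor"],
            "collapse_timepoint": cfg["collapse_timepoint"],
            "level": cfg["level"],
            "fdr": cfg["fdr"],
        },
        "stages": stages,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    log.info("pipeline complete: %s", outdir)
    return manifest
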