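"""End-to-end pipeline orchestration and evaluation artefacts.

Runs simulate/ingest -> SNP mask -> count -> filter -> beta-binomial test ->
FDR calling, and produces the evaluation outputs used to judge a labelling
experiment: marker-panel sensitivity, labelled proportion by T content,
overlap with a FACS-derived expression reference, and pseudo-counted
plotting tables.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .quant import QuantParams, call_snps, count_conversions, merge_samples, read_reference, read_windows
from .simulate import SimConfig, simulate_experiment
from .stats import call_labelled, run_labelling_tests

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerPanel",
    "evaluate_panel",
    "facs_overlap",
    "load_fpkm",
    "plotting_table",
    "run_pipeline",
    "tcontent_bins",
]

PLOT_PSEUDOCOUNT = 1e-5  # added to raw T>C fractions in plotting outputs only


@dataclass(frozen=True)
class MarkerPanel:
    """A named panel of marker genes, matched case-sensitively."""

    panel_name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("marker panel must be non-empty")

    @classmethod
    def from_file(cls, path: str | Path, panel_name: str | None = None) -> "MarkerPanel":
        genes = [
            line.strip()
            for line in Path(path).read_text().splitlines()
            if line.strip() and not line.startswith("#")
        ]
        return cls(panel_name or Path(path).stem, tuple(genes))


def evaluate_panel(results: pd.DataFrame, panel: MarkerPanel) -> tuple[pd.DataFrame, float | None]:
    """Per-gene labelling calls for a marker panel, plus sensitivity.

    Sensitivity = labelled / present-in-results; None (undefined) when no
    panel gene appears in the results.
    """
    called = dict(zip(results["gene"], results["labelled"]))
    rows = []
    for g in panel.genes:
        if g in called:
            status = "labelled" if called[g] else "unlabelled"
        else:
            status = "absent"
        rows.append({"panel": panel.panel_name, "gene": g, "status": status})
    df = pd.DataFrame(rows)
    present = (df["status"] != "absent").sum()
    if present == 0:
        return df, None
    return df, float((df["status"] == "labelled").sum() / present)


def tcontent_bins(
    results: pd.DataFrame,
    t_content: pd.Series,
    bin_edges: list[float] | None = None,
) -> pd.DataFrame:
    """Labelled proportion per T-content stratum.

    ``t_content`` maps gene -> number of T bases in its counting window.
    The default edges carry a dedicated "fewer than 50 T bases" stratum.
    """
    if bin_edges is None:
        bin_edges = [0, 50, 100, 200, 400, np.inf]
    tc = results["gene"].map(t_content)
    if tc.isna().any():
        missing = results.loc[tc.isna(), "gene"].tolist()[:4]
        raise ValueError(f"T content missing for genes: {missing}")
    binned = pd.cut(tc, bins=bin_edges, right=False)
    rows = []
    for iv in binned.cat.categories:
        in_bin = results[binned == iv]
        n = len(in_bin)
        n_lab = int(in_bin["labelled"].sum())
        rows.append(
            {
                "bin": str(iv),
                "n_genes": n,
                "n_labelled": n_lab,
                "labelled_proportion": n_lab / n if n > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def load_fpkm(path: str | Path, floor: float = 0.1) -> pd.DataFrame:
    """Read an FPKM table (gene + one column per cell type), flooring at 0.1.

    The flooring convention follows the source dataset: values below the
    expression-confidence threshold are rounded up to it so ratios are not
    inflated by near-zero denominators.
    """
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns:
        raise ValueError("FPKM table must have a 'gene' column")
    num = df.columns.drop("gene")
    df[num] = df[num].clip(lower=floor)
    return df


def facs_overlap(
    results: pd.DataFrame, fpkm: pd.DataFrame, target: str, floor: float = 0.1
) -> dict:
    """Compare the labelled set against FACS-defined expression sets.

    expressed-in-target: FPKM strictly above the floor in the target cell
    type; exclusive-other: mean FPKM above the floor across non-target
    types AND exactly at the floor in the target (i.e. undetected there).
    The two sets are disjoint by construction.  Returns cardinalities and,
    where defined, fractions of the labelled set.
    """
    if target not in fpkm.columns:
        raise ValueError(f"target cell type {target!r} not in FPKM table")
    others = [c for c in fpkm.columns if c not in ("gene", target)]
    expressed = set(fpkm.loc[fpkm[target] > floor, "gene"])
    excl = set(
        fpkm.loc[
            (fpkm[others].mean(axis=1) > floor) & (fpkm[target] == floor), "gene"
        ]
    )
    labelled = set(results.loc[results["labelled"], "gene"])
    n_lab = len(labelled)
    out = {
        "target": target,
        "n_labelled": n_lab,
        "n_expressed_target": len(expressed),
        "n_exclusive_other": len(excl),
        "labelled_and_expressed": len(labelled & expressed),
        "labelled_and_exclusive_other": len(labelled & excl),
        "labelled_only": len(labelled - expressed - excl),
        "frac_labelled_expressed": len(labelled & expressed) / n_lab if n_lab else None,
        "frac_labelled_exclusive_other": len(labelled & excl) / n_lab if n_lab else None,
    }
    return out


def plotting_table(
    results: pd.DataFrame,
    counts: pd.DataFrame,
    sheet: pd.DataFrame,
    pseudocount: float = PLOT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene group-mean T>C fraction with the plotting pseudo-count.

    The constant is a display convention for log-scale scatter only; the
    statistics upstream never see it.
    """
    groups = dict(zip(sheet["sample_id"], sheet["group"]))
    sub = counts[counts["gene"].isin(results["gene"])].copy()
    sub["group"] = sub["sample"].map(groups)
    means = (
        sub.groupby(["gene", "group"])["tc_fraction"]
        .mean()
        .unstack("group")
        .reindex(index=results["gene"], columns=["cre_pos", "cre_neg"])
    )
    out = pd.DataFrame(
        {
            "gene": results["gene"].to_numpy(),
            "mean_tc_pos": means["cre_pos"].to_numpy() + pseudocount,
            "mean_tc_neg": means["cre_neg"].to_numpy() + pseudocount,
            "labelled": results["labelled"].to_numpy(),
        }
    )
    return out


def _load_run_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, dict):
        raise ValueError("run configuration must be a mapping")
    if "simulate" not in config and "inputs" not in config:
        raise ValueError("config needs a 'simulate' block or an 'inputs' block")
    return config


def run_pipeline(
    config: dict | str | Path,
    out_dir: str | Path,
    force: bool = False,
) -> dict:
    """Run the full pipeline and write all stage outputs plus a manifest.

    ``config`` holds a ``simulate`` block (synthetic experiment) or an
    ``inputs`` block (reference/bed/sample-sheet/alignment paths), an
    optional ``quant`` block of counting parameters, and ``fdr``.
    Returns the manifest dictionary.  Deterministic given config.
    """
    cfg = _load_run_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_t0 = time.perf_counter()

    def _stage(name):
        logger.info("stage %-10s at %.1fs", name, time.perf_counter() - stage_t0)

    try:
        if "simulate" in cfg:
            _stage("simulate")
            sim_cfg = SimConfig(**cfg["simulate"])
            sim_dir = out / "experiment"
            simulate_experiment(sim_cfg, sim_dir, force=force)
            ref_path = sim_dir / "reference.fa"
            bed_path = sim_dir / "windows.bed"
            sheet_path = sim_dir / "samples.tsv"
            sheet = pd.read_csv(sheet_path, sep="\t")
            sam_paths = {s: sim_dir / f"{s}.sam" for s in sheet["sample_id"]}
        else:
            inputs = cfg["inputs"]
            ref_path, bed_path = inputs["reference"], inputs["bed"]
            sheet = pd.read_csv(inputs["sheet"], sep="\t")
            sam_dir = Path(inputs["alignments"])
            sam_paths = {}
            for s in sheet["sample_id"]:
                for ext in (".sam", ".bam"):
                    if (sam_dir / f"{s}{ext}").exists():
                        sam_paths[s] = sam_dir / f"{s}{ext}"
                        break
                else:
                    raise FileNotFoundError(f"no alignment file for sample {s}")
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'ingest' failed: {err}") from err

    params = QuantParams(**cfg.get("quant", {}))
    fdr = float(cfg.get("fdr", 0.05))

    try:
        _stage("snp-mask")
        seqs = read_reference(ref_path)
        windows = read_windows(bed_path)
        mask = call_snps(list(sam_paths.values()), seqs, windows, params)
        _stage("count")
        tables = [
            count_conversions(path, seqs, windows, mask, params, sample_id=s)
            for s, path in sam_paths.items()
        ]
        read_stats = {s: t.attrs["filter_stats"] for s, t in zip(sam_paths, tables)}
        counts = merge_samples(tables, sheet)
        counts.to_csv(out / "counts.tsv", sep="\t", index=False, na_rep="NA")
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'count' failed: {err}") from err

    try:
        _stage("test")
        results, filt = run_labelling_tests(counts, sheet)
        results = call_labelled(results, fdr=fdr)
        results.to_csv(out / "results.tsv", sep="\t", index=False)
        (out / "filter_report.json").write_text(
            json.dumps(filt.to_dict(), indent=2, sort_keys=True) + "\n"
        )
        # ranked list: every tested gene by ascending p, for enrichment tools
        (out / "ranked_genes.txt").write_text(
            "\n".join(results["gene"]) + "\n"
        )
        plot = plotting_table(results, counts, sheet)
        plot.to_csv(out / "plotting_table.tsv", sep="\t", index=False)
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'test' failed: {err}") from err

    _stage("manifest")
    manifest = {
        "slamitseq_version": __version__,
        "config": cfg,
        "quant_params": params.__dict__,
        "fdr": fdr,
        "n_snp_masked_sites": len(mask),
        "samples": list(sheet["sample_id"]),
        "reads": {s: st for s, st in read_stats.items()},
        "genes": {
            "windows": int(len(windows)),
            "in": filt.genes_in,
            "removed_zero_coverage": filt.genes_removed,
            "tested": filt.genes_tested,
            "labelled": int(results["labelled"].sum()),
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    _stage("done")
    return manifest
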