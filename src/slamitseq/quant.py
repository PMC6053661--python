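"""Per-gene T coverage and T>C conversion counting from 3'-end alignments.

For every read overlapping a gene's 3'UTR counting window, every aligned
position whose reference base is T on the window's annotated strand is one
unit of T coverage, and additionally one conversion when the read calls a C
there (strand-adjusted: on minus-strand windows the reference T is a
plus-strand A and the converted call a plus-strand G).  Position-level
filters mirror conversion-aware SLAM-seq counting: a 5' read-end trim, a
base-quality floor, a multimapper cap, and masking of reference-T sites
that look converted in every animal (germline T>C variants, found by a
pooled pileup threshold rather than per-sample variant calling, since the
genotype is shared across littermates).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "QuantParams",
    "SNPMask",
    "call_snps",
    "count_conversions",
    "merge_samples",
    "read_reference",
    "read_windows",
]


@dataclass(frozen=True)
class QuantParams:
    """Counting parameters.

    Defaults follow common SLAM-seq practice for 100-base QuantSeq reads:
    the first 12 read bases are discarded (adapter/UMI-contaminated 5'
    ends), reads reporting more than 100 alignments are dropped, and a
    reference-T site whose pooled converted fraction reaches 0.2 is treated
    as a genomic variant.  ``min_snp_coverage`` keeps single-read noise from
    masking sites; ``min_base_quality`` guards the counted base call.
    """

    trim5: int = 12
    max_alignments: int = 100
    min_var_fraction: float = 0.2
    min_snp_coverage: int = 10
    min_base_quality: int = 27
    read_length: int = 100

    def __post_init__(self) -> None:
        if self.trim5 < 0:
            raise ValueError("trim5 must be >= 0")
        if not 0.0 < self.min_var_fraction <= 1.0:
            raise ValueError("min_var_fraction must lie in (0, 1]")
        if self.min_snp_coverage < 1:
            raise ValueError("min_snp_coverage must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "QuantParams":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


class SNPMask:
    """Set of (contig, 0-based position) reference-T sites excluded from counting."""

    def __init__(self, sites: set[tuple[str, int]] | None = None):
        self.sites = set(sites or ())

    def __contains__(self, site: tuple[str, int]) -> bool:
        return site in self.sites

    def __len__(self) -> int:
        return len(self.sites)

    def __eq__(self, other) -> bool:
        return isinstance(other, SNPMask) and self.sites == other.sites


def read_reference(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def read_windows(path: str | Path) -> pd.DataFrame:
    """Read BED6 counting windows (0-based half-open, strand-aware)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["contig", "start", "end", "name", "score", "strand"],
        dtype={"contig": str, "name": str, "strand": str},
    )
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError("BED strand column must be '+' or '-'")
    return df


def _check_header(sam: pysam.AlignmentFile, seqs: dict[str, str], path) -> None:
    for name, length in zip(sam.references, sam.lengths):
        if name not in seqs:
            raise ValueError(f"{path}: contig {name!r} absent from reference FASTA")
        if len(seqs[name]) != length:
            raise ValueError(
                f"{path}: contig {name!r} length {length} != FASTA {len(seqs[name])}"
            )
    so = sam.header.to_dict().get("HD", {}).get("SO", "unknown")
    if so != "coordinate":
        raise ValueError(f"{path}: alignments must be coordinate-sorted (SO={so})")


def _window_arrays(seqs: dict[str, str], windows: pd.DataFrame):
    """Per window: sense-T boolean array and metadata, keyed by contig."""
    by_contig: dict[str, list[dict]] = {}
    for row in windows.itertuples(index=False):
        if row.contig not in seqs:
            raise ValueError(f"window contig {row.contig!r} absent from reference")
        seq = np.frombuffer(
            seqs[row.contig][row.start : row.end].encode(), dtype="S1"
        )
        sense_t = seq == (b"T" if row.strand == "+" else b"A")
        by_contig.setdefault(row.contig, []).append(
            {
                "gene": row.name,
                "start": int(row.start),
                "end": int(row.end),
                "strand": row.strand,
                "sense_t": sense_t,
            }
        )
    return by_contig


def _read_passes(read: pysam.AlignedSegment, params: QuantParams, stats: dict) -> bool:
    if read.is_unmapped:
        stats["unmapped"] += 1
        return False
    if read.is_secondary or read.is_supplementary:
        stats["secondary"] += 1
        return False
    nh = read.get_tag("NH") if read.has_tag("NH") else 1
    if nh > params.max_alignments:
        stats["multimapper"] += 1
        return False
    return True


def _aligned_positions(read: pysam.AlignedSegment):
    """(query_pos, ref_pos) arrays for aligned (match) columns."""
    cig = read.cigartuples
    if cig is not None and len(cig) == 1 and cig[0][0] == 0:
        n = cig[0][1]
        q = np.arange(n)
        r = read.reference_start + q
        return q, r
    pairs = read.get_aligned_pairs(matches_only=True)
    if not pairs:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    q, r = map(np.asarray, zip(*pairs))
    return q, r


def _scan(
    sam_path: str | Path,
    seqs: dict[str, str],
    by_contig,
    params: QuantParams,
    per_site: dict | None,
    per_gene: dict | None,
    mask_arrays: dict | None,
    stats: dict,
) -> None:
    """One pass over a SAM/BAM, accumulating site pileups and/or gene counts."""
    warned_contigs: set[str] = set()
    with pysam.AlignmentFile(str(sam_path), "r") as sam:
        _check_header(sam, seqs, sam_path)
        for read in sam:
            stats["seen"] += 1
            if not _read_passes(read, params, stats):
                continue
            contig = read.reference_name
            wlist = by_contig.get(contig)
            if wlist is None:
                if contig not in warned_contigs:
                    warned_contigs.add(contig)
                    logger.warning("no counting window for contig %s; reads skipped", contig)
                stats["no_window"] += 1
                continue
            qpos, rpos = _aligned_positions(read)
            if qpos.size == 0:
                continue
            quals = read.query_qualities
            quals = (
                np.asarray(quals) if quals is not None else np.full(read.query_length, 255)
            )
            seq = np.frombuffer(read.query_sequence.encode(), dtype="S1")
            qlen = read.query_length
            counted = False
            for w in wlist:
                if read.is_reverse != (w["strand"] == "-"):
                    continue
                inside = (rpos >= w["start"]) & (rpos < w["end"])
                if not inside.any():
                    continue
                qi, ri = qpos[inside], rpos[inside]
                off = ri - w["start"]
                site_t = w["sense_t"][off]
                good_q = quals[qi] >= params.min_base_quality
                keep = site_t & good_q
                conv_base = b"C" if w["strand"] == "+" else b"G"
                if per_site is not None:
                    # pooled pileup for variant masking: genomic, so no 5' trim
                    cov, var = per_site[(contig, w["gene"])]
                    np.add.at(cov, off[keep], 1)
                    hit = keep & (seq[qi] == conv_base)
                    np.add.at(var, off[hit], 1)
                if per_gene is not None:
                    five_prime = qi if not read.is_reverse else (qlen - 1 - qi)
                    keep_g = keep & (five_prime >= params.trim5)
                    if mask_arrays is not None:
                        keep_g = keep_g & ~mask_arrays[(contig, w["gene"])][off]
                    t_cov, tc = per_gene[w["gene"]]
                    n_keep = int(keep_g.sum())
                    n_conv = int((keep_g & (seq[qi] == conv_base)).sum())
                    per_gene[w["gene"]] = (t_cov + n_keep, tc + n_conv)
                counted = True
            if counted:
                stats["kept"] += 1
            else:
                stats["off_window"] += 1


def _new_stats() -> dict:
    return dict(seen=0, kept=0, unmapped=0, secondary=0, multimapper=0, no_window=0, off_window=0)


def call_snps(
    sam_paths: list[str | Path],
    seqs: dict[str, str],
    windows: pd.DataFrame,
    params: QuantParams,
) -> SNPMask:
    """Find germline T>C sites from the pooled pileup of all samples.

    A reference-T site (annotated strand) inside a counting window is masked
    iff pooled coverage >= ``min_snp_coverage`` and its converted-call
    fraction >= ``min_var_fraction``.  Pooling across samples is what
    distinguishes a genomic variant, which converts in every animal of both
    genotypes, from labelling, which is genotype-restricted.
    """
    by_contig = _window_arrays(seqs, windows)
    per_site = {
        (contig, w["gene"]): (
            np.zeros(w["end"] - w["start"], dtype=np.int64),
            np.zeros(w["end"] - w["start"], dtype=np.int64),
        )
        for contig, wlist in by_contig.items()
        for w in wlist
    }
    stats = _new_stats()
    for path in sam_paths:
        _scan(path, seqs, by_contig, params, per_site, None, None, stats)
    logger.info("snp pileup over %d files: %s", len(sam_paths), stats)

    sites: set[tuple[str, int]] = set()
    for contig, wlist in by_contig.items():
        for w in wlist:
            cov, var = per_site[(contig, w["gene"])]
            with np.errstate(divide="ignore", invalid="ignore"):
                frac = np.where(cov > 0, var / np.maximum(cov, 1), 0.0)
            hit = (cov >= params.min_snp_coverage) & (frac >= params.min_var_fraction)
            hit &= w["sense_t"]
            for off in np.flatnonzero(hit):
                sites.add((contig, w["start"] + int(off)))
    return SNPMask(sites)


def count_conversions(
    sam_path: str | Path,
    seqs: dict[str, str],
    windows: pd.DataFrame,
    mask: SNPMask | None,
    params: QuantParams,
    sample_id: str | None = None,
) -> pd.DataFrame:
    """Count T coverage and T>C conversions per gene for one sample.

    Returns one row per window gene (zero counts when unobserved) with
    columns gene, sample, t_coverage, tc_count, tc_fraction; tc_fraction is
    NaN where coverage is zero.  Per-filter read tallies are attached as
    ``df.attrs['filter_stats']`` and logged.
    """
    mask = mask or SNPMask()
    by_contig = _window_arrays(seqs, windows)
    mask_arrays = {}
    for contig, wlist in by_contig.items():
        for w in wlist:
            arr = np.zeros(w["end"] - w["start"], dtype=bool)
            for (c, p) in mask.sites:
                if c == contig and w["start"] <= p < w["end"]:
                    arr[p - w["start"]] = True
            mask_arrays[(contig, w["gene"])] = arr
    per_gene = {w["gene"]: (0, 0) for wl in by_contig.values() for w in wl}
    stats = _new_stats()
    _scan(sam_path, seqs, by_contig, params, None, per_gene, mask_arrays, stats)
    sid = sample_id if sample_id is not None else Path(sam_path).stem
    logger.info("counted %s: %s", sid, stats)

    rows = [
        (gene, sid, cov, tc, tc / cov if cov > 0 else np.nan)
        for gene, (cov, tc) in sorted(per_gene.items())
    ]
    df = pd.DataFrame(
        rows, columns=["gene", "sample", "t_coverage", "tc_count", "tc_fraction"]
    )
    df.attrs["filter_stats"] = stats
    return df


def merge_samples(tables: list[pd.DataFrame], sheet: pd.DataFrame) -> pd.DataFrame:
    """Combine per-sample count tables into one long (gene, sample) table.

    Every sheet sample must be present; genes missing from a sample get
    zero coverage; duplicate (gene, sample) rows are an integrity error.
    """
    merged = pd.concat(tables, ignore_index=True)
    if merged.duplicated(subset=["gene", "sample"]).any():
        dup = merged[merged.duplicated(subset=["gene", "sample"], keep=False)]
        raise ValueError(
            f"duplicate (gene, sample) rows in counts: {dup[['gene', 'sample']].values[:4]}"
        )
    samples = list(sheet["sample_id"])
    missing = set(samples) - set(merged["sample"].unique())
    if missing:
        raise ValueError(f"missing count tables for samples: {sorted(missing)}")
    genes = sorted(merged["gene"].unique())
    full = pd.MultiIndex.from_product([genes, samples], names=["gene", "sample"])
    out = (
        merged.set_index(["gene", "sample"])
        .reindex(full)
        .reset_index()
    )
    out["t_coverage"] = out["t_coverage"].fillna(0).astype(int)
    out["tc_count"] = out["tc_count"].fillna(0).astype(int)
    with np.errstate(divide="ignore", invalid="ignore"):
        out["tc_fraction"] = np.where(
            out["t_coverage"] > 0, out["tc_count"] / out["t_coverage"].replace(0, 1), np.nan
        )
    return out
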