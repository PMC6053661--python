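"""Ground-truthed synthetic SLAM-ITseq experiments.

Emulates the computational input of a 4-thiouracil metabolic-labelling
experiment read out by QuantSeq-style 3'-end sequencing: a two-genotype
replicate design (Cre+ animals express UPRT and label RNA in the cell type
of interest; Cre- littermates measure background conversion) in which a
per-gene fraction of molecules carries T>C conversions.

The model is two-level Bernoulli, matching the biology of labelled versus
unlabelled transcripts: each read is drawn from a labelled molecule with the
group's labelled fraction ``f``; every sense-strand T of a labelled molecule
is read as C with probability ``conversion_rate``; independently, every base
can be miscalled.  ``error_rate`` is the rate of one specific substitution
(so a T position is misread as specifically C with probability
``error_rate`` and the total miscall probability per base is three times
that), which makes the expected T>C fraction of a gene

    f * conversion_rate + (1 - f) * error_rate        (to first order)

Reads are emitted pre-aligned (SAM, correct POS, pure-match CIGAR): read
alignment is upstream of this package's scope, and true placements keep the
counting layer testable in isolation.  Each gene lives on its own contig
with one 3'UTR counting window flanked by read_length-1 bases, so every
window position has the same expected read depth.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneSpec",
    "SimConfig",
    "generate_reference",
    "simulate_sample",
    "simulate_experiment",
    "simulate_count_table",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class GeneSpec:
    """One synthetic gene: a single 3'UTR counting window on its own contig.

    ``t_positions`` are 0-based offsets within the window (reference
    orientation) whose sense-strand base is T -- i.e. reference T for a
    plus-strand gene, reference A for a minus-strand one.
    """

    gene_id: str
    length: int
    t_positions: tuple[int, ...]
    expression: float
    labelled_fraction_pos: float = 0.0
    labelled_fraction_neg: float = 0.0
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("gene window length must be positive")
        if self.expression < 0:
            raise ValueError("expression must be non-negative")
        for f in (self.labelled_fraction_pos, self.labelled_fraction_neg):
            if not 0.0 <= f <= 1.0:
                raise ValueError("labelled fractions must lie in [0, 1]")
        if any(p < 0 or p >= self.length for p in self.t_positions):
            raise ValueError("t_positions must lie in [0, length)")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass
class SimConfig:
    """Experiment-level simulation parameters.

    The replicate structure (``n_pos``/``n_neg``) mirrors a typical
    Cre+ n=4 vs Cre- n=3 littermate design; ``read_length`` the 100-base
    single-end QuantSeq reads the pipeline's trimming defaults assume.
    ``f_concentration``, when set, draws each animal's labelled fraction
    from Beta(f*c, (1-f)*c) instead of holding it fixed, to emulate
    biological replicate-to-replicate variability in labelling.
    """

    conversion_rate: float = 0.025
    error_rate: float = 0.001
    n_pos: int = 4
    n_neg: int = 3
    read_length: int = 100
    seed: int = 0
    snp_fraction: float = 0.0
    f_concentration: float | None = None
    # reference-generation block used when no gene panel is supplied
    n_genes: int = 100
    length_min: int = 250
    length_max: int = 450
    gc_content: float = 0.5
    expression: float = 300.0
    n_labelled: int = 0
    labelled_fraction_pos: float = 0.2
    labelled_fraction_neg: float = 0.0

    def __post_init__(self) -> None:
        for name in ("conversion_rate", "error_rate", "snp_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.error_rate > 1.0 / 3.0:
            raise ValueError("error_rate is a per-substitution rate; must be <= 1/3")
        if self.n_pos < 2 or self.n_neg < 2:
            raise ValueError("the replicate test requires n_pos, n_neg >= 2")
        if self.read_length < 1:
            raise ValueError("read_length must be positive")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.length_min > self.length_max or self.length_min < 1:
            raise ValueError("empty or invalid window length range")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must lie in [0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _flank(read_length: int) -> int:
    return read_length - 1


def _random_seq(rng: np.random.Generator, n: int, probs: np.ndarray) -> np.ndarray:
    return rng.choice(_BASES, size=n, p=probs)


def generate_reference(
    n_genes: int,
    length_range: tuple[int, int] = (250, 450),
    gc_content: float = 0.5,
    seed: int = 0,
    *,
    read_length: int = 100,
    expression: float = 300.0,
    base_probs: dict[str, float] | None = None,
    minus_strand_fraction: float = 0.5,
) -> tuple[dict[str, str], pd.DataFrame, list[GeneSpec]]:
    """Generate reference contigs, 3'UTR windows and gene specifications.

    One contig per gene: ``read_length - 1`` flanks around a single window
    of length drawn uniformly from ``length_range``, so reads overlapping
    the window can start anywhere and window coverage is uniform.  Base
    composition is i.i.d. with G+C probability ``gc_content`` split evenly
    (override with explicit ``base_probs``); windows are resampled until
    they contain a T on the sense strand whenever the composition allows one.

    Returns ``(sequences, windows, genes)`` with ``windows`` a BED-style
    frame (contig, start, end, name, score, strand; 0-based half-open).
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = length_range
    if lo > hi or lo < 1:
        raise ValueError("empty or invalid length range")
    if base_probs is None:
        probs = np.array(
            [(1 - gc_content) / 2, gc_content / 2, gc_content / 2, (1 - gc_content) / 2]
        )
    else:
        probs = np.array([base_probs.get(b, 0.0) for b in "ACGT"], dtype=float)
        if probs.sum() <= 0:
            raise ValueError("base_probs must have positive mass")
        probs = probs / probs.sum()

    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    seqs: dict[str, str] = {}
    rows = []
    genes: list[GeneSpec] = []
    flank = _flank(read_length)
    for i in range(n_genes):
        gid = f"gene{i + 1:0{width}d}"
        wlen = int(rng.integers(lo, hi + 1))
        strand = "-" if rng.random() < minus_strand_fraction else "+"
        sense_t = "T" if strand == "+" else "A"
        can_have_t = probs["ACGT".index(sense_t)] > 0
        for _ in range(100):
            window = _random_seq(rng, wlen, probs)
            if not can_have_t or (window == sense_t.encode()).any():
                break
        left = _random_seq(rng, flank, probs)
        right = _random_seq(rng, flank, probs)
        seq = b"".join([left.tobytes(), window.tobytes(), right.tobytes()]).decode()
        seqs[gid] = seq
        t_pos = tuple(int(p) for p in np.flatnonzero(window == sense_t.encode()))
        rows.append((gid, flank, flank + wlen, gid, 0, strand))
        genes.append(
            GeneSpec(
                gene_id=gid,
                length=wlen,
                t_positions=t_pos,
                expression=expression,
                strand=strand,
            )
        )
    windows = pd.DataFrame(
        rows, columns=["contig", "start", "end", "name", "score", "strand"]
    )
    return seqs, windows, genes


def write_reference(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_bed(windows: pd.DataFrame, path: str | Path) -> None:
    windows.to_csv(path, sep="\t", header=False, index=False)


def _sam_header(seqs: dict[str, str]) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": name, "LN": len(s)} for name, s in seqs.items()],
        }
    )


def simulate_sample(
    genes: list[GeneSpec],
    seqs: dict[str, str],
    windows: pd.DataFrame,
    group: str,
    config: SimConfig,
    replicate_seed: int,
    out_sam: str | Path,
    sample_id: str,
    snps: dict[str, tuple[int, ...]] | None = None,
) -> pd.DataFrame:
    """Simulate one animal's aligned reads; write a coordinate-sorted SAM.

    Reads are drawn per gene (expected count = the gene's ``expression``),
    placed uniformly over starts overlapping the window, and mutated by the
    two-level labelling model described in the module docstring.  Genomic
    SNPs (``snps``: window offsets per gene) are applied to every read of
    every sample before conversion.  Returns the per-gene truth for this
    sample: reads drawn, labelled reads, and the realised labelled fraction.
    """
    if group not in ("cre_pos", "cre_neg"):
        raise ValueError("group must be 'cre_pos' or 'cre_neg'")
    snps = snps or {}
    rng = np.random.default_rng(replicate_seed)
    rl = config.read_length
    win = windows.set_index("name")
    header = _sam_header(seqs)

    expr = np.array([g.expression for g in genes], dtype=float)
    total = int(round(expr.sum()))
    n_reads = (
        rng.multinomial(total, expr / expr.sum())
        if total > 0 and expr.sum() > 0
        else np.zeros(len(genes), dtype=int)
    )

    truth_rows = []
    with pysam.AlignmentFile(str(out_sam), "w", header=header) as sam:
        for g, n in zip(genes, n_reads):
            w = win.loc[g.gene_id]
            w_start, w_end = int(w["start"]), int(w["end"])
            contig = np.frombuffer(seqs[g.gene_id].encode(), dtype="S1").copy()
            sense_t, sense_c = (b"T", b"C") if g.strand == "+" else (b"A", b"G")
            # homozygous genomic variant: present in the molecule itself
            for off in snps.get(g.gene_id, ()):
                contig[w_start + off] = sense_c
            f = (
                g.labelled_fraction_pos
                if group == "cre_pos"
                else g.labelled_fraction_neg
            )
            if config.f_concentration is not None and 0.0 < f < 1.0:
                c0 = config.f_concentration
                f = float(rng.beta(f * c0, (1.0 - f) * c0))
            n = int(n)
            starts = np.sort(rng.integers(0, w_end - w_start + rl - 1, size=n))
            labelled = rng.random(n) < f
            tid = header.get_tid(g.gene_id)
            n_lab = 0
            for start, lab in zip(starts, labelled):
                read = contig[start : start + rl].copy()
                is_t = read == sense_t
                if lab:
                    n_lab += 1
                    conv = is_t & (rng.random(rl) < config.conversion_rate)
                    read[conv] = sense_c
                else:
                    conv = np.zeros(rl, dtype=bool)
                # sequencing error: per-substitution rate, any base not
                # already chemistry-converted
                err = (~conv) & (rng.random(rl) < 3.0 * config.error_rate)
                if err.any():
                    idx = np.flatnonzero(err)
                    shift = rng.integers(1, 4, size=idx.size)
                    codes = np.searchsorted(_BASES, read[idx])
                    read[idx] = _BASES[(codes + shift) % 4]
                a = pysam.AlignedSegment(header)
                a.query_name = f"{sample_id}:{g.gene_id}:{start}"
                a.query_sequence = read.tobytes().decode()
                a.flag = 0 if g.strand == "+" else 16
                a.reference_id = tid
                a.reference_start = int(start)
                a.mapping_quality = 60
                a.cigarstring = f"{rl}M"
                a.query_qualities = pysam.qualitystring_to_array("I" * rl)
                a.set_tag("NH", 1)
                sam.write(a)
            truth_rows.append(
                {
                    "gene": g.gene_id,
                    "sample": sample_id,
                    "group": group,
                    "n_reads": n,
                    "n_labelled": int(n_lab),
                    "labelled_fraction": f,
                    "expected_tc_fraction": f * config.conversion_rate
                    + (1.0 - f) * config.error_rate,
                }
            )
    return pd.DataFrame(truth_rows)


def _replicate_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def simulate_experiment(
    config: SimConfig,
    out_dir: str | Path,
    gene_panel: list[GeneSpec] | None = None,
    seqs: dict[str, str] | None = None,
    windows: pd.DataFrame | None = None,
    force: bool = False,
) -> Path:
    """Simulate a full Cre+/Cre- experiment into a directory.

    Writes ``reference.fa``, ``windows.bed``, one ``<sample>.sam`` per
    animal, ``samples.tsv`` (sample_id, group, replicate), ``truth.tsv``
    (per gene x sample generative truth plus SNP offsets) and an echo of the
    configuration.  Deterministic for a given config; refuses to write into
    a non-empty directory unless ``force``.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty; pass force=True to overwrite")
    out.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2**20]))
    if gene_panel is None:
        seqs, windows, gene_panel = generate_reference(
            config.n_genes,
            (config.length_min, config.length_max),
            config.gc_content,
            seed=int(rng.integers(2**31 - 1)),
            read_length=config.read_length,
            expression=config.expression,
        )
        if config.n_labelled > 0:
            chosen = rng.choice(
                len(gene_panel), size=min(config.n_labelled, len(gene_panel)), replace=False
            )
            for i in chosen:
                gene_panel[i].labelled_fraction_pos = config.labelled_fraction_pos
                gene_panel[i].labelled_fraction_neg = config.labelled_fraction_neg
    if seqs is None or windows is None:
        raise ValueError("a gene panel requires matching sequences and windows")

    # genomic SNPs: one T->C per selected gene, at a sense-T window offset
    snps: dict[str, tuple[int, ...]] = {}
    if config.snp_fraction > 0:
        for g in gene_panel:
            if g.t_positions and rng.random() < config.snp_fraction:
                snps[g.gene_id] = (int(rng.choice(g.t_positions)),)
    # SNP sites are no longer sense-T in the genome of these animals
    for g in gene_panel:
        if g.gene_id in snps:
            g.t_positions = tuple(
                p for p in g.t_positions if p not in snps[g.gene_id]
            )

    write_reference(seqs, out / "reference.fa")
    write_bed(windows, out / "windows.bed")
    config.to_yaml(out / "config.yaml")

    sample_rows = []
    truths = []
    seeds = _replicate_seeds(config.seed, config.n_pos + config.n_neg)
    idx = 0
    for group, count in (("cre_pos", config.n_pos), ("cre_neg", config.n_neg)):
        for rep in range(1, count + 1):
            sid = f"{'pos' if group == 'cre_pos' else 'neg'}_{rep}"
            truth = simulate_sample(
                gene_panel,
                seqs,
                windows,
                group,
                config,
                seeds[idx],
                out / f"{sid}.sam",
                sid,
                snps=snps,
            )
            truths.append(truth)
            sample_rows.append((sid, group, rep))
            idx += 1

    pd.DataFrame(sample_rows, columns=["sample_id", "group", "replicate"]).to_csv(
        out / "samples.tsv", sep="\t", index=False
    )
    truth = pd.concat(truths, ignore_index=True)
    truth["snp_offsets"] = truth["gene"].map(
        lambda gid: ",".join(str(p) for p in snps.get(gid, ())) or "."
    )
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    return out


def simulate_count_table(
    n_genes: int,
    sheet: pd.DataFrame,
    coverage_range: tuple[int, int],
    mu_pos: float | np.ndarray,
    mu_neg: float | np.ndarray,
    rho: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a (gene x sample) conversion-count table directly.

    Statistical-level counterpart of the read simulator for studies of the
    test itself: per gene and sample, T coverage is uniform over
    ``coverage_range`` and the conversion count beta-binomial with the
    group's mean and common intra-class correlation ``rho`` (binomial at
    ``rho = 0``).
    """
    rng = np.random.default_rng(seed)
    lo, hi = coverage_range
    mu_pos = np.broadcast_to(np.asarray(mu_pos, dtype=float), (n_genes,))
    mu_neg = np.broadcast_to(np.asarray(mu_neg, dtype=float), (n_genes,))
    rows = []
    width = len(str(n_genes))
    for i in range(n_genes):
        gid = f"gene{i + 1:0{width}d}"
        for sid, grp in zip(sheet["sample_id"], sheet["group"]):
            mu = mu_pos[i] if grp == "cre_pos" else mu_neg[i]
            n = int(rng.integers(lo, hi + 1))
            if rho > 0 and 0.0 < mu < 1.0:
                a = mu * (1 - rho) / rho
                b = (1 - mu) * (1 - rho) / rho
                p = rng.beta(a, b)
            else:
                p = mu
            k = int(rng.binomial(n, p))
            rows.append((gid, sid, n, k))
    df = pd.DataFrame(rows, columns=["gene", "sample", "t_coverage", "tc_count"])
    df["tc_fraction"] = df["tc_count"] / df["t_coverage"]
    return df
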