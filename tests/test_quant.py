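"""Tests for conversion counting, SNP masking and table merging."""

from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import pytest

from slamitseq.quant import (
    QuantParams,
    SNPMask,
    call_snps,
    count_conversions,
    merge_samples,
    read_reference,
    read_windows,
)


# ------------------------------------------------------------ SAM helpers


def _write_sam(path, seqs, reads):
    """Write a minimal SAM; each read is a dict of segment fields."""
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": n, "LN": len(s)} for n, s in seqs.items()],
        }
    )
    with pysam.AlignmentFile(str(path), "w", header=header) as fh:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment(header)
            a.query_name = r.get("name", f"r{i}")
            a.query_sequence = r["seq"]
            a.flag = r.get("flag", 0)
            a.reference_id = header.get_tid(r["contig"])
            a.reference_start = r["start"]
            a.mapping_quality = 60
            a.cigarstring = r.get("cigar", f"{len(r['seq'])}M")
            qual = r.get("qual", "I" * len(r["seq"]))
            a.query_qualities = pysam.qualitystring_to_array(qual)
            a.set_tag("NH", r.get("nh", 1))
            fh.write(a)


@pytest.fixture()
def plus_gene(tmp_path):
    """One plus-strand gene: window [10, 50) with T at offsets 0,4,...,36."""
    seqs = {"g1": "A" * 10 + "TGCA" * 10 + "A" * 10}
    windows = pd.DataFrame(
        [("g1", 10, 50, "g1", 0, "+")],
        columns=["contig", "start", "end", "name", "score", "strand"],
    )
    return tmp_path, seqs, windows


def _count(tmp_path, seqs, windows, reads, params=None, mask=None):
    sam = tmp_path / "t.sam"
    _write_sam(sam, seqs, reads)
    return count_conversions(sam, seqs, windows, mask, params or QuantParams())


# -------------------------------------------------------- counting basics


def test_perfect_match_counts_untrimmed_ts_no_conversions(plus_gene):
    tmp_path, seqs, windows = plus_gene
    read = {"contig": "g1", "start": 10, "seq": seqs["g1"][10:50]}
    df = _count(tmp_path, seqs, windows, [read])
    # T window-offsets 0,4,8 fall in query positions < trim5=12; the
    # remaining 7 of the 10 window Ts are counted, none converted
    assert df.loc[0, ["t_coverage", "tc_count"]].tolist() == [7, 0]
    assert df.loc[0, "tc_fraction"] == 0.0


def test_conversion_counted_only_outside_trim(plus_gene):
    tmp_path, seqs, windows = plus_gene
    body = list(seqs["g1"][10:50])
    body[4] = "C"   # T at query pos 4: inside the 5' trim, must be ignored
    body[16] = "C"  # T at query pos 16: counted as a conversion
    df = _count(tmp_path, seqs, windows, [{"contig": "g1", "start": 10, "seq": "".join(body)}])
    # the trimmed site is also removed from coverage, so 6 Ts + 1 converted
    assert df.loc[0, "t_coverage"] == 7
    assert df.loc[0, "tc_count"] == 1


def test_non_t_mismatches_are_ignored(plus_gene):
    tmp_path, seqs, windows = plus_gene
    body = list(seqs["g1"][10:50])
    body[13] = "T"  # G>T at a non-T site: irrelevant to T>C counting
    body[20] = "A"  # T>A at a T site: coverage but not conversion
    df = _count(tmp_path, seqs, windows, [{"contig": "g1", "start": 10, "seq": "".join(body)}])
    assert df.loc[0, "t_coverage"] == 7
    assert df.loc[0, "tc_count"] == 0


def test_low_quality_base_is_excluded_from_coverage(plus_gene):
    tmp_path, seqs, windows = plus_gene
    qual = ["I"] * 40
    qual[16] = "#"  # Q2 at the T in query pos 16
    read = {"contig": "g1", "start": 10, "seq": seqs["g1"][10:50], "qual": "".join(qual)}
    df = _count(tmp_path, seqs, windows, [read])
    assert df.loc[0, "t_coverage"] == 6


def test_antisense_read_is_not_counted(plus_gene):
    tmp_path, seqs, windows = plus_gene
    read = {"contig": "g1", "start": 10, "seq": seqs["g1"][10:50], "flag": 16}
    df = _count(tmp_path, seqs, windows, [read])
    assert df.loc[0, "t_coverage"] == 0
    assert np.isnan(df.loc[0, "tc_fraction"])


def test_multimapper_and_secondary_reads_are_dropped(plus_gene):
    tmp_path, seqs, windows = plus_gene
    body = seqs["g1"][10:50]
    reads = [
        {"contig": "g1", "start": 10, "seq": body, "nh": 101},
        {"contig": "g1", "start": 10, "seq": body, "flag": 0x100},
    ]
    df = _count(tmp_path, seqs, windows, reads)
    assert df.loc[0, "t_coverage"] == 0
    assert df.attrs["filter_stats"]["multimapper"] == 1
    assert df.attrs["filter_stats"]["secondary"] == 1


def test_masked_site_contributes_nothing(plus_gene):
    tmp_path, seqs, windows = plus_gene
    body = list(seqs["g1"][10:50])
    body[16] = "C"
    mask = SNPMask({("g1", 10 + 16)})
    df = _count(
        tmp_path, seqs, windows, [{"contig": "g1", "start": 10, "seq": "".join(body)}], mask=mask
    )
    assert df.loc[0, "t_coverage"] == 6
    assert df.loc[0, "tc_count"] == 0


def test_minus_strand_window_counts_a_to_g(tmp_path):
    # minus-strand gene: sense T is a plus-strand A, conversion a G; the 5'
    # trim applies to the read's 3' end in reference coordinates
    seqs = {"g2": "C" * 10 + "AGCT" * 10 + "C" * 10}
    windows = pd.DataFrame(
        [("g2", 10, 50, "g2", 0, "-")],
        columns=["contig", "start", "end", "name", "score", "strand"],
    )
    body = list(seqs["g2"][10:50])
    body[8] = "G"   # A at query pos 8 -> five_prime = 39-8 = 31 >= 12: counted
    body[32] = "G"  # A at query pos 32 -> five_prime = 7 < 12: trimmed
    df = _count(
        tmp_path, seqs, windows, [{"contig": "g2", "start": 10, "seq": "".join(body), "flag": 16}]
    )
    # A offsets 0..36 step 4; offsets 28,32,36 have five_prime < 12
    assert df.loc[0, "t_coverage"] == 7
    assert df.loc[0, "tc_count"] == 1


def test_trim_monotonically_reduces_coverage(plus_gene):
    tmp_path, seqs, windows = plus_gene
    read = {"contig": "g1", "start": 10, "seq": seqs["g1"][10:50]}
    covs = [
        _count(tmp_path, seqs, windows, [read], params=QuantParams(trim5=t)).loc[0, "t_coverage"]
        for t in (0, 12, 24, 40)
    ]
    assert covs[0] == 10
    assert covs == sorted(covs, reverse=True)
    assert covs[-1] == 0


def test_read_overlapping_window_edge_counts_partial(plus_gene):
    tmp_path, seqs, windows = plus_gene
    # read starts before the window; only in-window positions count
    read = {"contig": "g1", "start": 0, "seq": seqs["g1"][0:40]}
    df = _count(tmp_path, seqs, windows, [read])
    # window offsets covered: 0..29; T offsets 0..28 at query pos 10+off,
    # all >= trim5 except none (qpos starts at 10, 10+0=10 < 12 trims off 0)
    expect = sum(1 for off in range(0, 30, 4) if 10 + off >= 12)
    assert df.loc[0, "t_coverage"] == expect


# ----------------------------------------------------------- input checks


def test_read_windows_rejects_bad_strand(tmp_path):
    p = tmp_path / "bad.bed"
    p.write_text("g1\t0\t10\tg1\t0\t.\n")
    with pytest.raises(ValueError):
        read_windows(p)


def test_header_contig_mismatch_is_an_error(plus_gene):
    tmp_path, seqs, windows = plus_gene
    sam = tmp_path / "t.sam"
    _write_sam(sam, seqs, [{"contig": "g1", "start": 10, "seq": seqs["g1"][10:50]}])
    with pytest.raises(ValueError):
        count_conversions(sam, {"g1": "A" * 5}, windows, None, QuantParams())
    with pytest.raises(ValueError):
        count_conversions(sam, {"other": seqs["g1"]}, windows.assign(contig="other", name="other"), None, QuantParams())


def test_unsorted_header_is_rejected(plus_gene):
    tmp_path, seqs, windows = plus_gene
    sam = tmp_path / "u.sam"
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "unsorted"}, "SQ": [{"SN": "g1", "LN": len(seqs["g1"])}]}
    )
    with pysam.AlignmentFile(str(sam), "w", header=header):
        pass
    with pytest.raises(ValueError):
        count_conversions(sam, seqs, windows, None, QuantParams())


def test_quant_params_validation_and_yaml(tmp_path):
    with pytest.raises(ValueError):
        QuantParams(trim5=-1)
    with pytest.raises(ValueError):
        QuantParams(min_var_fraction=0.0)
    p = QuantParams(trim5=5, min_base_quality=20)
    p.to_yaml(tmp_path / "q.yaml")
    assert QuantParams.from_yaml(tmp_path / "q.yaml") == p


# ------------------------------------------------------------ SNP masking


def test_call_snps_masks_homozygous_sites_only(plus_gene):
    tmp_path, seqs, windows = plus_gene
    body_var = list(seqs["g1"][10:50])
    body_var[20] = "C"  # every read converted at offset 20: genomic variant
    reads = [{"contig": "g1", "start": 10, "seq": "".join(body_var)} for _ in range(20)]
    body_once = list(seqs["g1"][10:50])
    body_once[28] = "C"  # 1/21 converted at offset 28: labelling-scale signal
    reads.append({"contig": "g1", "start": 10, "seq": "".join(body_once)})
    sam = tmp_path / "pool.sam"
    _write_sam(sam, seqs, reads)
    mask = call_snps([sam], seqs, windows, QuantParams())
    assert mask == SNPMask({("g1", 30)})


def test_call_snps_needs_minimum_coverage(plus_gene):
    tmp_path, seqs, windows = plus_gene
    body = list(seqs["g1"][10:50])
    body[20] = "C"
    reads = [{"contig": "g1", "start": 10, "seq": "".join(body)} for _ in range(5)]
    sam = tmp_path / "lo.sam"
    _write_sam(sam, seqs, reads)
    assert len(call_snps([sam], seqs, windows, QuantParams())) == 0  # cov 5 < 10
    assert len(call_snps([sam], seqs, windows, QuantParams(min_snp_coverage=5))) == 1


def test_call_snps_never_masks_non_t_sites(plus_gene):
    tmp_path, seqs, windows = plus_gene
    body = list(seqs["g1"][10:50])
    body[13] = "C"  # G>C at a non-T site
    reads = [{"contig": "g1", "start": 10, "seq": "".join(body)} for _ in range(20)]
    sam = tmp_path / "g.sam"
    _write_sam(sam, seqs, reads)
    assert len(call_snps([sam], seqs, windows, QuantParams())) == 0


# ------------------------------------------------------ independent oracle


def _oracle_counts(sam_path, seqs, windows, mask, params):
    """Plain-python per-read re-derivation of the counting rules."""
    per_gene = {w.name: [0, 0] for w in windows.itertuples(index=False)}
    with pysam.AlignmentFile(str(sam_path), "r") as fh:
        for read in fh.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if (read.get_tag("NH") if read.has_tag("NH") else 1) > params.max_alignments:
                continue
            quals = read.query_qualities
            qlen = read.query_length
            for w in windows.itertuples(index=False):
                if w.contig != read.reference_name:
                    continue
                if read.is_reverse != (w.strand == "-"):
                    continue
                sense_t = "T" if w.strand == "+" else "A"
                conv = "C" if w.strand == "+" else "G"
                for qi, ri in read.get_aligned_pairs(matches_only=True):
                    if not (w.start <= ri < w.end):
                        continue
                    if seqs[w.contig][ri] != sense_t:
                        continue
                    if quals[qi] < params.min_base_quality:
                        continue
                    fp = qi if not read.is_reverse else qlen - 1 - qi
                    if fp < params.trim5:
                        continue
                    if mask is not None and (w.contig, ri) in mask:
                        continue
                    per_gene[w.name][0] += 1
                    if read.query_sequence[qi] == conv:
                        per_gene[w.name][1] += 1
    return per_gene


def test_counts_match_independent_oracle_on_simulated_data(demo_experiment):
    cfg, out = demo_experiment
    seqs = read_reference(out / "reference.fa")
    windows = read_windows(out / "windows.bed")
    params = QuantParams()
    sams = sorted(out.glob("*.sam"))
    mask = call_snps(sams, seqs, windows, params)
    for sam in (out / "pos_1.sam", out / "neg_2.sam"):
        df = count_conversions(sam, seqs, windows, mask, params).set_index("gene")
        oracle = _oracle_counts(sam, seqs, windows, mask, params)
        for gene, (cov, tc) in oracle.items():
            assert df.loc[gene, "t_coverage"] == cov, gene
            assert df.loc[gene, "tc_count"] == tc, gene


def test_snp_mask_recovers_simulated_variants(demo_experiment):
    cfg, out = demo_experiment
    seqs = read_reference(out / "reference.fa")
    windows = read_windows(out / "windows.bed").set_index("name", drop=False)
    truth = pd.read_csv(out / "truth.tsv", sep="\t").drop_duplicates("gene")
    expected = set()
    for _, r in truth[truth["snp_offsets"] != "."].iterrows():
        for off in str(r["snp_offsets"]).split(","):
            expected.add((r["gene"], int(windows.loc[r["gene"], "start"]) + int(off)))
    mask = call_snps(sorted(out.glob("*.sam")), seqs, windows.reset_index(drop=True), QuantParams())
    # every simulated homozygous variant is masked; chemistry/labelling
    # noise may add at most a handful of extra sites at this depth
    assert expected <= mask.sites
    assert len(mask.sites - expected) <= 2


def test_sam_and_bam_give_identical_counts(demo_experiment, tmp_path):
    cfg, out = demo_experiment
    seqs = read_reference(out / "reference.fa")
    windows = read_windows(out / "windows.bed")
    sam = out / "pos_1.sam"
    bam = tmp_path / "pos_1.bam"
    with pysam.AlignmentFile(str(sam), "r") as ih, pysam.AlignmentFile(
        str(bam), "wb", header=ih.header
    ) as oh:
        for read in ih.fetch(until_eof=True):
            oh.write(read)
    a = count_conversions(sam, seqs, windows, None, QuantParams(), sample_id="x")
    b = count_conversions(bam, seqs, windows, None, QuantParams(), sample_id="x")
    pd.testing.assert_frame_equal(a, b)


def test_error_free_fractions_recover_the_conversion_product(tmp_path):
    from slamitseq.simulate import SimConfig, simulate_experiment

    cfg = SimConfig(
        seed=17, n_genes=6, n_labelled=6, error_rate=0.0, expression=400.0,
        length_min=300, length_max=380,
    )
    out = simulate_experiment(cfg, tmp_path / "exp")
    seqs = read_reference(out / "reference.fa")
    windows = read_windows(out / "windows.bed")
    cov = tc = 0
    for i in range(1, 5):
        df = count_conversions(out / f"pos_{i}.sam", seqs, windows, None, QuantParams())
        cov += df["t_coverage"].sum()
        tc += df["tc_count"].sum()
    p = cfg.labelled_fraction_pos * cfg.conversion_rate
    assert abs(tc / cov - p) < 3 * np.sqrt(p * (1 - p) / cov)
    # Cre- samples carry no conversions at all without sequencing error
    for i in range(1, 4):
        df = count_conversions(out / f"neg_{i}.sam", seqs, windows, None, QuantParams())
        assert df["tc_count"].sum() == 0


# ----------------------------------------------------------------- merging


def _mini_table(sample, genes, cov=100, tc=1):
    return pd.DataFrame(
        {
            "gene": genes,
            "sample": sample,
            "t_coverage": cov,
            "tc_count": tc,
            "tc_fraction": tc / cov,
        }
    )


def test_merge_builds_full_cross_product(sheet_4v3):
    tables = [_mini_table(s, ["gA", "gB"]) for s in sheet_4v3["sample_id"]]
    merged = merge_samples(tables, sheet_4v3)
    assert len(merged) == 2 * 7
    assert set(merged["sample"]) == set(sheet_4v3["sample_id"])


def test_merge_fills_absent_genes_with_zero(sheet_4v3):
    tables = [_mini_table(s, ["gA", "gB"]) for s in sheet_4v3["sample_id"]]
    tables[0] = _mini_table("pos_1", ["gA"])  # gB unobserved in pos_1
    merged = merge_samples(tables, sheet_4v3).set_index(["gene", "sample"])
    assert merged.loc[("gB", "pos_1"), "t_coverage"] == 0
    assert np.isnan(merged.loc[("gB", "pos_1"), "tc_fraction"])


def test_merge_rejects_duplicates_and_missing_samples(sheet_4v3):
    tables = [_mini_table(s, ["gA"]) for s in sheet_4v3["sample_id"]]
    with pytest.raises(ValueError, match="duplicate"):
        merge_samples(tables + [tables[0]], sheet_4v3)
    with pytest.raises(ValueError, match="missing"):
        merge_samples(tables[:-1], sheet_4v3)


def test_merge_is_invariant_to_table_order(sheet_4v3):
    tables = [_mini_table(s, ["gA", "gB"], cov=100 + i) for i, s in enumerate(sheet_4v3["sample_id"])]
    a = merge_samples(tables, sheet_4v3)
    b = merge_samples(tables[::-1], sheet_4v3)
    pd.testing.assert_frame_equal(a, b)
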