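"""Synthetic-data generator: determinism, planted truth self-consistency."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirlift import SimConfig, make_source_catalog
from mirlift._scan import hamming, reverse_complement
from mirlift.io import mean_quality, write_fasta
from mirlift.simulate import (
    CT_SENTINEL,
    GroundTruth,
    plant_genome,
    simulate_ct,
    simulate_reads,
)


def fasta_bytes(records):
    buf = io.StringIO()
    for name, seq in records.items():
        buf.write(f">{name}\n{seq}\n")
    return buf.getvalue()


def test_empty_catalog():
    cat = make_source_catalog(SimConfig(seed=3, n_precursors=0, n_decoy_copies=0,
                                        n_family_collisions=0))
    assert cat.precursors == {} and cat.matures == {}


def test_catalog_byte_identical_across_runs():
    cfgs = [SimConfig(seed=1, n_precursors=10, n_family_collisions=1) for _ in range(2)]
    a, b = (make_source_catalog(c) for c in cfgs)
    assert fasta_bytes(a.precursors) == fasta_bytes(b.precursors)
    assert fasta_bytes(a.matures) == fasta_bytes(b.matures)


def test_different_seed_differs():
    a = make_source_catalog(SimConfig(seed=1, n_precursors=10))
    b = make_source_catalog(SimConfig(seed=2, n_precursors=10))
    assert fasta_bytes(a.precursors) != fasta_bytes(b.precursors)


def test_every_mature_is_substring_of_named_precursor():
    cat = make_source_catalog(SimConfig(seed=11, n_precursors=50, n_family_collisions=5))
    truth = {m.name: m for m in cat.mature_truth if m.annotated}
    assert set(truth) == set(cat.matures)
    for name, seq in cat.matures.items():
        mt = truth[name]
        assert seq in cat.precursors[mt.precursor]
        assert cat.precursors[mt.precursor][mt.offset : mt.offset + mt.length] == seq


def test_suffixless_fraction_and_family_naming():
    cfg = SimConfig(seed=5, n_precursors=40, n_family_collisions=2, frac_suffixless=1.0)
    cat = make_source_catalog(cfg)
    for a, b in cat.family_pairs:
        assert a[-1] == "a" and b[-1] == "b" and a[:-1] == b[:-1]
    single_arm = [
        m for m in cat.mature_truth
        if m.annotated and len(cat.matures_of(m.precursor)) == 1
    ]
    assert single_arm and all(not m.name.endswith(("5p", "3p")) for m in single_arm)


class TestPlantGenome:
    def test_identity_one_plants_verbatim(self):
        cfg = SimConfig(seed=2, n_precursors=8, genome_len=20_000,
                        planted_identity_range=(1.0, 1.0), n_decoy_copies=0,
                        n_family_collisions=0)
        cat = make_source_catalog(cfg)
        genome, gt = plant_genome(cat, cfg)
        for row in gt.precursors.itertuples():
            window = genome[row.chrom][row.start : row.end]
            if row.strand == "-":
                window = reverse_complement(window)
            assert window == cat.precursors[row.name]
            assert row.mismatches == 0

    def test_truth_mismatches_equal_recomputed_hamming(self):
        cfg = SimConfig(seed=9, n_precursors=25, genome_len=60_000,
                        n_decoy_copies=3, n_family_collisions=2)
        cat = make_source_catalog(cfg)
        genome, gt = plant_genome(cat, cfg)
        for row in gt.precursors.itertuples():
            window = genome[row.chrom][row.start : row.end]
            if row.strand == "-":
                window = reverse_complement(window)
            assert window == row.planted_seq
            assert hamming(cat.precursors[row.name], window) == row.mismatches
        for row in gt.decoys.itertuples():
            window = genome[row.chrom][row.start : row.end]
            if row.strand == "-":
                window = reverse_complement(window)
            assert hamming(cat.precursors[row.name], window) == row.mismatches

    def test_decoys_marked_ambiguous_with_equal_mismatches(self):
        cfg = SimConfig(seed=4, n_precursors=15, genome_len=40_000, n_decoy_copies=4,
                        n_family_collisions=0)
        cat = make_source_catalog(cfg)
        _, gt = plant_genome(cat, cfg)
        flagged = gt.precursors[gt.precursors.ambiguous]
        assert len(flagged) == 4 == len(gt.decoys)
        primary = flagged.set_index("name")["mismatches"]
        for row in gt.decoys.itertuples():
            assert row.mismatches == primary[row.name]


class TestSimulateReads:
    def test_error_free_reads_are_precursor_substrings(self, small_cfg, small_study):
        result, cat, gt = small_study
        reads = simulate_reads(cat, gt, small_cfg)
        planted = list(gt.precursors.planted_seq)
        for name, seq, qual in reads["K1"][:500]:
            if len(seq) < 18:  # spiked junk
                continue
            assert any(seq in p for p in planted)

    def test_read_conservation_counts_plus_junk(self, small_cfg):
        cat = make_source_catalog(small_cfg)
        _, gt = plant_genome(cat, small_cfg)
        reads = simulate_reads(cat, gt, small_cfg)
        junk = gt.junk.set_index("sample")
        for sample in gt.counts.columns:
            expected = gt.counts[sample].sum() + junk.loc[sample, "low_quality"] + junk.loc[sample, "short"]
            assert len(reads[sample]) == expected

    def test_fastq_deterministic(self):
        cfg = SimConfig(seed=13, n_precursors=6, genome_len=15_000, n_decoy_copies=0,
                        n_family_collisions=0, expression_log_mean=1.2)
        out = []
        for _ in range(2):
            cat = make_source_catalog(cfg)
            _, gt = plant_genome(cat, cfg)
            out.append(simulate_reads(cat, gt, cfg))
        assert out[0] == out[1]

    def test_substitution_rate_within_binomial_bounds(self):
        cfg = SimConfig(seed=21, n_precursors=10, genome_len=25_000, n_decoy_copies=0,
                        n_family_collisions=0, seq_error_rate=0.01,
                        frac_low_quality=0.0, frac_short=0.0, n_samples=1,
                        expression_log_mean=1.8, expression_log_sd=0.4)
        cat = make_source_catalog(cfg)
        _, gt = plant_genome(cat, cfg)
        reads = simulate_reads(cat, gt, cfg)["K1"]
        planted = list(gt.precursors.planted_seq)
        # observed substitutions: min Hamming of each read over all same-length
        # windows of the planted precursors (exact because errors are sparse)
        from mirlift._scan import best_windows

        n_err = n_bases = 0
        for _, seq, _ in reads:
            best = min(best_windows(seq, p)[0] for p in planted)
            n_err += best
            n_bases += len(seq)
        p = cfg.seq_error_rate
        sd = (n_bases * p * (1 - p)) ** 0.5
        assert abs(n_err - n_bases * p) <= 3 * sd

    def test_junk_reads_fail_the_filters(self, small_cfg):
        cfg = SimConfig(**{**small_cfg.__dict__, "frac_low_quality": 0.05,
                           "frac_short": 0.05})
        cat = make_source_catalog(cfg)
        _, gt = plant_genome(cat, cfg)
        reads = simulate_reads(cat, gt, cfg)["K1"]
        junk = gt.junk.set_index("sample").loc["K1"]
        short = [r for r in reads if len(r[1]) < 18]
        lowq = [r for r in reads if len(r[1]) >= 18 and mean_quality(r[2]) < 20]
        assert len(short) == junk.short and len(lowq) == junk.low_quality


def tiny_gt(counts: dict[str, list[int]]) -> GroundTruth:
    samples = [f"K{i+1}" for i in range(len(next(iter(counts.values()))))]
    matures = pd.DataFrame(
        [dict(name=n, precursor=f"p-{n}", offset=2, length=20, arm="5p",
              annotated=True, target_sequence="ACGT" * 5) for n in counts]
    )
    return GroundTruth(
        precursors=pd.DataFrame(), decoys=pd.DataFrame(), matures=matures,
        counts=pd.DataFrame.from_dict(counts, orient="index", columns=samples),
    )


class TestSimulateCt:
    def test_zero_count_gives_sentinel(self):
        cfg = SimConfig(seed=1, ct_noise_sd=0.0, frac_assay_mismatch=0.0,
                        n_offtarget_assays=0)
        ct = simulate_ct(tiny_gt({"m1": [0, 0, 0]}), cfg)
        assert (ct[["K1", "K2", "K3"]].to_numpy() == CT_SENTINEL).all()

    def test_doubling_count_lowers_ct_by_slope_log2(self):
        cfg = SimConfig(seed=1, ct_noise_sd=0.0, frac_assay_mismatch=0.0,
                        n_offtarget_assays=0)
        ct = simulate_ct(tiny_gt({"m1": [100], "m2": [200]}), cfg).set_index("assay_id")
        delta = ct.loc["assay-m1", "K1"] - ct.loc["assay-m2", "K1"]
        assert delta == pytest.approx(cfg.ct_slope * np.log10(2), abs=2e-3)

    def test_rank_correlation_with_expression(self):
        r = np.random.default_rng(5)
        counts = {f"m{i}": [int(10 ** r.uniform(0.5, 4))] for i in range(200)}
        cfg = SimConfig(seed=1, ct_noise_sd=0.5, frac_assay_mismatch=0.0,
                        n_offtarget_assays=0)
        ct = simulate_ct(tiny_gt(counts), cfg).set_index("assay_id")
        log_counts = np.log10([counts[f"m{i}"][0] for i in range(200)])
        neg_ct = -ct["K1"].to_numpy()
        rho = stats.spearmanr(neg_ct, log_counts).statistic
        assert rho > 0.9


def test_write_fasta_roundtrip(tmp_path):
    cat = make_source_catalog(SimConfig(seed=1, n_precursors=5, n_family_collisions=0))
    path = tmp_path / "p.fa"
    write_fasta(cat.precursors, path)
    from mirlift.io import read_fasta

    assert read_fasta(path) == cat.precursors
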