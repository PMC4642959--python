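"""Read filtering, read-to-mature assignment, expression calls, TMM/CPM."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirlift.expression import (
    CountMatrix,
    ReadFilterParams,
    call_expressed,
    expressed_set,
    filter_reads,
    map_reads,
    tmm_normalize,
    top_k,
)

from conftest import mutate_at, random_seq


def q(chars: str) -> str:
    """Phred string from characters (Phred+33)."""
    return chars


def read(seq, qual=None, name="r"):
    return (name, seq, qual if qual is not None else "I" * len(seq))


class TestFilterReads:
    def test_short_read_removed(self):
        kept, acct = filter_reads([read("A" * 17)])
        assert kept == [] and acct["removed_length"] == 1

    def test_good_read_kept(self):
        kept, acct = filter_reads([read("A" * 22, "?" * 22)])  # Q30
        assert len(kept) == 1 and acct["kept"] == 1

    def test_mean_quality_boundary_is_exact(self):
        # 20-nt read with nineteen Q20 and one Q19: mean 19.95 -> removed
        qual = chr(20 + 33) * 19 + chr(19 + 33)
        kept, acct = filter_reads([read("A" * 20, qual)])
        assert kept == [] and acct["removed_quality"] == 1
        # all-Q20: mean exactly 20 -> kept
        kept, _ = filter_reads([read("A" * 20, chr(20 + 33) * 20)])
        assert len(kept) == 1

    @given(
        st.lists(
            st.tuples(st.integers(5, 30), st.integers(2, 41)), max_size=40
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_accounting_conserves_reads(self, spec):
        reads = [
            (f"r{i}", "A" * n, chr(qv + 33) * n) for i, (n, qv) in enumerate(spec)
        ]
        kept, acct = filter_reads(reads)
        assert acct["kept"] + acct["removed_length"] + acct["removed_quality"] == acct["input"]
        assert acct["input"] == len(reads) and acct["kept"] == len(kept)


def brute_force_assign(read_seq, matures, max_mm, max_overhang=2):
    """Independent oracle: exhaustive distance over all allowed alignments."""
    best = {}
    for name, mseq in matures.items():
        short, long_ = sorted([read_seq, mseq], key=len)
        if len(long_) - len(short) > max_overhang:
            continue
        d = min(
            sum(a != b for a, b in zip(short, long_[o : o + len(short)]))
            for o in range(len(long_) - len(short) + 1)
        )
        best[name] = d
    if not best:
        return set()
    dmin = min(best.values())
    if dmin > max_mm:
        return set()
    return {n for n, d in best.items() if d == dmin}


class TestMapReads:
    def test_exact_read_counts_once(self, rng):
        matures = {"m1": random_seq(rng, 22), "m2": random_seq(rng, 22)}
        cm = map_reads({"s": [read(matures["m1"])]}, matures)
        assert cm.counts.loc["m1", "s"] == 1 and cm.counts.loc["m2", "s"] == 0

    def test_one_mismatch_gap_between_modes(self, rng):
        m = random_seq(rng, 22)
        variant = mutate_at(m, [10], rng)
        cm0 = map_reads({"s": [read(variant)]}, {"m": m}, max_mm=0)
        cm1 = map_reads({"s": [read(variant)]}, {"m": m}, max_mm=1)
        assert cm0.counts.loc["m", "s"] == 0
        assert cm1.counts.loc["m", "s"] == 1

    def test_length_jitter_within_overhang_matches(self, rng):
        m = random_seq(rng, 22)
        cm = map_reads({"s": [read(m[:20]), read(m + "A")]}, {"m": m})
        # 3'-trimmed read and read overhanging the mature's 3' end both match
        assert cm.counts.loc["m", "s"] == 2

    def test_beyond_overhang_does_not_match(self, rng):
        m = random_seq(rng, 24)
        cm = map_reads({"s": [read(m[:20])]}, {"m": m})  # 4 nt overhang
        assert cm.counts.loc["m", "s"] == 0

    def test_empty_mature_set_errors(self):
        with pytest.raises(ValueError):
            map_reads({"s": []}, {})

    @pytest.mark.parametrize("max_mm", [0, 1])
    def test_recovery_equals_brute_force_oracle(self, max_mm):
        r = np.random.default_rng(77)
        matures = {f"m{i}": random_seq(r, int(r.integers(18, 25))) for i in range(30)}
        reads = []
        expected = {name: 0 for name in matures}
        for _ in range(400):
            src = f"m{int(r.integers(0, 30))}"
            seq = matures[src]
            if r.random() < 0.3:
                seq = seq[: len(seq) - int(r.integers(0, 3))]
            if r.random() < 0.3:
                seq = mutate_at(seq, [int(r.integers(0, len(seq)))], r)
            reads.append(read(seq))
            for name in brute_force_assign(seq, matures, max_mm):
                expected[name] += 1
        cm = map_reads({"s": reads}, matures, max_mm=max_mm)
        assert dict(cm.counts["s"]) == expected

    def test_error_free_simulated_reads_recover_truth(self, small_study):
        result, cat, gt = small_study
        # pipeline 0-mm counts equal the generator's true counts exactly
        for old, new in result.name_map.items():
            if old in gt.counts.index:
                assert (result.matrix_0mm.counts.loc[new].to_numpy()
                        == gt.counts.loc[old].to_numpy()).all()

    def test_multi_assignment_flagged(self, rng):
        seq = random_seq(rng, 22)
        cm = map_reads({"s": [read(seq)]}, {"a": seq, "b": seq})
        assert cm.counts.loc["a", "s"] == 1 and cm.counts.loc["b", "s"] == 1
        assert cm.accounting.loc[0, "multi_assigned"] == 1
        assert cm.accounting.loc[0, "assigned"] == 1  # counted once in totals


class TestCallExpressed:
    def make(self, rows):
        return CountMatrix(pd.DataFrame(rows, columns=["K1", "K2", "K3"]).T.T)

    @pytest.mark.parametrize(
        "counts,expressed",
        [((5, 5, 5), True), ((0, 0, 0), False), ((7, 7, 0), False), ((14, 1, 0), True)],
    )
    def test_combined_threshold(self, counts, expressed):
        cm = CountMatrix(pd.DataFrame({"K1": [counts[0]], "K2": [counts[1]],
                                       "K3": [counts[2]]}, index=["m"]))
        (call,) = call_expressed(cm, min_total=15)
        assert call.expressed is expressed
        assert call.total == sum(counts)

    @given(st.lists(st.tuples(st.integers(0, 30), st.integers(0, 30)), min_size=1, max_size=20))
    @settings(max_examples=40, deadline=None)
    def test_expressed_set_monotone_in_threshold(self, rows):
        cm = CountMatrix(pd.DataFrame(rows, columns=["K1", "K2"],
                                      index=[f"m{i}" for i in range(len(rows))]))
        for t in (5, 10, 15):
            assert expressed_set(call_expressed(cm, t + 1)) <= expressed_set(
                call_expressed(cm, t)
            )


def reference_tmm(counts: pd.DataFrame, trim_m=0.3, trim_a=0.05) -> pd.Series:
    """Independent plain-Python reimplementation of the TMM factor formula."""
    import math

    lib = {s: counts[s].sum() for s in counts.columns}
    uq = {}
    for s in counts.columns:
        uq[s] = counts[s].quantile(0.75) / lib[s]
    mean_uq = sum(uq.values()) / len(uq)
    ref = min(uq, key=lambda s: (abs(uq[s] - mean_uq), list(counts.columns).index(s)))
    logf = {}
    for s in counts.columns:
        pairs = [
            (yk, yr)
            for yk, yr in zip(counts[s], counts[ref])
            if yk > 0 and yr > 0
        ]
        if not pairs:
            logf[s] = 0.0
            continue
        m = [math.log2((yk / lib[s]) / (yr / lib[ref])) for yk, yr in pairs]
        a = [0.5 * math.log2((yk / lib[s]) * (yr / lib[ref])) for yk, yr in pairs]
        w = [
            (lib[s] - yk) / (lib[s] * yk) + (lib[ref] - yr) / (lib[ref] * yr)
            for yk, yr in pairs
        ]
        if max(abs(x) for x in m) < 1e-6:
            logf[s] = 0.0
            continue
        n = len(m)
        lo_m, hi_m = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
        lo_a, hi_a = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)

        def ranks(vals):
            order = sorted(range(n), key=lambda i: vals[i])
            rk = [0.0] * n
            i = 0
            while i < n:
                j = i
                while j + 1 < n and vals[order[j + 1]] == vals[order[i]]:
                    j += 1
                avg = (i + j) / 2 + 1
                for t in range(i, j + 1):
                    rk[order[t]] = avg
                i = j + 1
            return rk

        rm, ra = ranks(m), ranks(a)
        num = den = 0.0
        for i in range(n):
            if lo_m <= rm[i] <= hi_m and lo_a <= ra[i] <= hi_a and w[i] > 0:
                num += m[i] / w[i]
                den += 1.0 / w[i]
        logf[s] = num / den if den else 0.0
    mean_log = sum(logf.values()) / len(logf)
    return pd.Series({s: 2.0 ** (v - mean_log) for s, v in logf.items()})


class TestTMM:
    def random_matrix(self, seed, n=200, k=3):
        r = np.random.default_rng(seed)
        lam = 10 ** r.uniform(0, 3, size=n)
        data = {f"S{i}": r.poisson(lam * r.uniform(0.5, 2.0)) for i in range(k)}
        df = pd.DataFrame(data, index=[f"m{i}" for i in range(n)])
        return df[df.sum(axis=1) > 0]

    def test_identical_columns_unit_factors_plain_cpm(self):
        col = [10, 100, 1000, 5]
        cm = CountMatrix(pd.DataFrame({"A": col, "B": col}))
        out = tmm_normalize(cm)
        assert np.allclose(out.norm_factors, 1.0)
        assert np.allclose(out.norm, cm.cpm())
        assert np.allclose(out.norm.sum(axis=0), 1e6)

    def test_global_scaling_absorbed_by_library_size(self):
        a = np.array([10, 100, 1000, 5, 60])
        cm = CountMatrix(pd.DataFrame({"A": a, "B": 2 * a}))
        out = tmm_normalize(cm)
        assert np.allclose(out.norm_factors, 1.0)
        assert np.allclose(out.norm["A"], out.norm["B"])

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_independent_implementation(self, seed):
        counts = self.random_matrix(seed)
        out = tmm_normalize(CountMatrix(counts))
        ref = reference_tmm(counts)
        assert np.allclose(out.norm_factors, ref[out.norm_factors.index], atol=1e-6)
        assert np.isclose(np.exp(np.mean(np.log(out.norm_factors))), 1.0, atol=1e-9)

    def test_matches_edger_reference(self, tmp_path):
        """Factors agree with edgeR's calcNormFactors on the same counts."""
        import subprocess

        counts = self.random_matrix(99, n=300, k=4)
        tsv = tmp_path / "counts.tsv"
        counts.to_csv(tsv, sep="\t", index=False)
        script = tmp_path / "tmm.R"
        script.write_text(
            "suppressMessages(library(edgeR))\n"
            f'x <- as.matrix(read.delim("{tsv}"))\n'
            'cat(sprintf("%.10f\\n", calcNormFactors(x, method="TMM")))\n'
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        edger = np.array([float(v) for v in out.stdout.split()])
        mine = tmm_normalize(CountMatrix(counts)).norm_factors.to_numpy()
        assert np.allclose(mine, edger, atol=1e-6)


class TestTopK:
    def test_unique_max(self):
        cm = CountMatrix(pd.DataFrame({"A": [1, 100, 10]}, index=["x", "y", "z"]))
        assert top_k(cm, 1) == ["y"]

    def test_ties_at_rank_k_all_reported_lexicographic(self):
        cm = CountMatrix(
            pd.DataFrame({"A": [100, 50, 50, 10]}, index=["d", "b", "a", "c"])
        )
        assert top_k(cm, 2) == ["d", "a", "b"]

    def test_seeded_truth_ranking_recovered(self, small_study):
        result, cat, gt = small_study
        # widely separated true abundances must appear in order at the top
        truth_order = gt.counts.sum(axis=1).sort_values(ascending=False)
        mapped = [result.name_map[n] for n in truth_order.index[:3]
                  if n in result.name_map]
        top = top_k(result.norm_matrix, 10)
        assert mapped[0] == top[0]
        assert set(mapped) <= set(top)
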