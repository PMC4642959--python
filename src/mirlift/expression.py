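"""Small RNA-seq quantification of the transferred mature catalog.

Reads are quality/length filtered, assigned to mature miRNAs by a
substitution-only matcher, called expressed at a combined-read threshold,
and normalized by the trimmed-mean-of-M-values (TMM) method with
counts-per-million (CPM) output.

Read-to-mature matching tolerates 3'-style length jitter: a read and a
mature match when the shorter of the two is within ``max_mm`` substitutions
of an equal-length window of the longer, with at most ``max_overhang``
(default 2) nucleotides of the longer sequence left hanging.  IsomiR-type
end variability is universal in small RNA-seq, so an exact-length matcher
would systematically undercount.  A read is credited to *every* mature name
it matches at its best distance; multi-credited reads are reported in the
accounting so fractional schemes can be compared.
"""

from __future__ import annotations

import os
from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .io import iter_fastq


@dataclass(frozen=True)
class ReadFilterParams:
    """Read pre-processing thresholds."""

    min_len: int = 18
    min_mean_q: float = 20.0

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")


@dataclass
class ExpressionCall:
    name: str
    total: int
    expressed: bool
    mismatch_mode: int


@dataclass
class CountMatrix:
    """Per-mature read counts across samples, raw and (optionally) normalized."""

    counts: pd.DataFrame  # matures x samples, integer
    max_mm: int = 0
    norm_factors: pd.Series | None = None
    norm: pd.DataFrame | None = None  # CPM on effective library sizes
    accounting: pd.DataFrame | None = None  # per-sample assignment bookkeeping

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def cpm(self) -> pd.DataFrame:
        """Plain counts-per-million (unit normalization factors)."""
        lib = self.lib_sizes.astype(float)
        return self.counts.div(lib.where(lib > 0, 1.0), axis=1) * 1e6

    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


def filter_reads(
    reads: Iterable[tuple[str, str, str]] | str | os.PathLike,
    params: ReadFilterParams = ReadFilterParams(),
) -> tuple[list[tuple[str, str, str]], dict[str, int]]:
    """Drop short and low-mean-quality reads.

    A read is kept when its length reaches ``min_len`` AND its mean Phred
    score reaches ``min_mean_q``.  The mean is compared exactly on the
    integer score sum (``sum(q) >= min_mean_q * n``), so a 20-nt read with
    mean 19.95 is removed, with no float round-off at the boundary.
    Length is checked first; a short low-quality read counts as removed by
    length.
    """
    if isinstance(reads, (str, os.PathLike)):
        reads = iter_fastq(reads)
    kept: list[tuple[str, str, str]] = []
    acct = {"input": 0, "kept": 0, "removed_length": 0, "removed_quality": 0}
    for name, seq, qual in reads:
        acct["input"] += 1
        n = len(seq)
        if n < params.min_len:
            acct["removed_length"] += 1
            continue
        score_sum = sum(qual.encode("ascii")) - 33 * n
        if score_sum < params.min_mean_q * n:
            acct["removed_quality"] += 1
            continue
        acct["kept"] += 1
        kept.append((name, seq, qual))
    return kept, acct


class _MatureIndex:
    """Hash index over mature windows for 0/1-mismatch lookup with overhang."""

    def __init__(self, matures: dict[str, str], max_overhang: int = 2):
        if not matures:
            raise ValueError("empty mature set")
        self.max_overhang = max_overhang
        # dedupe by (name, sequence); identical names with identical seqs collapse
        uniq = dict(matures)
        # window (mature >= read): every window whose total overhang <= budget
        self.window_index: dict[str, set[str]] = {}
        # full sequences grouped by length (read >= mature case)
        self.full_by_len: dict[int, dict[str, set[str]]] = {}
        for name, seq in uniq.items():
            L = len(seq)
            self.full_by_len.setdefault(L, {}).setdefault(seq, set()).add(name)
            for wl in range(max(1, L - max_overhang), L + 1):
                for off in range(L - wl + 1):
                    self.window_index.setdefault(seq[off : off + wl], set()).add(name)
        self.lengths = sorted(self.full_by_len)

    def _exact(self, read: str) -> set[str]:
        names = set(self.window_index.get(read, ()))
        R = len(read)
        for L in range(max(1, R - self.max_overhang), R):
            table = self.full_by_len.get(L)
            if not table:
                continue
            for off in range(R - L + 1):
                names |= table.get(read[off : off + L], set())
        return names

    def _one_mismatch(self, read: str) -> set[str]:
        names: set[str] = set()
        chars = list(read)
        for i, orig in enumerate(chars):
            for b in "ACGT":
                if b == orig:
                    continue
                chars[i] = b
                names |= self._exact("".join(chars))
            chars[i] = orig
        return names

    def assign(self, read: str, max_mm: int) -> tuple[set[str], int]:
        """Names matched at the read's best distance (<= max_mm), and that distance."""
        names = self._exact(read)
        if names or max_mm == 0:
            return names, 0
        return self._one_mismatch(read), 1


def map_reads(
    reads_by_sample: dict[str, list],
    matures: dict[str, str],
    max_mm: int = 0,
    max_overhang: int = 2,
) -> CountMatrix:
    """Assign reads to mature miRNAs and tabulate per-sample counts.

    ``reads_by_sample`` maps sample id to a list of sequences or
    ``(name, seq, qual)`` tuples (already filtered).  ``max_mm`` is 0 or 1;
    at 1, a read with any exact match is never also credited at distance 1
    (best-distance semantics).
    """
    if max_mm not in (0, 1):
        raise ValueError("max_mm must be 0 or 1")
    index = _MatureIndex(matures, max_overhang=max_overhang)
    names = list(matures)
    samples = list(reads_by_sample)
    counts = pd.DataFrame(0, index=names, columns=samples, dtype=int)
    acct_rows = []
    for sample, reads in reads_by_sample.items():
        seqs = Counter(
            r if isinstance(r, str) else r[1] for r in reads
        )
        col = dict.fromkeys(names, 0)
        n_assigned = n_multi = n_unassigned = 0
        for seq, mult in seqs.items():
            matched, _dist = index.assign(seq, max_mm)
            if not matched:
                n_unassigned += mult
                continue
            n_assigned += mult
            if len(matched) > 1:
                n_multi += mult
            for name in matched:
                col[name] += mult
        counts[sample] = pd.Series(col)
        acct_rows.append(
            dict(sample=sample, input=sum(seqs.values()), assigned=n_assigned,
                 unassigned=n_unassigned, multi_assigned=n_multi)
        )
    return CountMatrix(
        counts=counts,
        max_mm=max_mm,
        accounting=pd.DataFrame(
            acct_rows, columns=["sample", "input", "assigned", "unassigned", "multi_assigned"]
        ),
    )


def call_expressed(matrix: CountMatrix, min_total: int = 15) -> list[ExpressionCall]:
    """Call a mature expressed when its combined count over samples reaches
    ``min_total`` (>=, matching a "minimum of N combined reads" rule)."""
    totals = matrix.row_totals()
    return [
        ExpressionCall(name=n, total=int(t), expressed=bool(t >= min_total),
                       mismatch_mode=matrix.max_mm)
        for n, t in totals.items()
    ]


def expressed_set(calls: list[ExpressionCall]) -> set[str]:
    return {c.name for c in calls if c.expressed}


def _tmm_pair_factor(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    """TMM scaling factor of one library against the reference library."""
    mask = (obs > 0) & (ref > 0)
    yk, yr = obs[mask].astype(float), ref[mask].astype(float)
    if yk.size == 0:
        return 1.0
    m = np.log2((yk / n_obs) / (yr / n_ref))
    a = 0.5 * np.log2((yk / n_obs) * (yr / n_ref))
    # inverse of the delta-method variance of M
    w = (n_obs - yk) / (n_obs * yk) + (n_ref - yr) / (n_ref * yr)
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = int(np.floor(n * trim_m)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_a)) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_w = 1.0 / w
    num = np.nansum((m * inv_w)[keep])
    den = np.nansum(inv_w[keep])
    if not np.isfinite(num) or not np.isfinite(den) or den == 0:
        return 1.0
    f = 2.0 ** (num / den)
    return f if np.isfinite(f) and f > 0 else 1.0


def tmm_normalize(
    matrix: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05
) -> CountMatrix:
    """Trimmed-mean-of-M-values between-library normalization.

    The reference library is the one whose upper-quartile (of counts scaled
    by library size) is closest to the mean upper-quartile.  Each library's
    factor is the weighted mean of log2 count ratios (M) against the
    reference, doubly trimmed — the most extreme ``trim_m`` of M values on
    each side and ``trim_a`` of average log abundances (A) on each side —
    with inverse delta-method variances as weights.  Factors are rescaled to
    geometric mean 1; normalized values are counts per million of the
    effective library size (lib_size x factor).
    """
    counts = matrix.counts
    lib = counts.sum(axis=0).astype(float)
    if (lib <= 0).any():
        raise ValueError("every sample needs a positive library size")
    f75 = counts.quantile(0.75, axis=0) / lib
    ref = (f75 - f75.mean()).abs().idxmin()
    raw_factors = pd.Series(
        {
            s: _tmm_pair_factor(
                counts[s].to_numpy(), counts[ref].to_numpy(),
                lib[s], lib[ref], trim_m, trim_a,
            )
            for s in counts.columns
        }
    )
    factors = raw_factors / np.exp(np.mean(np.log(raw_factors)))
    eff_lib = lib * factors
    norm = counts.div(eff_lib, axis=1) * 1e6
    return CountMatrix(
        counts=counts,
        max_mm=matrix.max_mm,
        norm_factors=factors,
        norm=norm,
        accounting=matrix.accounting,
    )


def top_k(matrix: CountMatrix, k: int = 10) -> list[str]:
    """Top-k mature names by mean normalized value (mean CPM fallback).

    Deterministic: sorted by descending mean then name; every name tied with
    the k-th value is included.
    """
    values = matrix.norm if matrix.norm is not None else matrix.cpm()
    means = values.mean(axis=1)
    order = sorted(means.items(), key=lambda kv: (-kv[1], kv[0]))
    if k <= 0 or not order:
        return []
    if k >= len(order):
        return [n for n, _ in order]
    cutoff = order[k - 1][1]
    return [n for n, v in order if v > cutoff or v == cutoff]
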