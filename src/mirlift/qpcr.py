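"""RT-qPCR concordance with the sequencing-based expression calls.

TLDA-style assay tables carry one row per assay (assay id, target sequence,
one Ct column per sample).  Assays are matched to the transferred mature
catalog by sequence (exact preferred, else a unique same-length
single-substitution match), detection is called on the across-sample mean
Ct, and the cross-platform agreement is summarized as the Venn partition of
catalog / sequencing-detected / qPCR-tested / qPCR-detected sets.

"Undetermined" wells enter the mean as the sentinel Ct of 40 rather than
being dropped: dropping them would bias borderline assays toward detection.
The policy is switchable (``undetermined='drop'``).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._scan import hamming

CT_SENTINEL = 40.0

MATCH_EXACT = "matched_0mm"
MATCH_1MM = "matched_1mm"
UNMATCHED_AMBIGUOUS = "unmatched_ambiguous"
UNMATCHED = "unmatched"


@dataclass(frozen=True)
class AssayMatch:
    assay_id: str
    mature: str | None
    mismatches: int  # -1 when unmatched
    status: str


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def match_assays(
    assay_seqs: dict[str, str], matures: dict[str, str], max_mm: int = 1
) -> dict[str, AssayMatch]:
    """Match each assay's target sequence to at most one mature.

    Exact sequence identity wins; otherwise a unique same-length match at
    one substitution (when ``max_mm`` >= 1).  Several equally good
    candidates leave the assay unmatched-ambiguous rather than guessing.
    """
    by_seq: dict[str, list[str]] = {}
    for name, seq in matures.items():
        by_seq.setdefault(_norm(seq), []).append(name)
    out: dict[str, AssayMatch] = {}
    for assay, raw in assay_seqs.items():
        seq = _norm(raw)
        exact = by_seq.get(seq, [])
        if len(exact) == 1:
            out[assay] = AssayMatch(assay, exact[0], 0, MATCH_EXACT)
            continue
        if len(exact) > 1:
            out[assay] = AssayMatch(assay, None, 0, UNMATCHED_AMBIGUOUS)
            continue
        if max_mm >= 1:
            near = [
                name
                for name, mseq in matures.items()
                if len(mseq) == len(seq) and hamming(seq, _norm(mseq)) == 1
            ]
            if len(near) == 1:
                out[assay] = AssayMatch(assay, near[0], 1, MATCH_1MM)
                continue
            if len(near) > 1:
                out[assay] = AssayMatch(assay, None, 1, UNMATCHED_AMBIGUOUS)
                continue
        out[assay] = AssayMatch(assay, None, -1, UNMATCHED)
    return out


def mean_ct(
    ct_table: pd.DataFrame,
    sample_cols: list[str] | None = None,
    undetermined: str = "sentinel",
) -> pd.Series:
    """Across-sample mean Ct per assay, indexed by assay id.

    ``undetermined='sentinel'`` keeps sentinel (40) wells in the mean;
    ``'drop'`` excludes them (an all-sentinel assay then means 40).
    """
    if sample_cols is None:
        sample_cols = [
            c for c in ct_table.columns if c not in ("assay_id", "target_sequence")
        ]
    values = ct_table.set_index("assay_id")[sample_cols].astype(float)
    if undetermined == "drop":
        masked = values.where(values < CT_SENTINEL)
        return masked.mean(axis=1).fillna(CT_SENTINEL)
    if undetermined != "sentinel":
        raise ValueError("undetermined must be 'sentinel' or 'drop'")
    return values.mean(axis=1)


def call_detected(
    ct_table: pd.DataFrame,
    max_ct: float = 32.0,
    sample_cols: list[str] | None = None,
    undetermined: str = "sentinel",
) -> set[str]:
    """Assays whose mean Ct is at or below ``max_ct`` (<= boundary)."""
    means = mean_ct(ct_table, sample_cols, undetermined)
    return set(means.index[means <= max_ct])


def detected_matures(
    detected_assays: set[str], matches: dict[str, AssayMatch]
) -> set[str]:
    """Collapse assay detections to mature names.

    Duplicate assays for one mature collapse to a single call: the mature is
    detected when any of its assays is (equivalently, by minimum mean Ct).
    """
    return {
        m.mature for a, m in matches.items() if a in detected_assays and m.mature
    }


def tested_matures(matches: dict[str, AssayMatch]) -> set[str]:
    return {m.mature for m in matches.values() if m.mature}


@dataclass(frozen=True)
class VennPartition:
    """Cross-platform comparison sets (catalog-wide)."""

    catalog: frozenset
    seq_detected: frozenset
    tested: frozenset
    qpcr_detected: frozenset

    @property
    def both(self) -> frozenset:
        return self.seq_detected & self.qpcr_detected

    @property
    def qpcr_only(self) -> frozenset:
        return self.qpcr_detected - self.seq_detected

    @property
    def seq_only_tested(self) -> frozenset:
        return (self.seq_detected & self.tested) - self.qpcr_detected

    @property
    def untested_seq(self) -> frozenset:
        return self.seq_detected - self.tested

    def counts(self) -> dict[str, int]:
        return {
            "catalog": len(self.catalog),
            "seq_detected": len(self.seq_detected),
            "tested": len(self.tested),
            "qpcr_detected": len(self.qpcr_detected),
            "both": len(self.both),
            "qpcr_only": len(self.qpcr_only),
            "seq_only_tested": len(self.seq_only_tested),
            "untested_seq": len(self.untested_seq),
        }


def venn(catalog, seq_set, tested_set, qpcr_set) -> VennPartition:
    """Build the platform-comparison partition from the four base sets."""
    return VennPartition(
        catalog=frozenset(catalog),
        seq_detected=frozenset(seq_set),
        tested=frozenset(tested_set),
        qpcr_detected=frozenset(qpcr_set),
    )
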