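"""Conservation tiers of transferred matures against a reference species.

Each target-species mature is compared with its same-named counterpart in a
reference (human-role) catalog and classified into one of seven mutually
exclusive tiers, in precedence order:

``full_perfect``            identical sequences;
``internal_match_0mm_gt15`` an exact shared internal stretch of >15 nt
                            (i.e. >=16, read strictly);
``same_length_le5mm``       equal length, Hamming distance <= 5;
``high_divergence``         equal length, any larger distance;
``stemloop_match``          no catalog counterpart tier, but the mature
                            places inside a reference stem-loop within
                            ``max_mm`` (default 1: "fewer than 2");
``genome_only``             its precursor still finds a full-length hit in
                            the reference genome;
``unmatched``               none of the above.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import _scan
from .annotate import scan_genome, strip_prefix

TIER_FULL = "full_perfect"
TIER_INTERNAL = "internal_match_0mm_gt15"
TIER_SAME_LEN = "same_length_le5mm"
TIER_DIVERGENT = "high_divergence"
TIER_STEMLOOP = "stemloop_match"
TIER_GENOME = "genome_only"
TIER_UNMATCHED = "unmatched"

TIERS = (
    TIER_FULL,
    TIER_INTERNAL,
    TIER_SAME_LEN,
    TIER_DIVERGENT,
    TIER_STEMLOOP,
    TIER_GENOME,
    TIER_UNMATCHED,
)


@dataclass(frozen=True)
class ConservationCall:
    mature_name: str
    tier: str
    detail: int  # mismatches, or matched-stretch length for the internal tier
    counterpart: str | None = None


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def longest_common_substring(a: str, b: str) -> int:
    """Length of the longest exact shared substring (dynamic programming)."""
    best = 0
    prev = [0] * (len(b) + 1)
    for ca in a:
        cur = [0] * (len(b) + 1)
        for j, cb in enumerate(b, start=1):
            if ca == cb:
                cur[j] = prev[j - 1] + 1
                if cur[j] > best:
                    best = cur[j]
        prev = cur
    return best


def classify_vs_catalog(
    mature_seq: str,
    counterpart_seq: str,
    mature_name: str = "mature",
    counterpart_name: str | None = None,
) -> ConservationCall:
    """Catalog-level tier of a mature against its named counterpart."""
    a, b = _norm(mature_seq), _norm(counterpart_seq)
    if a == b:
        return ConservationCall(mature_name, TIER_FULL, 0, counterpart_name)
    lcs = longest_common_substring(a, b)
    if lcs > 15:
        return ConservationCall(mature_name, TIER_INTERNAL, lcs, counterpart_name)
    if len(a) == len(b):
        mm = _scan.hamming(a, b)
        tier = TIER_SAME_LEN if mm <= 5 else TIER_DIVERGENT
        return ConservationCall(mature_name, tier, mm, counterpart_name)
    return ConservationCall(mature_name, TIER_UNMATCHED, 0, counterpart_name)


def map_to_stemloops(
    mature_seq: str,
    counterpart_stemloops: dict[str, str],
    max_mm: int = 1,
    mature_name: str = "mature",
) -> ConservationCall | None:
    """Fuzzy-substring placement of a mature in reference stem-loops.

    Same engine as mature extraction; returns the lowest-mismatch placement
    within ``max_mm`` (first stem-loop in catalog order on ties), else None.
    """
    seq = _norm(mature_seq)
    best: tuple[int, str] | None = None
    for name, stemloop in counterpart_stemloops.items():
        if len(seq) > len(stemloop):
            continue
        mm, offsets = _scan.best_windows(seq, _norm(stemloop))
        if offsets and mm <= max_mm and (best is None or mm < best[0]):
            best = (mm, name)
    if best is None:
        return None
    return ConservationCall(mature_name, TIER_STEMLOOP, best[0], best[1])


def scan_counterpart_genome(
    precursor_seq: str,
    genome,
    min_identity: float = 0.90,
    mature_name: str = "mature",
) -> ConservationCall:
    """Genome-level fallback: any full-length precursor hit -> genome_only."""
    hits = scan_genome(precursor_seq, genome, min_identity, query_id=mature_name)
    if hits:
        top = hits[0]
        return ConservationCall(
            mature_name, TIER_GENOME, top.mismatches, f"{top.chrom}:{top.start}-{top.end}"
        )
    return ConservationCall(mature_name, TIER_UNMATCHED, 0, None)


def classify_cohort(
    matures: dict[str, str],
    ref_matures: dict[str, str],
    ref_precursors: dict[str, str] | None = None,
    ref_genome=None,
    precursor_of: dict[str, str] | None = None,
    min_identity: float = 0.90,
    stemloop_max_mm: int = 1,
) -> list[ConservationCall]:
    """Tier every mature of a cohort; tiers are exclusive and exhaustive.

    Counterparts are located by species-prefix-stripped name (family-stem
    normalization); matures without a counterpart fall through to the
    stem-loop and genome tiers rather than erroring.  ``precursor_of`` maps
    each mature name to its precursor *sequence* for the genome fallback.
    """
    ref_by_core = {strip_prefix(n).lower(): n for n in ref_matures}
    calls: list[ConservationCall] = []
    for name, seq in matures.items():
        counterpart = ref_by_core.get(strip_prefix(name).lower())
        if counterpart is not None:
            call = classify_vs_catalog(seq, ref_matures[counterpart], name, counterpart)
            if call.tier != TIER_UNMATCHED:
                calls.append(call)
                continue
        if ref_precursors:
            call = map_to_stemloops(seq, ref_precursors, stemloop_max_mm, name)
            if call is not None:
                calls.append(call)
                continue
        if ref_genome is not None and precursor_of and name in precursor_of:
            calls.append(
                scan_counterpart_genome(precursor_of[name], ref_genome, min_identity, name)
            )
            continue
        calls.append(ConservationCall(name, TIER_UNMATCHED, 0, None))
    return calls


def tier_counts(calls: list[ConservationCall]) -> dict[str, int]:
    out = {tier: 0 for tier in TIERS}
    for c in calls:
        out[c.tier] += 1
    return out
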