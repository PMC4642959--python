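"""Hairpin arm profiling and novel-arm miRNA discovery.

Mapping small RNA-seq reads directly onto stem-loop precursors (rather than
onto the mature catalog) makes both arms of every hairpin visible at once:
it classifies each precursor as expressing both arms, one arm, or an arm the
source catalog never annotated — the signature of a novel mature miRNA —
and it settles the arm of suffixless matures (catalog entries named without
-5p/-3p because only one arm's product was known).

Arm assignment uses the read-center rule: a read whose center lies in the
5'-side half of the precursor belongs to the 5p arm, otherwise 3p (center
exactly at the midpoint -> 5p).  Reads whose center falls within 2 nt of the
midpoint while overlapping both halves are loop-spanning: they are still
counted to their center's arm but flagged, since no cut-site model
adjudicates them.

Threshold conventions: an *annotated* arm counts as expressed when its
mature reaches ``expressed_min`` combined reads (>=); an *unannotated* arm
counts as novel only when its arm total strictly exceeds ``novel_min``.
The two comparisons deliberately differ; both are parameters.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from . import _scan
from .annotate import assign_arm

CLASS_BOTH = "both_expressed"
CLASS_ONLY_5P = "only_5p"
CLASS_ONLY_3P = "only_3p"
CLASS_NOVEL_5P = "novel_5p"
CLASS_NOVEL_3P = "novel_3p"
CLASS_SILENT = "silent"


@dataclass(frozen=True)
class Placement:
    """A read multiset placed at one offset of one precursor."""

    precursor: str
    offset: int
    length: int
    mismatches: int
    count: int
    loop_spanning: bool


@dataclass
class ArmProfile:
    """Per-precursor arm read totals and expression classification."""

    precursor: str
    length: int
    reads_5p: int = 0
    reads_3p: int = 0
    loop_spanning: int = 0
    annotated_arms: frozenset = frozenset()
    annotated_totals: dict = field(default_factory=dict)  # arm -> mature total
    classification: str = CLASS_SILENT
    novel_consensus_seq: str | None = None

    def arm_reads(self, arm: str) -> int:
        return self.reads_5p if arm == "5p" else self.reads_3p


def _read_center_arm(offset: int, length: int, plen: int) -> tuple[str, bool]:
    arm = assign_arm(offset, length, plen)
    center = offset + length / 2.0
    mid = plen / 2.0
    spans = offset < mid < offset + length
    return arm, spans and abs(center - mid) <= 2.0


def map_to_precursors(
    reads, precursors: dict[str, str], max_mm: int = 0
) -> dict[str, list[Placement]]:
    """Place every read at its best (fewest-mismatch) offsets on the precursors.

    ``reads`` is a list of sequences or ``(name, seq, qual)`` tuples.  A read
    tied across several precursors at its best distance is counted for each;
    within one precursor the smallest best offset is used.  Returns
    ``{precursor: [Placement, ...]}`` for precursors with any read.
    """
    if not precursors:
        raise ValueError("empty precursor set")
    seqs = Counter(r if isinstance(r, str) else r[1] for r in reads)
    placements: dict[str, list[Placement]] = {name: [] for name in precursors}

    if max_mm == 0:
        # hash every precursor window of every observed read length
        lengths = sorted({len(s) for s in seqs})
        window_index: dict[str, list[tuple[str, int]]] = {}
        for pname, pseq in precursors.items():
            for L in lengths:
                for off in range(len(pseq) - L + 1):
                    window_index.setdefault(pseq[off : off + L], []).append((pname, off))
        for seq, mult in seqs.items():
            hits = window_index.get(seq)
            if not hits:
                continue
            first_per_prec: dict[str, int] = {}
            for pname, off in hits:
                first_per_prec.setdefault(pname, off)
            for pname, off in first_per_prec.items():
                plen = len(precursors[pname])
                _, spanning = _read_center_arm(off, len(seq), plen)
                placements[pname].append(
                    Placement(pname, off, len(seq), 0, mult, spanning)
                )
    else:
        for seq, mult in seqs.items():
            best_mm = max_mm + 1
            best: list[tuple[str, int]] = []
            for pname, pseq in precursors.items():
                mm, offsets = _scan.best_windows(seq, pseq)
                if not offsets or mm > max_mm:
                    continue
                if mm < best_mm:
                    best_mm, best = mm, [(pname, offsets[0])]
                elif mm == best_mm:
                    best.append((pname, offsets[0]))
            for pname, off in best:
                plen = len(precursors[pname])
                _, spanning = _read_center_arm(off, len(seq), plen)
                placements[pname].append(
                    Placement(pname, off, len(seq), best_mm, mult, spanning)
                )
    return {p: pl for p, pl in placements.items() if pl}


def arm_totals(placements: list[Placement], precursor_len: int) -> tuple[int, int]:
    """Total read counts on the 5p and 3p arms by the read-center rule."""
    r5 = r3 = 0
    for pl in placements:
        arm, _ = _read_center_arm(pl.offset, pl.length, precursor_len)
        if arm == "5p":
            r5 += pl.count
        else:
            r3 += pl.count
    return r5, r3


def novel_consensus(placements: list[Placement], precursor_seq: str, arm: str) -> str | None:
    """Consensus novel mature on an arm: the modal (offset, length) read form.

    Ties are broken toward the longer form, then the smaller offset.  The
    returned sequence is the precursor substring at the modal coordinates,
    so sequencing errors in individual reads never leak into the consensus.
    """
    plen = len(precursor_seq)
    forms: Counter = Counter()
    for pl in placements:
        a, _ = _read_center_arm(pl.offset, pl.length, plen)
        if a == arm:
            forms[(pl.offset, pl.length)] += pl.count
    if not forms:
        return None
    (offset, length), _ = min(
        forms.items(), key=lambda kv: (-kv[1], -kv[0][1], kv[0][0])
    )
    return precursor_seq[offset : offset + length]


def classify(
    profile: ArmProfile, expressed_min: int = 15, novel_min: int = 15
) -> str:
    """Expression classification of one precursor.

    Novel-arm evidence (unannotated arm total > ``novel_min``, strict) takes
    precedence; otherwise the classification reflects which annotated arms
    carry an expressed mature (total >= ``expressed_min``).
    """
    novel = [
        arm
        for arm in ("5p", "3p")
        if arm not in profile.annotated_arms and profile.arm_reads(arm) > novel_min
    ]
    if novel:
        if len(novel) == 2:
            novel = ["5p" if profile.reads_5p >= profile.reads_3p else "3p"]
        return CLASS_NOVEL_5P if novel[0] == "5p" else CLASS_NOVEL_3P
    expressed = {
        arm
        for arm in profile.annotated_arms
        if profile.annotated_totals.get(arm, 0) >= expressed_min
    }
    if expressed == {"5p", "3p"}:
        return CLASS_BOTH
    if expressed == {"5p"}:
        return CLASS_ONLY_5P
    if expressed == {"3p"}:
        return CLASS_ONLY_3P
    return CLASS_SILENT


def profile_precursors(
    reads,
    precursors: dict[str, str],
    annotated_arms: dict[str, dict[str, int]],
    expressed_min: int = 15,
    novel_min: int = 15,
    max_mm: int = 0,
) -> dict[str, ArmProfile]:
    """End-to-end arm profiling of a precursor set.

    ``annotated_arms`` maps precursor -> {arm: combined mature read total}
    for the arms the catalog annotates (totals from the expression stage).
    Returns a profile per precursor, with a consensus sequence attached to
    every novel-arm call.
    """
    placements = map_to_precursors(reads, precursors, max_mm=max_mm)
    profiles: dict[str, ArmProfile] = {}
    for pname, pseq in precursors.items():
        pl = placements.get(pname, [])
        r5, r3 = arm_totals(pl, len(pseq))
        totals = annotated_arms.get(pname, {})
        prof = ArmProfile(
            precursor=pname,
            length=len(pseq),
            reads_5p=r5,
            reads_3p=r3,
            loop_spanning=sum(p.count for p in pl if p.loop_spanning),
            annotated_arms=frozenset(totals),
            annotated_totals=dict(totals),
        )
        prof.classification = classify(prof, expressed_min, novel_min)
        if prof.classification in (CLASS_NOVEL_5P, CLASS_NOVEL_3P):
            arm = "5p" if prof.classification == CLASS_NOVEL_5P else "3p"
            prof.novel_consensus_seq = novel_consensus(pl, pseq, arm)
        profiles[pname] = prof
    return profiles


@dataclass
class ArmAssignment:
    name: str
    arm: str  # '5p' | '3p' | 'unknown'
    flagged: bool
    per_parent: dict


def resolve_suffixless(
    matures: dict[str, str],
    parents: dict[str, list[str]],
    precursor_seqs: dict[str, str],
    profiles: dict[str, ArmProfile] | None = None,
    max_mm: int = 2,
) -> dict[str, ArmAssignment]:
    """Assign an arm to matures whose names carry no -5p/-3p suffix.

    Each suffixless mature inherits the arm of its placement within its
    parent precursor(s).  Parents that disagree are flagged and the
    majority-read arm (summed over the disagreeing parents' arm totals) is
    reported; a mature placing in no parent is 'unknown' and flagged.
    """
    out: dict[str, ArmAssignment] = {}
    for name, seq in matures.items():
        per_parent: dict[str, str] = {}
        for parent in parents.get(name, []):
            pseq = precursor_seqs.get(parent)
            if pseq is None or len(seq) > len(pseq):
                continue
            mm, offsets = _scan.best_windows(seq, pseq)
            if mm > max_mm or not offsets:
                continue
            per_parent[parent] = assign_arm(offsets[0], len(seq), len(pseq))
        arms = set(per_parent.values())
        if not arms:
            out[name] = ArmAssignment(name, "unknown", True, per_parent)
        elif len(arms) == 1:
            out[name] = ArmAssignment(name, arms.pop(), False, per_parent)
        else:
            votes = {"5p": 0, "3p": 0}
            for parent, arm in per_parent.items():
                if profiles and parent in profiles:
                    votes[arm] += profiles[parent].arm_reads(arm)
                else:
                    votes[arm] += 1
            majority = "5p" if votes["5p"] >= votes["3p"] else "3p"
            out[name] = ArmAssignment(name, majority, True, per_parent)
    return out
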