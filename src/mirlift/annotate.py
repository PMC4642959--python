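"""Homology transfer of a miRNA catalog onto a target genome.

Stem-loop precursors from a well-annotated source species are located on the
target genome by an exhaustive full-length k-mismatch (Hamming) scan of both
strands.  A locus is accepted only when it passes the catalog-transfer
criteria:

1. full-length identity at or above ``min_identity`` (default 90%);
2. no second genomic location tied at the same mismatch count
   (``ambiguous_multihit`` otherwise);
3. no two members of the same miRNA family resolving to one locus
   (``family_collision`` otherwise);
4. everything not accepted is surfaced as a flagged report row for manual
   curation — never silently dropped or silently chosen.

Mature miRNAs are then placed inside each accepted target precursor by a
fuzzy (minimum-Hamming) substring search, so target-genome substitutions
propagate into the transferred mature sequence.  Finally the catalog is
systematically renamed to the target-species prefix.

The engine is substitution-only by design: the acceptance rule is a
full-length identity fraction and the mismatch bookkeeping is substitution
counting, which an exact Hamming scan reproduces verbatim (and which a
brute-force oracle can verify).  Indel-tolerant alignment is out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from . import _scan
from ._scan import reverse_complement

#: default ambiguity budget: queries with more than this fraction of non-ACGT
#: characters are rejected outright.
MAX_AMBIGUOUS_FRACTION = 0.10

MIN_QUERY_LENGTH = 18

STATUS_ACCEPTED = "accepted"
STATUS_AMBIGUOUS = "ambiguous_multihit"
STATUS_FAMILY_COLLISION = "family_collision"
STATUS_NEEDS_CURATION = "needs_curation"
STATUS_NOT_FOUND = "not_found"


@dataclass(frozen=True)
class Thresholds:
    """Numeric criteria of the catalog-transfer workflow."""

    min_identity: float = 0.90
    max_mature_mismatch: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.min_identity <= 1.0:
            raise ValueError("min_identity must be in (0, 1]")
        if self.max_mature_mismatch < 0:
            raise ValueError("max_mature_mismatch must be >= 0")


@dataclass(frozen=True)
class GenomeHit:
    """One full-length placement of a precursor query on the genome."""

    query_id: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str  # '+' or '-'
    mismatches: int
    sequence: str  # strand-resolved target subsequence

    @property
    def identity(self) -> float:
        return 1.0 - self.mismatches / (self.end - self.start)


@dataclass
class StemLoopAnnotation:
    """Resolution of one source precursor on the target genome."""

    name: str  # target-species name (set by rename_catalog)
    source_name: str
    status: str
    sequence: str | None = None
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None
    mismatches: int | None = None
    genome_label: str | None = None
    rename_collision: bool = False
    #: competing hits retained for the curation report
    competing: list[GenomeHit] = field(default_factory=list)

    @property
    def needs_curation(self) -> bool:
        return self.status in (STATUS_AMBIGUOUS, STATUS_FAMILY_COLLISION, STATUS_NEEDS_CURATION)


@dataclass
class MatureRecord:
    """A mature miRNA placed within a target precursor."""

    name: str
    parent_precursors: list[str]
    offset: int  # 0-based start within the precursor
    length: int
    arm: str  # '5p' | '3p' | 'unknown'
    mismatches_vs_source: int
    sequence: str
    tie_flag: bool = False  # >1 equally good placement
    arm_midpoint: bool = False  # mature center exactly at precursor midpoint
    rename_collision: bool = False


class EncodedGenome:
    """A genome pre-encoded for repeated k-mismatch scanning."""

    def __init__(self, sequences: dict[str, str], label: str = "genome"):
        if not sequences:
            raise ValueError("genome has no sequences")
        self.label = label
        self.sequences = {name: seq.upper() for name, seq in sequences.items()}
        self._arrays = {name: _scan.encode(seq) for name, seq in self.sequences.items()}

    def __len__(self) -> int:
        return sum(len(s) for s in self.sequences.values())

    def items(self):
        return self._arrays.items()

    def window(self, chrom: str, start: int, end: int, strand: str) -> str:
        seq = self.sequences[chrom][start:end]
        return reverse_complement(seq) if strand == "-" else seq


def as_genome(genome) -> EncodedGenome:
    return genome if isinstance(genome, EncodedGenome) else EncodedGenome(genome)


# ---------------------------------------------------------------------------
# miRBase-style name handling


_PREFIX_RE = re.compile(r"^[A-Za-z]{2,4}-")
_ARM_RE = re.compile(r"-(5p|3p)$", re.IGNORECASE)
_LOCUS_RE = re.compile(r"-\d+$")


def strip_prefix(name: str) -> str:
    """Drop the species prefix: ``mml-mir-122`` -> ``mir-122``."""
    return _PREFIX_RE.sub("", name)


def mature_core(name: str) -> str:
    """Precursor-level core of a mature name: strip prefix, arm, case.

    ``mml-miR-29b-2-5p`` -> ``mir-29b-2``.
    """
    core = _ARM_RE.sub("", strip_prefix(name))
    return core.replace("miR", "mir")


def family_stem(name: str) -> str:
    """Family key: numeric core, ignoring letter and locus suffixes.

    ``mml-mir-29a`` and ``mml-mir-29b-1`` share the stem ``mir-29``;
    this mirrors miRBase naming semantics, where lettered variants are
    paralogous family members and trailing digits index genomic loci.
    """
    core = mature_core(name)
    core = _LOCUS_RE.sub("", core)
    m = re.match(r"^(?P<cls>let|lin|mir)-(?P<num>\d+)", core, re.IGNORECASE)
    if m:
        return f"{m.group('cls').lower()}-{m.group('num')}"
    return core.lower()


def matures_to_parents(mature_names, precursor_names) -> dict[str, list[str]]:
    """Map each mature name to its corresponding precursor names.

    Correspondence is by name: the mature's core either equals the precursor
    core or the precursor carries an extra numeric locus suffix
    (``miR-29b-5p`` -> ``mir-29b-1`` and ``mir-29b-2``).
    """
    by_core: dict[str, list[str]] = {}
    for p in precursor_names:
        by_core.setdefault(strip_prefix(p).replace("miR", "mir").lower(), []).append(p)
    out: dict[str, list[str]] = {}
    for m in mature_names:
        core = mature_core(m).lower()
        parents = list(by_core.get(core, []))
        for p_core, names in by_core.items():
            if p_core != core and _LOCUS_RE.sub("", p_core) == core and re.match(
                re.escape(core) + r"-\d+$", p_core
            ):
                parents.extend(names)
        out[m] = sorted(set(parents), key=parents.index if parents else None)
    return out


# ---------------------------------------------------------------------------
# Operations


def scan_genome(
    precursor_seq: str,
    genome,
    min_identity: float = 0.90,
    query_id: str = "query",
) -> list[GenomeHit]:
    """Every full-length placement of a precursor within the identity bound.

    Both strands are scanned exhaustively; a placement is reported when its
    Hamming distance is at most ``floor((1 - min_identity) * len(query))``.
    Hits are sorted by mismatch count, then chromosome/coordinate/strand.
    """
    precursor_seq = precursor_seq.upper()
    if len(precursor_seq) < MIN_QUERY_LENGTH:
        raise ValueError(f"query {query_id!r} shorter than {MIN_QUERY_LENGTH} nt")
    if _scan.ambiguous_fraction(precursor_seq) > MAX_AMBIGUOUS_FRACTION:
        raise ValueError(f"query {query_id!r} exceeds the ambiguity budget")
    genome = as_genome(genome)
    L = len(precursor_seq)
    max_mm = int(np.floor((1.0 - min_identity) * L))
    hits: list[GenomeHit] = []
    rc_query = reverse_complement(precursor_seq)
    for chrom, arr in genome.items():
        for strand, q in (("+", precursor_seq), ("-", rc_query)):
            for start, mm in _scan.scan(q, arr, max_mm):
                hits.append(
                    GenomeHit(
                        query_id=query_id,
                        chrom=chrom,
                        start=start,
                        end=start + L,
                        strand=strand,
                        mismatches=mm,
                        sequence=genome.window(chrom, start, start + L, strand),
                    )
                )
    hits.sort(key=lambda h: (h.mismatches, h.chrom, h.start, h.strand))
    return hits


def _loci_overlap(a: StemLoopAnnotation, b: StemLoopAnnotation) -> bool:
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


def resolve_hits(
    hits_by_query: dict[str, list[GenomeHit]],
    genome_label: str | None = None,
) -> dict[str, StemLoopAnnotation]:
    """Resolve raw hit lists into per-precursor annotations.

    A unique best-mismatch hit is accepted; ties at the best mismatch count
    are flagged ``ambiguous_multihit`` (never silently broken); same-family
    queries accepted over overlapping loci are both demoted to
    ``family_collision``; queries with no hits are ``not_found``.
    """
    annotations: dict[str, StemLoopAnnotation] = {}
    for query, hits in hits_by_query.items():
        if not hits:
            annotations[query] = StemLoopAnnotation(
                name=query, source_name=query, status=STATUS_NOT_FOUND
            )
            continue
        best_mm = min(h.mismatches for h in hits)
        best = [h for h in hits if h.mismatches == best_mm]
        top = best[0]
        ann = StemLoopAnnotation(
            name=query,
            source_name=query,
            status=STATUS_ACCEPTED if len(best) == 1 else STATUS_AMBIGUOUS,
            sequence=top.sequence,
            chrom=top.chrom,
            start=top.start,
            end=top.end,
            strand=top.strand,
            mismatches=top.mismatches,
            genome_label=genome_label,
            competing=best[1:],
        )
        annotations[query] = ann

    # criterion 3: same family, same genomic location
    accepted = [a for a in annotations.values() if a.status == STATUS_ACCEPTED]
    by_family: dict[str, list[StemLoopAnnotation]] = {}
    for ann in accepted:
        by_family.setdefault(family_stem(ann.source_name), []).append(ann)
    for members in by_family.values():
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if _loci_overlap(a, b):
                    a.status = STATUS_FAMILY_COLLISION
                    b.status = STATUS_FAMILY_COLLISION
    return annotations


def annotate_catalog(
    precursors: dict[str, str],
    genomes,
    thresholds: Thresholds = Thresholds(),
) -> dict[str, StemLoopAnnotation]:
    """Scan and resolve a whole precursor catalog, with genome fallback.

    ``genomes`` is one genome or an ordered list; a precursor is searched in
    genome ``i + 1`` only when its status in genome ``i`` is not accepted
    (the second assembly is a fallback, not a second vote).
    """
    if isinstance(genomes, (dict, EncodedGenome)):
        genomes = [genomes]
    genomes = [as_genome(g) for g in genomes]
    pending = dict(precursors)
    final: dict[str, StemLoopAnnotation] = {}
    first_round: dict[str, StemLoopAnnotation] = {}
    for gi, genome in enumerate(genomes):
        hits = {
            name: scan_genome(seq, genome, thresholds.min_identity, query_id=name)
            for name, seq in pending.items()
        }
        resolved = resolve_hits(hits, genome_label=genome.label)
        if gi == 0:
            first_round = resolved
        for name, ann in resolved.items():
            if ann.status == STATUS_ACCEPTED:
                final[name] = ann
                del pending[name]
    # unaccepted queries keep their primary-genome diagnosis
    for name, ann in first_round.items():
        final.setdefault(name, ann)
    return {name: final[name] for name in precursors}


def extract_mature(
    source_mature_seq: str,
    annotation: StemLoopAnnotation,
    max_mm: int = 3,
    name: str = "mature",
) -> MatureRecord | None:
    """Place a source mature inside an accepted target precursor.

    Finds the minimum-Hamming same-length substring of the target precursor
    and, when within ``max_mm``, returns the *target-side* sequence, so that
    genomic substitutions inside the mature propagate into the transferred
    record.  Ties at equal distance are broken toward the smaller offset and
    flagged.
    """
    if annotation.status != STATUS_ACCEPTED:
        raise ValueError(f"precursor {annotation.source_name!r} is not accepted")
    precursor = annotation.sequence or ""
    mature = source_mature_seq.upper().replace("U", "T")
    if len(mature) > len(precursor):
        raise ValueError("mature longer than its precursor")
    best_mm, offsets = _scan.best_windows(mature, precursor)
    if best_mm > max_mm or not offsets:
        return None
    offset = offsets[0]
    length = len(mature)
    arm = assign_arm(offset, length, len(precursor))
    return MatureRecord(
        name=name,
        parent_precursors=[annotation.source_name],
        offset=offset,
        length=length,
        arm=arm,
        mismatches_vs_source=best_mm,
        sequence=precursor[offset : offset + length],
        tie_flag=len(offsets) > 1,
        arm_midpoint=(offset + length / 2.0) == len(precursor) / 2.0,
    )


def assign_arm(offset: int, length: int, precursor_length: int) -> str:
    """Hairpin arm of a mature from its position: center rule.

    The mature's center ``offset + length/2`` falls in the 5'-side half of
    the precursor -> ``5p``, otherwise ``3p``; a center exactly at the
    midpoint is assigned ``5p`` (documented tie-break).
    """
    center = offset + length / 2.0
    return "5p" if center <= precursor_length / 2.0 else "3p"


def annotate_matures(
    matures: dict[str, str],
    annotations: dict[str, StemLoopAnnotation],
    max_mm: int = 3,
) -> dict[str, MatureRecord]:
    """Place every source mature into its corresponding accepted precursors.

    A mature may derive from more than one precursor (locus-suffixed family
    members); the record keeps every parent in which it was found and the
    sequence/offset from the lowest-mismatch parent.
    """
    accepted = {n: a for n, a in annotations.items() if a.status == STATUS_ACCEPTED}
    parent_map = matures_to_parents(matures.keys(), accepted.keys())
    out: dict[str, MatureRecord] = {}
    for mname, mseq in matures.items():
        records: list[MatureRecord] = []
        for parent in parent_map.get(mname, []):
            rec = extract_mature(mseq, accepted[parent], max_mm=max_mm, name=mname)
            if rec is not None:
                records.append(rec)
        if not records:
            continue
        best = min(records, key=lambda r: r.mismatches_vs_source)
        best.parent_precursors = sorted(
            {p for r in records for p in r.parent_precursors}
        )
        out[mname] = best
    return out


def rename_catalog(
    annotations: dict[str, StemLoopAnnotation],
    matures: dict[str, MatureRecord],
    prefix: str,
) -> tuple[dict[str, StemLoopAnnotation], dict[str, MatureRecord]]:
    """Systematically rename the transferred catalog to the target prefix.

    The source species prefix is swapped for ``prefix`` (idempotent when a
    name already carries it).  Should two source names collapse onto one
    target name, both are kept with ``-1``/``-2`` suffixes and flagged.
    """

    def rename_one(name: str) -> str:
        if name.lower().startswith(prefix.lower() + "-"):
            return name
        return f"{prefix}-{strip_prefix(name)}"

    def apply(records: dict):
        proposed: dict[str, list[str]] = {}
        for old in records:
            proposed.setdefault(rename_one(old), []).append(old)
        renamed = {}
        mapping: dict[str, str] = {}
        for new, olds in proposed.items():
            collided = len(olds) > 1
            for i, old in enumerate(olds):
                final = f"{new}-{i + 1}" if collided else new
                mapping[old] = final
        for old, rec in records.items():
            rec.name = mapping[old]
            rec.rename_collision = len(proposed[rename_one(old)]) > 1
            renamed[rec.name] = rec
        return renamed, mapping

    renamed_annotations, prec_map = apply(annotations)
    renamed_matures, _ = apply(matures)
    for rec in renamed_matures.values():
        rec.parent_precursors = [prec_map.get(p, p) for p in rec.parent_precursors]
    return renamed_annotations, renamed_matures


def status_report(annotations: dict[str, StemLoopAnnotation]):
    """Per-precursor status table (one flagged row per curation case)."""
    import pandas as pd

    rows = []
    for ann in annotations.values():
        rows.append(
            {
                "source_name": ann.source_name,
                "name": ann.name,
                "status": ann.status,
                "mismatches": ann.mismatches,
                "chrom": ann.chrom,
                "start": ann.start,
                "end": ann.end,
                "strand": ann.strand,
                "genome": ann.genome_label,
                "needs_curation": ann.needs_curation,
                "n_competing": len(ann.competing),
            }
        )
    return pd.DataFrame(rows)
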