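"""Seeded synthetic data with planted ground truth.

The generator emulates every input of the catalog-transfer study so the full
pipeline runs with no downloads:

* a miRBase-style source catalog (stem-loop precursors with one or two
  embedded mature miRNAs, letter-suffixed family members, a fraction of
  mature names without the -5p/-3p arm suffix);
* a target genome with each precursor planted at a recorded locus and
  identity, including equal-mismatch decoy copies (which the resolver must
  flag as ambiguous) and family pairs sharing one locus (which it must flag
  as collisions);
* small RNA-seq FASTQ libraries: 18-24 nt reads drawn from the *target-side*
  mature sequences with 3'-end length jitter, substitution errors, Phred+33
  qualities, and spiked-in short/low-quality junk to exercise filtering;
* RT-qPCR Ct tables following a linear Ct-vs-log10(expression) model with an
  "Undetermined" sentinel of 40.

Mutations planted into a precursor are biased away from the mature regions
(at most one substitution per mature), reflecting the much stronger
conservation of mature miRNAs than of the loop and flanks that homology
studies observe.  Everything is a pure function of the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._scan import reverse_complement

BASES = np.array(list("ACGT"))
CT_SENTINEL = 40.0

#: between-sample log10 spread of a mature's expression (library-to-library
#: biological/technical variability on top of Poisson counting noise)
SAMPLE_LOG_SD = 0.12


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, fully determined by ``seed``."""

    seed: int = 0
    n_precursors: int = 100
    precursor_len_range: tuple[int, int] = (55, 120)
    mature_len_range: tuple[int, int] = (18, 24)
    genome_len: int = 200_000
    planted_identity_range: tuple[float, float] = (0.90, 1.00)
    n_decoy_copies: int = 5
    n_family_collisions: int = 3
    n_samples: int = 3
    expression_log_mean: float = 2.1
    expression_log_sd: float = 0.8
    arm_dominance_range: tuple[float, float] = (0.6, 0.99)
    frac_single_arm: float = 0.25
    frac_novel_arm: float = 0.5
    frac_suffixless: float = 0.5
    seq_error_rate: float = 0.01
    frac_low_quality: float = 0.01
    frac_short: float = 0.01
    ct_slope: float = 3.32
    ct_intercept: float = 34.0
    ct_noise_sd: float = 0.5
    frac_assay_mismatch: float = 0.06
    n_offtarget_assays: int = 10
    source_prefix: str = "sim"
    chrom_name: str = "chr1"

    def __post_init__(self) -> None:
        for name in (
            "planted_identity_range",
            "arm_dominance_range",
        ):
            lo, hi = getattr(self, name)
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError(f"{name} must be an ordered pair in [0, 1]")
        for name in ("precursor_len_range", "mature_len_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be an ordered positive pair")
        for name in (
            "frac_single_arm",
            "frac_novel_arm",
            "frac_suffixless",
            "seq_error_rate",
            "frac_low_quality",
            "frac_short",
            "frac_assay_mismatch",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_precursors < 0 or self.n_samples < 1:
            raise ValueError("n_precursors must be >= 0 and n_samples >= 1")
        if 2 * self.n_family_collisions > self.n_precursors:
            raise ValueError("too many family-collision pairs for n_precursors")
        # both mature arms (plus 2 nt of placement margin each side) must fit
        # in a precursor half
        if self.mature_len_range[1] + 4 > self.precursor_len_range[0] // 2 + 3:
            raise ValueError("mature_len_range too long for precursor_len_range")


@dataclass
class MatureTruth:
    name: str
    precursor: str
    offset: int
    length: int
    arm: str
    annotated: bool  # False for planted novel-arm products


@dataclass
class SourceCatalog:
    """Source-species catalog plus the structural metadata behind it."""

    precursors: dict[str, str]
    matures: dict[str, str]
    mature_truth: list[MatureTruth]
    family_pairs: list[tuple[str, str]]  # (planted member, shadow member)

    def matures_of(self, precursor: str) -> list[MatureTruth]:
        return [m for m in self.mature_truth if m.precursor == precursor]


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream verification."""

    precursors: pd.DataFrame  # name, chrom, start, end, strand, mismatches,
    #                            ambiguous, family_collision, planted_seq
    decoys: pd.DataFrame  # name, chrom, start, end, strand, mismatches
    matures: pd.DataFrame  # name, precursor, offset, length, arm, annotated,
    #                          target_sequence
    counts: pd.DataFrame | None = None  # true per-sample counts (matures x samples)
    junk: pd.DataFrame | None = None  # per-sample spiked junk-read accounting
    assays: pd.DataFrame | None = None  # assay truth incl. detected flag

    def clean_precursors(self) -> set[str]:
        """Precursors planted without deliberate ambiguity or family collision
        (the ones the annotation stage is expected to accept)."""
        p = self.precursors
        return set(p.loc[~p.ambiguous & ~p.family_collision, "name"])

    def expressed_truth(self, min_total: int = 15, clean_only: bool = True) -> set[str]:
        """Annotated matures whose true combined count reaches ``min_total``.

        With ``clean_only`` (default) the set is restricted to matures of
        cleanly planted precursors — matures of decoy/collision precursors
        never enter the transferred catalog, so they cannot be called.
        """
        if self.counts is None:
            raise ValueError("counts not simulated yet")
        rows = self.matures[self.matures.annotated]
        if clean_only:
            rows = rows[rows.precursor.isin(self.clean_precursors())]
        totals = self.counts.sum(axis=1)
        return {m for m in rows.name if totals.get(m, 0) >= min_total}

    def novel_arm_truth(self, novel_min: int = 15, clean_only: bool = True) -> set[tuple[str, str]]:
        """(precursor, arm) pairs whose planted unannotated arm strictly
        exceeds ``novel_min`` true combined reads."""
        if self.counts is None:
            raise ValueError("counts not simulated yet")
        rows = self.matures[~self.matures.annotated]
        if clean_only:
            rows = rows[rows.precursor.isin(self.clean_precursors())]
        totals = self.counts.sum(axis=1)
        return {
            (r.precursor, r.arm)
            for r in rows.itertuples()
            if totals.get(r.name, 0) > novel_min
        }


def _rngs(cfg: SimConfig, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(cfg.seed).spawn(n)]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def _mutate(
    rng: np.random.Generator, seq: str, positions: np.ndarray
) -> str:
    """Substitute each listed position with a different random base."""
    chars = list(seq)
    for p in positions:
        old = chars[p]
        choices = [b for b in "ACGT" if b != old]
        chars[p] = choices[rng.integers(0, 3)]
    return "".join(chars)


# ---------------------------------------------------------------------------
# catalog


def make_source_catalog(cfg: SimConfig) -> SourceCatalog:
    """Generate the source-species stem-loop + mature catalog.

    Every mature is an exact substring of its named precursor, one per arm
    half, 5'-anchored a couple of nucleotides in from the hairpin ends.
    ``cfg.n_family_collisions`` letter-suffixed family pairs are created in
    which the second member is a lightly mutated copy of the first (two
    forced substitutions in the central third of each mature region keep the
    members' products distinguishable at zero mismatches).
    """
    rng = _rngs(cfg, 5)[0]
    precursors: dict[str, str] = {}
    matures: dict[str, str] = {}
    truth: list[MatureTruth] = []
    family_pairs: list[tuple[str, str]] = []
    p = cfg.source_prefix

    n = cfg.n_precursors
    n_fam = cfg.n_family_collisions
    n_plain = n - 2 * n_fam
    # arm structure for plain precursors
    n_single = int(round(cfg.frac_single_arm * n_plain))
    single_idx = set(rng.choice(n_plain, size=n_single, replace=False).tolist()) if n_plain else set()
    single_list = sorted(single_idx)
    n_novel = int(round(cfg.frac_novel_arm * len(single_list)))
    novel_idx = set(
        rng.choice(len(single_list), size=n_novel, replace=False).tolist()
    ) if single_list else set()
    novel_set = {single_list[i] for i in novel_idx}

    def place_matures(plen: int) -> dict[str, tuple[int, int]]:
        """(offset, length) of a candidate mature on each arm."""
        half = plen // 2
        out = {}
        for arm in ("5p", "3p"):
            mlen = int(rng.integers(cfg.mature_len_range[0], cfg.mature_len_range[1] + 1))
            if arm == "5p":
                off = int(rng.integers(2, max(3, half - mlen - 1)))
            else:
                lo = max(half + 1, plen - mlen - 4)
                hi = plen - mlen - 2
                off = int(rng.integers(lo, max(lo + 1, hi + 1)))
            out[arm] = (off, mlen)
        return out

    def add_precursor(pname: str, seq: str, arms: dict[str, tuple[int, int]],
                      annotated_arms: list[str], novel_arm: str | None,
                      suffixless: bool) -> None:
        precursors[pname] = seq
        core = pname.split("-", 1)[1].replace("mir", "miR")
        for arm in ("5p", "3p"):
            off, mlen = arms[arm]
            mseq = seq[off : off + mlen]
            if arm in annotated_arms:
                if suffixless and len(annotated_arms) == 1:
                    mname = f"{p}-{core}"
                else:
                    mname = f"{p}-{core}-{arm}"
                matures[mname] = mseq
                truth.append(MatureTruth(mname, pname, off, mlen, arm, True))
            elif arm == novel_arm:
                truth.append(
                    MatureTruth(f"{pname}/novel-{arm}", pname, off, mlen, arm, False)
                )

    num = 0
    for i in range(n_plain):
        num += 1
        pname = f"{p}-mir-{num}"
        plen = int(rng.integers(cfg.precursor_len_range[0], cfg.precursor_len_range[1] + 1))
        seq = _random_seq(rng, plen)
        arms = place_matures(plen)
        if i in single_idx:
            annotated = [("5p", "3p")[int(rng.integers(0, 2))]]
            other = "3p" if annotated[0] == "5p" else "5p"
            novel_arm = other if i in novel_set else None
            suffixless = bool(rng.random() < cfg.frac_suffixless)
        else:
            annotated, novel_arm, suffixless = ["5p", "3p"], None, False
        add_precursor(pname, seq, arms, annotated, novel_arm, suffixless)

    for _ in range(n_fam):
        num += 1
        plen = int(rng.integers(cfg.precursor_len_range[0], cfg.precursor_len_range[1] + 1))
        seq_a = _random_seq(rng, plen)
        arms = place_matures(plen)
        # two substitutions inside the central third of each mature region
        # keep every length-jittered read of one member at Hamming >= 1 from
        # the other member's mature
        pos = []
        for off, mlen in arms.values():
            lo, hi = off + mlen // 3, off + 2 * mlen // 3
            pos.extend(rng.choice(np.arange(lo, hi), size=2, replace=False).tolist())
        seq_b = _mutate(rng, seq_a, np.array(pos))
        name_a, name_b = f"{p}-mir-{num}a", f"{p}-mir-{num}b"
        add_precursor(name_a, seq_a, arms, ["5p", "3p"], None, False)
        add_precursor(name_b, seq_b, arms, ["5p", "3p"], None, False)
        family_pairs.append((name_a, name_b))

    return SourceCatalog(precursors, matures, truth, family_pairs)


# ---------------------------------------------------------------------------
# genome


def plant_genome(catalog: SourceCatalog, cfg: SimConfig) -> tuple[dict[str, str], GroundTruth]:
    """Plant each precursor into an i.i.d.-uniform background genome.

    Each precursor gets one locus at an identity drawn from
    ``planted_identity_range`` (mismatch count = floor((1-identity)*len),
    at most one substitution inside any mature region).  The first
    ``n_decoy_copies`` plain precursors get a second locus with the *same*
    mismatch count (ambiguous by design).  For each family pair only the
    first member is planted, so both members later resolve to that shared
    locus (family collision by design).
    """
    rng = _rngs(cfg, 5)[1]
    genome = list(_random_seq(rng, cfg.genome_len))
    shadow = {b for _, b in catalog.family_pairs}
    plantable = [n for n in catalog.precursors if n not in shadow]
    decoy_names = [n for n in plantable if "a" not in n.rsplit("-", 1)[1]][: cfg.n_decoy_copies]

    used: list[tuple[int, int]] = []

    def alloc(length: int) -> int:
        margin = 5
        for _ in range(10_000):
            s = int(rng.integers(0, cfg.genome_len - length))
            if all(s + length + margin <= a or b + margin <= s for a, b in used):
                used.append((s, s + length))
                return s
        raise RuntimeError("genome too crowded; increase genome_len")

    def mutation_positions(name: str, plen: int, n_mut: int) -> np.ndarray:
        mature_pos: set[int] = set()
        regions = []
        for mt in catalog.matures_of(name):
            regions.append((mt.offset, mt.offset + mt.length))
            mature_pos.update(range(mt.offset, mt.offset + mt.length))
        outside = np.array(sorted(set(range(plen)) - mature_pos))
        chosen: list[int] = []
        # at most one substitution per mature region (mature sequences are
        # under much stronger selection than the hairpin backbone)
        inside_budget = [(lo, hi) for lo, hi in regions]
        for _ in range(n_mut):
            if inside_budget and rng.random() < 0.15:
                lo, hi = inside_budget.pop(int(rng.integers(0, len(inside_budget))))
                chosen.append(int(rng.integers(lo, hi)))
            else:
                pick = int(rng.integers(0, len(outside)))
                chosen.append(int(outside[pick]))
                outside = np.delete(outside, pick)
        return np.array(sorted(set(chosen)), dtype=int)

    prec_rows, decoy_rows, mature_rows = [], [], []

    def plant(seq: str) -> tuple[int, int, str]:
        start = alloc(len(seq))
        strand = "+" if rng.random() < 0.5 else "-"
        placed = seq if strand == "+" else reverse_complement(seq)
        genome[start : start + len(seq)] = list(placed)
        return start, start + len(seq), strand

    fam_planted = {a for a, _ in catalog.family_pairs}
    shared_locus: dict[str, tuple[int, int, str, str]] = {}

    for name in plantable:
        seq = catalog.precursors[name]
        plen = len(seq)
        if name in fam_planted:
            n_mut = 0
            mutated = seq
        else:
            identity = rng.uniform(*cfg.planted_identity_range)
            n_mut = int(math.floor((1.0 - identity) * plen))
            pos = mutation_positions(name, plen, n_mut)
            mutated = _mutate(rng, seq, pos)
            n_mut = len(pos)
        start, end, strand = plant(mutated)
        if name in fam_planted:
            shared_locus[name] = (start, end, strand, mutated)
        prec_rows.append(
            dict(
                name=name,
                chrom=cfg.chrom_name,
                start=start,
                end=end,
                strand=strand,
                mismatches=n_mut,
                ambiguous=name in decoy_names,
                family_collision=name in fam_planted,
                planted_seq=mutated,
            )
        )
        for mt in catalog.matures_of(name):
            mature_rows.append(
                dict(
                    name=mt.name,
                    precursor=name,
                    offset=mt.offset,
                    length=mt.length,
                    arm=mt.arm,
                    annotated=mt.annotated,
                    target_sequence=mutated[mt.offset : mt.offset + mt.length],
                )
            )
        if name in decoy_names:
            pos = mutation_positions(name, plen, n_mut)
            while len(pos) != n_mut:  # decoy must tie the primary exactly
                pos = mutation_positions(name, plen, n_mut)
            decoy_seq = _mutate(rng, seq, pos)
            dstart, dend, dstrand = plant(decoy_seq)
            decoy_rows.append(
                dict(name=name, chrom=cfg.chrom_name, start=dstart, end=dend,
                     strand=dstrand, mismatches=n_mut)
            )

    # family shadow members: truth records point at the shared locus
    for a, b in catalog.family_pairs:
        start, end, strand, planted = shared_locus[a]
        from ._scan import hamming

        prec_rows.append(
            dict(
                name=b,
                chrom=cfg.chrom_name,
                start=start,
                end=end,
                strand=strand,
                mismatches=hamming(catalog.precursors[b], planted),
                ambiguous=False,
                family_collision=True,
                planted_seq=planted,
            )
        )
        for mt in catalog.matures_of(b):
            mature_rows.append(
                dict(
                    name=mt.name,
                    precursor=b,
                    offset=mt.offset,
                    length=mt.length,
                    arm=mt.arm,
                    annotated=mt.annotated,
                    target_sequence=catalog.precursors[b][mt.offset : mt.offset + mt.length],
                )
            )

    gt = GroundTruth(
        precursors=pd.DataFrame(
            prec_rows,
            columns=["name", "chrom", "start", "end", "strand", "mismatches",
                     "ambiguous", "family_collision", "planted_seq"],
        ),
        decoys=pd.DataFrame(
            decoy_rows, columns=["name", "chrom", "start", "end", "strand", "mismatches"]
        ),
        matures=pd.DataFrame(
            mature_rows,
            columns=["name", "precursor", "offset", "length", "arm", "annotated",
                     "target_sequence"],
        ),
    )
    return {cfg.chrom_name: "".join(genome)}, gt


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    catalog: SourceCatalog, gt: GroundTruth, cfg: SimConfig
) -> dict[str, list[tuple[str, str, str]]]:
    """Simulate per-sample small RNA-seq libraries from the planted truth.

    True per-mature per-sample counts are drawn from a log-normal expression
    model partitioned by arm dominance, then exactly that many reads are
    written per mature (before junk spikes), so truth-to-FASTQ count
    conservation holds by construction.  Reads are the target-side mature
    sequences with 0-2 nt of 3'-end length jitter (clamped to
    ``mature_len_range``), per-base substitution errors at
    ``seq_error_rate``, and constant high quality; junk spikes add short
    (<18 nt) and low-mean-quality reads for the filtering stage.

    Fills ``gt.counts`` and ``gt.junk`` in place and returns
    ``{sample: [(read id, sequence, quality), ...]}``.
    """
    rng = _rngs(cfg, 5)[2]
    samples = [f"K{i + 1}" for i in range(cfg.n_samples)]
    prec_seq = dict(zip(gt.precursors.name, gt.precursors.planted_seq))
    # family shadow members share the planted member's locus but their reads
    # come from their own (source) sequence: exclude them from read simulation
    shadow = {b for _, b in catalog.family_pairs}

    mature_rows = gt.matures[~gt.matures.precursor.isin(shadow)]

    # expression model: per-precursor total, split by arm dominance
    arm_mean: dict[str, float] = {}
    for prec, grp in mature_rows.groupby("precursor", sort=False):
        total = 10.0 ** rng.normal(cfg.expression_log_mean, cfg.expression_log_sd)
        dom = rng.uniform(*cfg.arm_dominance_range)
        arms = list(grp.itertuples())
        if len(arms) == 1:
            arm_mean[arms[0].name] = total
        else:
            dom_i = int(rng.integers(0, 2))
            for i, row in enumerate(arms):
                arm_mean[row.name] = total * (dom if i == dom_i else 1.0 - dom)

    names = list(mature_rows.name)
    counts = pd.DataFrame(0, index=names, columns=samples, dtype=int)
    for name in names:
        mu = arm_mean[name]
        for s in samples:
            lam = mu * 10.0 ** rng.normal(0.0, SAMPLE_LOG_SD)
            counts.loc[name, s] = int(rng.poisson(lam))

    lo_len, hi_len = cfg.mature_len_range
    reads_by_sample: dict[str, list[tuple[str, str, str]]] = {}
    junk_rows = []
    for s in samples:
        reads: list[tuple[str, str, str]] = []
        ridx = 0
        for row in mature_rows.itertuples():
            n = int(counts.loc[row.name, s])
            if n == 0:
                continue
            pseq = prec_seq[row.precursor]
            max_ext = min(2, len(pseq) - row.offset - row.length, hi_len - row.length)
            max_trim = min(2, row.length - lo_len)
            jitters = rng.integers(-max_trim, max_ext + 1, size=n)
            n_err = rng.binomial(row.length, cfg.seq_error_rate, size=n) if cfg.seq_error_rate > 0 else np.zeros(n, dtype=int)
            for j, k in zip(jitters, n_err):
                seq = pseq[row.offset : row.offset + row.length + j]
                if k > 0:
                    pos = rng.choice(len(seq), size=min(k, len(seq)), replace=False)
                    seq = _mutate(rng, seq, pos)
                ridx += 1
                reads.append((f"{s}_r{ridx}", seq, "I" * len(seq)))
        total_true = int(counts[s].sum())
        n_lowq = int(round(cfg.frac_low_quality * total_true))
        n_short = int(round(cfg.frac_short * total_true))
        mat_seqs = list(mature_rows.target_sequence)
        for i in range(n_lowq):
            seq = mat_seqs[int(rng.integers(0, len(mat_seqs)))]
            ridx += 1
            reads.append((f"{s}_r{ridx}", seq, "+" * len(seq)))  # Q10
        for i in range(n_short):
            length = int(rng.integers(10, 18))
            ridx += 1
            reads.append((f"{s}_r{ridx}", _random_seq(rng, length), "I" * length))
        junk_rows.append(dict(sample=s, low_quality=n_lowq, short=n_short))
        reads_by_sample[s] = reads

    gt.counts = counts
    gt.junk = pd.DataFrame(junk_rows, columns=["sample", "low_quality", "short"])
    return reads_by_sample


# ---------------------------------------------------------------------------
# RT-qPCR


def simulate_ct(gt: GroundTruth, cfg: SimConfig) -> pd.DataFrame:
    """Simulate a TLDA-style Ct table from the true expression counts.

    Ct = intercept - slope * log10(count) + Gaussian noise, clipped at the
    Undetermined sentinel (40); a zero count is always the sentinel.  One
    assay per annotated mature (a fraction carry one target-sequence
    substitution, emulating cross-species assay design) plus
    ``n_offtarget_assays`` assays matching nothing.  Fills ``gt.assays``
    with per-assay truth and returns the Ct table.
    """
    if gt.counts is None:
        raise ValueError("simulate_reads must run before simulate_ct")
    rng = _rngs(cfg, 5)[3]
    samples = list(gt.counts.columns)
    annotated = gt.matures[gt.matures.annotated & gt.matures.name.isin(gt.counts.index)]
    rows, truth_rows = [], []
    for row in annotated.itertuples():
        target = row.target_sequence
        mm = 0
        if rng.random() < cfg.frac_assay_mismatch:
            target = _mutate(rng, target, np.array([int(rng.integers(0, len(target)))]))
            mm = 1
        cts = {}
        for s in samples:
            c = int(gt.counts.loc[row.name, s])
            if c <= 0:
                cts[s] = CT_SENTINEL
            else:
                ct = cfg.ct_intercept - cfg.ct_slope * math.log10(c)
                if cfg.ct_noise_sd > 0:
                    ct += rng.normal(0.0, cfg.ct_noise_sd)
                cts[s] = min(round(ct, 3), CT_SENTINEL)
        assay = f"assay-{row.name}"
        rows.append(dict(assay_id=assay, target_sequence=target, **cts))
        truth_rows.append(
            dict(assay_id=assay, mature=row.name, target_mismatch=mm,
                 detected=float(np.mean(list(cts.values()))) <= 32.0)
        )
    for i in range(cfg.n_offtarget_assays):
        length = int(rng.integers(*cfg.mature_len_range))
        rows.append(
            dict(
                assay_id=f"assay-offtarget-{i + 1}",
                target_sequence=_random_seq(rng, length),
                **{s: CT_SENTINEL for s in samples},
            )
        )
        truth_rows.append(
            dict(assay_id=f"assay-offtarget-{i + 1}", mature=None,
                 target_mismatch=-1, detected=False)
        )
    gt.assays = pd.DataFrame(truth_rows)
    return pd.DataFrame(rows)
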