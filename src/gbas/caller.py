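"""From amplicon reads to a co-dominant genotype matrix.

Stages: merge read pairs over their overlap, assign merged reads to panel
loci by primer matching, call two alleles per sample x locus from insert
length plus internal sequence (collapsing sequencing errors and SSR stutter),
and apply the study's missingness/monomorphism/population-size filters.

Calling thresholds (minimum depth 10, minor-allele fraction 0.25, 10:1
edit-distance-1 error collapse, stutter fraction 0.5) are disclosed,
configurable defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib

from .io import AlleleLabel, Call, GenotypeMatrix, SequenceRecord, revcomp
from .primers import PrimerPair

logger = logging.getLogger("gbas")

LOW_DEPTH = "LOW_DEPTH"
AMBIGUOUS_RATIO = "AMBIGUOUS_RATIO"
STUTTER_COLLAPSED = "STUTTER_COLLAPSED"


# ---------------------------------------------------------------------------
# read merging
# ---------------------------------------------------------------------------


def merge_pairs(
    r1: SequenceRecord,
    r2: SequenceRecord,
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> SequenceRecord | None:
    """Merge a mate pair over the best ungapped 3' overlap.

    ``r2`` is reverse-complemented; overlaps of at least ``min_overlap`` are
    scored by matches minus mismatches, and the best one is accepted when its
    mismatch fraction is within ``max_mismatch_frac``. Disagreeing overlap
    bases resolve to the higher-quality call. Returns None when no acceptable
    overlap exists (e.g. insert longer than the mates can span).
    """
    s1, q1 = r1.seq, r1.qual or [30] * len(r1.seq)
    s2 = revcomp(r2.seq)
    q2 = list(reversed(r2.qual or [30] * len(r2.seq)))
    max_o = min(len(s1), len(s2))

    def evaluate(overlaps) -> tuple[int, int, int] | None:
        best: tuple[int, int, int] | None = None  # (score, overlap, mismatches)
        for o in overlaps:
            if not min_overlap <= o <= max_o:
                continue
            tail = s1[len(s1) - o :]
            head = s2[:o]
            mm = sum(a != b for a, b in zip(tail, head))
            if mm / o > max_mismatch_frac:
                continue
            score = o - 2 * mm
            if best is None or score > best[0] or (score == best[0] and o > best[1]):
                best = (score, o, mm)
        return best

    # fast path: locate the overlap via exact 20-mer seeds from the start of
    # the reverse-complemented mate, then verify; errors in all three seed
    # windows are rare, and the exhaustive scan below backs them up
    k = 20
    candidates: set[int] = set()
    for off in (0, k, 2 * k):
        if off + k > len(s2):
            break
        seed = s2[off : off + k]
        p = s1.find(seed)
        while p != -1:
            candidates.add(len(s1) - p + off)
            p = s1.find(seed, p + 1)
    best = evaluate(sorted(candidates))
    if best is None:
        best = evaluate(range(min_overlap, max_o + 1))
    if best is None:
        return None
    _, o, _ = best
    off = len(s1) - o
    merged_seq = list(s1[:off])
    merged_qual = q1[:off]
    for k in range(o):
        b1, b2 = s1[off + k], s2[k]
        if b1 == b2:
            merged_seq.append(b1)
            merged_qual.append(max(q1[off + k], q2[k]))
        elif q1[off + k] >= q2[k]:
            merged_seq.append(b1)
            merged_qual.append(q1[off + k])
        else:
            merged_seq.append(b2)
            merged_qual.append(q2[k])
    merged_seq.extend(s2[o:])
    merged_qual.extend(q2[o:])
    return SequenceRecord(r1.id, "".join(merged_seq), merged_qual)


def merge_read_pairs(
    pairs: Iterable[tuple[SequenceRecord, SequenceRecord]],
    min_overlap: int = 20,
    max_mismatch_frac: float = 0.1,
) -> list[SequenceRecord]:
    out = []
    for r1, r2 in pairs:
        m = merge_pairs(r1, r2, min_overlap, max_mismatch_frac)
        if m is not None:
            out.append(m)
    return out


# ---------------------------------------------------------------------------
# locus demultiplexing
# ---------------------------------------------------------------------------


def _hamming_leq(a: str, b: str, k: int) -> bool:
    if len(a) != len(b):
        return False
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > k:
                return False
    return True


def demultiplex_by_primer(
    merged_reads: Iterable[SequenceRecord],
    panel: Sequence[PrimerPair],
    max_mismatch: int = 2,
) -> tuple[dict[str, list[str]], list[tuple[str, str]]]:
    """Assign merged reads to loci by primer matching.

    A read must carry the forward primer at its 5' end and the reverse
    complement of the reverse primer at its 3' end, each within
    ``max_mismatch`` substitutions, for exactly one locus; primers are
    trimmed from assigned reads. Unassignable or conflicting reads go to the
    undetermined bin with a reason. Two panel loci sharing a primer sequence
    is a configuration error.
    """
    seen_f: dict[str, str] = {}
    seen_r: dict[str, str] = {}
    for p in panel:
        for store, seq in ((seen_f, p.fwd), (seen_r, p.rev)):
            if seq in store and store[seq] != p.locus_id:
                raise ValueError(
                    f"panel loci {store[seq]} and {p.locus_id} share a primer sequence"
                )
            store[seq] = p.locus_id
    by_locus: dict[str, list[str]] = {p.locus_id: [] for p in panel}
    undetermined: list[tuple[str, str]] = []
    rc_rev = {p.locus_id: revcomp(p.rev) for p in panel}
    for rec in merged_reads:
        fwd_hits = {
            p.locus_id
            for p in panel
            if len(rec.seq) >= len(p.fwd) + len(p.rev)
            and _hamming_leq(rec.seq[: len(p.fwd)], p.fwd, max_mismatch)
        }
        rev_hits = {
            p.locus_id
            for p in panel
            if len(rec.seq) >= len(p.fwd) + len(p.rev)
            and _hamming_leq(rec.seq[len(rec.seq) - len(p.rev) :], rc_rev[p.locus_id], max_mismatch)
        }
        both = fwd_hits & rev_hits
        if len(both) == 1:
            locus = next(iter(both))
            pp = next(p for p in panel if p.locus_id == locus)
            insert = rec.seq[len(pp.fwd) : len(rec.seq) - len(pp.rev)]
            if insert:
                by_locus[locus].append(insert)
            else:
                undetermined.append((rec.id, "empty insert"))
        elif len(both) > 1:
            undetermined.append((rec.id, "ambiguous"))
        elif fwd_hits and rev_hits:
            undetermined.append((rec.id, "chimeric/conflicting"))
        else:
            undetermined.append((rec.id, "no primer match"))
    return by_locus, undetermined


# ---------------------------------------------------------------------------
# allele calling
# ---------------------------------------------------------------------------


@dataclass
class LocusReadSet:
    sample_id: str
    locus_id: str
    seq_counts: dict[str, int]

    def __post_init__(self) -> None:
        if any(c <= 0 for c in self.seq_counts.values()):
            raise ValueError("read counts must be positive")


@dataclass
class GenotypeCall:
    alleles: Call | None
    depths: tuple[int, ...]
    flags: set[str] = field(default_factory=set)

    @property
    def missing(self) -> bool:
        return self.alleles is None


def _edit_distance_leq(a: str, b: str, k: int) -> bool:
    if abs(len(a) - len(b)) > k:
        return False
    return edlib.align(a, b, mode="NW", k=k)["editDistance"] != -1


def call_genotype(
    rs: LocusReadSet,
    min_depth: int = 10,
    min_allele_frac: float = 0.25,
    stutter_frac: float = 0.5,
    ssr_unit: int | None = None,
    error_collapse_ratio: int = 10,
) -> GenotypeCall:
    """Call up to two alleles from primer-trimmed insert counts.

    1) sequences within edit distance 1 of a >= ``error_collapse_ratio``-fold
       more abundant sequence fold into it (sequencing error);
    2) with ``ssr_unit`` set, sequences exactly one repeat unit shorter than a
       more abundant sequence and below ``stutter_frac`` of its count fold
       into it (PCR stutter);
    3) remaining sequences with depth >= ``min_depth`` are candidates: the
       most abundant is allele one, the runner-up is allele two iff its
       count is at least ``min_allele_frac`` of the top count;
    4) no candidates -> missing with LOW_DEPTH.
    """
    counts = dict(rs.seq_counts)
    flags: set[str] = set()

    def order(d: dict[str, int]) -> list[str]:
        return sorted(d, key=lambda s: (-d[s], s))

    # 1) error collapse, least abundant first
    for s in sorted(counts, key=lambda s: (counts[s], s)):
        if s not in counts:
            continue
        targets = [
            t
            for t in counts
            if t != s
            and counts[t] >= error_collapse_ratio * counts[s]
            and _edit_distance_leq(s, t, 1)
        ]
        if targets:
            t = order({t: counts[t] for t in targets})[0]
            counts[t] += counts.pop(s)

    # 2) stutter collapse
    if ssr_unit is not None:
        for s in sorted(counts, key=lambda s: (counts[s], s)):
            if s not in counts:
                continue
            parents = [
                t
                for t in counts
                if len(t) == len(s) + ssr_unit
                and counts[t] > counts[s]
                and counts[s] < stutter_frac * counts[t]
                and _edit_distance_leq(s, t, ssr_unit)
            ]
            if parents:
                t = order({t: counts[t] for t in parents})[0]
                counts[t] += counts.pop(s)
                flags.add(STUTTER_COLLAPSED)

    candidates = [s for s in order(counts) if counts[s] >= min_depth]
    if not candidates:
        flags.add(LOW_DEPTH)
        return GenotypeCall(None, (), flags)

    top = candidates[0]
    label_top = AlleleLabel(len(top), 0, top)
    if len(candidates) >= 2 and counts[candidates[1]] / counts[top] >= min_allele_frac:
        second = candidates[1]
        if (
            len(candidates) >= 3
            and counts[candidates[2]] / counts[top] >= min_allele_frac
        ):
            flags.add(AMBIGUOUS_RATIO)  # three plausible alleles in a diploid
        label_second = AlleleLabel(len(second), 0, second)
        a, b = sorted(
            (label_top, label_second), key=lambda l: (l.length, l.canonical_seq or "")
        )
        return GenotypeCall((a, b), (counts[top], counts[second]), flags)
    return GenotypeCall((label_top, label_top), (counts[top],), flags)


def relabel_variants(
    calls: Mapping[tuple[str, str], GenotypeCall],
    individuals: Sequence[tuple[str, str]],
    loci: Sequence[str],
) -> GenotypeMatrix:
    """Assign deterministic variant ids per locus and build the matrix.

    Within a locus, alleles of the same length get variant ids by descending
    total called depth then lexicographic sequence (ids 1..n); a length with
    a single sequence variant keeps id 0, so it serializes as plain length.
    """
    # total depth per (locus, length, seq)
    weight: dict[tuple[str, int, str], int] = {}
    for (sample, locus), call in calls.items():
        if call.alleles is None:
            continue
        labels = [call.alleles[0]]
        # provisional labels can only be told apart by sequence: variant ids
        # are all 0 before relabeling
        if (call.alleles[1].length, call.alleles[1].canonical_seq) != (
            call.alleles[0].length,
            call.alleles[0].canonical_seq,
        ):
            labels.append(call.alleles[1])
        for lab, depth in zip(labels, call.depths):
            key = (locus, lab.length, lab.canonical_seq or "")
            weight[key] = weight.get(key, 0) + depth
    variant_id: dict[tuple[str, int, str], int] = {}
    by_len: dict[tuple[str, int], list[str]] = {}
    for locus, length, seq in weight:
        by_len.setdefault((locus, length), []).append(seq)
    for (locus, length), seqs in by_len.items():
        seqs = sorted(set(seqs), key=lambda s: (-weight[(locus, length, s)], s))
        if len(seqs) == 1:
            variant_id[(locus, length, seqs[0])] = 0
        else:
            for i, s in enumerate(seqs, start=1):
                variant_id[(locus, length, s)] = i

    matrix_calls: dict[tuple[str, str], Call] = {}
    for (sample, locus), call in calls.items():
        if call.alleles is None:
            continue
        relabeled = tuple(
            AlleleLabel(
                lab.length,
                variant_id[(locus, lab.length, lab.canonical_seq or "")],
                lab.canonical_seq,
            )
            for lab in call.alleles
        )
        matrix_calls[(sample, locus)] = relabeled  # type: ignore[assignment]
    return GenotypeMatrix(list(individuals), list(loci), matrix_calls)


def genotype_samples(
    sample_reads: Mapping[str, list[SequenceRecord]],
    panel: Sequence[PrimerPair],
    populations: Mapping[str, str],
    ssr_units: Mapping[str, int] | None = None,
    max_mismatch: int = 2,
    **call_kwargs,
) -> tuple[GenotypeMatrix, dict[tuple[str, str], GenotypeCall]]:
    """Demultiplex and call every sample against a panel; returns the
    relabeled matrix plus the raw per-cell calls. ``sample_reads`` holds
    merged reads per sample; ``ssr_units`` maps SSR locus ids to their repeat
    unit length (EPIC loci omitted)."""
    ssr_units = ssr_units or {}
    calls: dict[tuple[str, str], GenotypeCall] = {}
    loci = [p.locus_id for p in panel]
    for sample, reads in sample_reads.items():
        by_locus, _ = demultiplex_by_primer(reads, panel, max_mismatch)
        for locus, inserts in by_locus.items():
            if not inserts:
                continue
            counts: dict[str, int] = {}
            for ins in inserts:
                counts[ins] = counts.get(ins, 0) + 1
            call = call_genotype(
                LocusReadSet(sample, locus, counts),
                ssr_unit=ssr_units.get(locus),
                **call_kwargs,
            )
            if not call.missing:
                calls[(sample, locus)] = call
    individuals = [(s, populations[s]) for s in sample_reads]
    return relabel_variants(calls, individuals, loci), calls


# ---------------------------------------------------------------------------
# study filters
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    dropped_samples: list[tuple[str, float]] = field(default_factory=list)
    dropped_markers: list[tuple[str, float]] = field(default_factory=list)
    dropped_monomorphic: list[str] = field(default_factory=list)
    dropped_populations: list[tuple[str, int]] = field(default_factory=list)


def is_monomorphic(m: GenotypeMatrix, locus: str) -> bool:
    alleles = {
        a for (s, l), pair in m.calls.items() if l == locus for a in pair
    }
    return len(alleles) <= 1


def apply_study_filters(
    m: GenotypeMatrix,
    max_sample_missing: float = 0.30,
    max_marker_missing: float = 0.30,
    min_pop_n: int = 5,
    drop_monomorphic: bool = True,
) -> tuple[GenotypeMatrix, FilterReport]:
    """The study's filter cascade, in order: drop samples with strictly more
    than 30% missing markers, then markers missing in strictly more than 30%
    of the remaining samples, then markers monomorphic across the whole
    dataset, then populations with fewer than ``min_pop_n`` individuals.
    Missingness denominators use the current (partially filtered) matrix."""
    report = FilterReport()

    keep_samples = []
    for sample in m.sample_ids:
        frac = m.missing_fraction_sample(sample)
        if frac > max_sample_missing:
            report.dropped_samples.append((sample, frac))
        else:
            keep_samples.append(sample)
    m = m.subset(samples=keep_samples)

    keep_loci = []
    for locus in m.loci:
        frac = m.missing_fraction_locus(locus)
        if frac > max_marker_missing:
            report.dropped_markers.append((locus, frac))
        else:
            keep_loci.append(locus)
    m = m.subset(loci=keep_loci)

    if drop_monomorphic:
        keep_loci = []
        for locus in m.loci:
            if is_monomorphic(m, locus):
                report.dropped_monomorphic.append(locus)
            else:
                keep_loci.append(locus)
        m = m.subset(loci=keep_loci)

    keep_samples = []
    for pop in m.populations:
        members = m.samples_in(pop)
        if len(members) < min_pop_n:
            report.dropped_populations.append((pop, len(members)))
        else:
            keep_samples.extend(members)
    m = m.subset(samples=keep_samples)

    if not m.individuals or not m.loci:
        raise ValueError("empty matrix after filtering")
    return m, report
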