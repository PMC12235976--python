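"""Primer pair generation and screening.

Constraints follow the study design: primer lengths 18-22 bp, optimum melting
temperature 55 °C (individual band ±3 °C, pairwise difference < 5 °C), GC
content 40-60%, a GC clamp of one to two G/C bases among the two terminal
positions at each primer end, and product sizes of 425-470 bp so that 250/300
bp paired reads merge. SSR amplicons must carry the complete repeat motif
within the first or last 250 bases so both mates read across it.

Melting temperatures are nearest-neighbor values (SantaLucia unified
parameters, 50 mM monovalent salt, 250 nM oligo), computed via Biopython.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

from Bio.SeqUtils import MeltingTemp as _mt

from .io import SequenceRecord, revcomp

#: Partial Illumina adapters appended 5' of locus-specific primers; the index
#: PCR later completes them (P5 side on forward, P7 side on reverse).
P5_TAIL = "TCTTTCCCTACACGACGCTCTTCCGATCT"
P7_TAIL = "CTGGAGTTCAGACGTGTGCTCTTCCGATCT"

# screen flags
DUPLICATED_READS = "DUPLICATED_READS"
MULTI_GENOME_HIT = "MULTI_GENOME_HIT"
NO_GENOME_HIT = "NO_GENOME_HIT"
MOTIF_PLACEMENT_FAIL = "MOTIF_PLACEMENT_FAIL"


@dataclass
class PrimerConstraints:
    min_len: int = 18
    max_len: int = 22
    tm_opt: float = 55.0
    tm_band: float = 3.0  # individual acceptance: tm_opt +/- tm_band
    max_tm_diff: float = 5.0  # strict <
    gc_min: float = 0.40
    gc_max: float = 0.60
    clamp_min: int = 1  # G/C bases among the terminal two positions, each end
    clamp_max: int = 2
    product_min: int = 425
    product_max: int = 470
    product_opt: int = 450
    motif_edge: int = 250  # SSR motif must sit within this many bases of an end


@dataclass
class PrimerPair:
    locus_id: str
    fwd: str  # 5'->3' on the template strand
    rev: str  # 5'->3' on the opposite strand
    tm_fwd: float
    tm_rev: float
    gc_fwd: float
    gc_rev: float
    product_len: int
    fwd_start: int = 0  # template coordinate of the amplicon 5' end
    tails_attached: bool = False
    tailed_fwd: str | None = None
    tailed_rev: str | None = None
    screen_flags: set[str] = field(default_factory=set)

    @property
    def accepted(self) -> bool:
        return not self.screen_flags


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


@lru_cache(maxsize=65536)
def melting_temperature(seq: str) -> float:
    """Nearest-neighbor Tm (°C) at 50 mM Na+, 250 nM oligo.

    SantaLucia unified NN parameters with the SantaLucia (1998) entropy salt
    correction. Ambiguity codes are rejected.
    """
    if len(seq) < 8:
        raise ValueError("Tm undefined for oligos shorter than 8 nt")
    if set(seq) - set("ACGT"):
        raise ValueError(f"ambiguity codes not supported in {seq!r}")
    return float(_mt.Tm_NN(seq, Na=50, dnac1=250, dnac2=0, saltcorr=5))


def passes_single_primer(seq: str, c: PrimerConstraints) -> bool:
    """All per-primer predicates: length, GC content, terminal GC clamps,
    individual Tm band."""
    if not (c.min_len <= len(seq) <= c.max_len):
        return False
    gc = gc_fraction(seq)
    if not (c.gc_min <= gc <= c.gc_max):
        return False
    for end in (seq[:2], seq[-2:]):
        n_gc = sum(b in "GC" for b in end)
        if not (c.clamp_min <= n_gc <= c.clamp_max):
            return False
    tm = melting_temperature(seq)
    return c.tm_opt - c.tm_band <= tm <= c.tm_opt + c.tm_band


def _in_windows(start: int, end: int, windows: Sequence[tuple[int, int]] | None) -> bool:
    if windows is None:
        return True
    return any(ws <= start and end <= we for ws, we in windows)


def design_pairs(
    template: str,
    constraints: PrimerConstraints | None = None,
    motif_span: tuple[int, int] | None = None,
    windows: Sequence[tuple[int, int]] | None = None,
    locus_id: str = "locus",
    max_pairs: int | None = None,
) -> list[PrimerPair]:
    """Enumerate constraint-satisfying primer pairs on a template.

    ``motif_span`` (SSR mode) restricts pairs to amplicons whose complete
    repeat motif lies within the first or last ``motif_edge`` bases and whose
    primers do not overlap the motif. ``windows`` (EPIC mode) restricts primer
    footprints to conserved intervals. Pairs are ranked by summed distance of
    both Tm values from the optimum, then product-length distance from the
    optimum, then 5'-most forward position. No feasible pair yields an empty
    list.
    """
    c = constraints or PrimerConstraints()
    template = template.upper()
    n = len(template)

    fwd_by_start: dict[int, list[str]] = {}
    rev_by_end: dict[int, list[str]] = {}
    for length in range(c.min_len, c.max_len + 1):
        for i in range(0, n - length + 1):
            seq = template[i : i + length]
            if "N" in seq:
                continue
            if _in_windows(i, i + length, windows) and passes_single_primer(seq, c):
                fwd_by_start.setdefault(i, []).append(seq)
            # reverse primer covering template[j-length:j], amplicon 3' end = j
            j = i + length
            rseq = revcomp(seq)
            if _in_windows(i, j, windows) and passes_single_primer(rseq, c):
                rev_by_end.setdefault(j, []).append(rseq)

    pairs: list[PrimerPair] = []
    for i, fwds in sorted(fwd_by_start.items()):
        for j in range(i + c.product_min, min(n, i + c.product_max) + 1):
            revs = rev_by_end.get(j)
            if not revs:
                continue
            product = j - i
            if motif_span is not None:
                ms, me = motif_span
                if not (i <= ms and me <= j):
                    continue  # motif must be inside the amplicon
                near_start = me - i <= c.motif_edge
                near_end = j - ms <= c.motif_edge
                if not (near_start or near_end):
                    continue
            for fwd in fwds:
                if motif_span is not None and i + len(fwd) > motif_span[0]:
                    continue  # primer must not run into the motif
                tm_f = melting_temperature(fwd)
                for rev in revs:
                    if motif_span is not None and j - len(rev) < motif_span[1]:
                        continue
                    tm_r = melting_temperature(rev)
                    if abs(tm_f - tm_r) >= c.max_tm_diff:
                        continue
                    pairs.append(
                        PrimerPair(
                            locus_id=locus_id,
                            fwd=fwd,
                            rev=rev,
                            tm_fwd=tm_f,
                            tm_rev=tm_r,
                            gc_fwd=gc_fraction(fwd),
                            gc_rev=gc_fraction(rev),
                            product_len=product,
                            fwd_start=i,
                        )
                    )
    pairs.sort(
        key=lambda p: (
            abs(p.tm_fwd - c.tm_opt) + abs(p.tm_rev - c.tm_opt),
            abs(p.product_len - c.product_opt),
            p.fwd_start,
        )
    )
    return pairs[:max_pairs] if max_pairs else pairs


# ---------------------------------------------------------------------------
# screens
# ---------------------------------------------------------------------------


def _matches_with_mismatches(read: str, primer: str, max_mismatch: int) -> bool:
    lp = len(primer)
    for i in range(len(read) - lp + 1):
        mm = 0
        window = read[i : i + lp]
        for a, b in zip(window, primer):
            if a != b:
                mm += 1
                if mm > max_mismatch:
                    break
        else:
            return True
    return False


def count_read_matches(
    primer: str, reads: Iterable[SequenceRecord], max_mismatch: int = 1
) -> int:
    """Reads containing a full-length occurrence of the primer (either
    strand) with at most ``max_mismatch`` substitutions."""
    rc = revcomp(primer)
    count = 0
    for rec in reads:
        if _matches_with_mismatches(rec.seq, primer, max_mismatch) or _matches_with_mismatches(
            rec.seq, rc, max_mismatch
        ):
            count += 1
    return count


def duplication_screen_reads(
    pair: PrimerPair,
    library_reads: Sequence[SequenceRecord],
    max_mismatch: int = 1,
    min_support: int = 0,
) -> PrimerPair:
    """Flag DUPLICATED_READS when either primer is matched by more than one
    shotgun read — a primer drawn from a repeated region would be. The rule
    as stated passes zero-support primers; ``min_support`` > 0 optionally
    also requires at least that many matching reads."""
    for primer in (pair.fwd, pair.rev):
        n = count_read_matches(primer, library_reads, max_mismatch)
        if n > 1 or n < min_support:
            pair.screen_flags.add(DUPLICATED_READS)
            break
    return pair


def _exact_hits(primer: str, genome: Mapping[str, SequenceRecord]) -> list[tuple[str, str, int]]:
    """(contig, orientation, start) of exact occurrences; orientation 'F'
    means the literal primer, 'R' its reverse complement."""
    hits = []
    rc = revcomp(primer)
    for contig, rec in genome.items():
        for orient, needle in (("F", primer), ("R", rc)):
            pos = rec.seq.find(needle)
            while pos != -1:
                hits.append((contig, orient, pos))
                pos = rec.seq.find(needle, pos + 1)
    return hits


def genome_screen(
    pair: PrimerPair,
    reference_genome: Mapping[str, SequenceRecord],
    product_window: tuple[int, int] | None = None,
) -> PrimerPair:
    """Exact-match both primers against a reference genome.

    Zero hits for either primer suggests contamination (NO_GENOME_HIT); two
    or more hits suggests duplication (MULTI_GENOME_HIT); a unique hit for
    each, inward-facing at a product-window-compatible distance, passes.
    """
    if product_window is None:
        c = PrimerConstraints()
        product_window = (c.product_min, c.product_max)
    hf = _exact_hits(pair.fwd, reference_genome)
    hr = _exact_hits(pair.rev, reference_genome)
    if not hf or not hr:
        pair.screen_flags.add(NO_GENOME_HIT)
        return pair
    if len(hf) > 1 or len(hr) > 1:
        pair.screen_flags.add(MULTI_GENOME_HIT)
        return pair
    (cf, of, sf), (cr, orr, sr) = hf[0], hr[0]
    lo, hi = product_window
    ok = False
    if cf == cr:
        if of == "F" and orr == "R" and sr >= sf:
            ok = lo <= sr + len(pair.rev) - sf <= hi
        elif of == "R" and orr == "F" and sf >= sr:
            ok = lo <= sf + len(pair.fwd) - sr <= hi
    if not ok:
        # unique hits that cannot form the intended product: no genomic
        # support for the amplicon
        pair.screen_flags.add(NO_GENOME_HIT)
    return pair


def attach_tails(pair: PrimerPair) -> PrimerPair:
    """Prefix the partial Illumina adapters (P5 on forward, P7 on reverse).
    Re-tailing an already tailed pair is an error."""
    if pair.tails_attached:
        raise ValueError(f"{pair.locus_id}: tails already attached")
    pair.tailed_fwd = P5_TAIL + pair.fwd
    pair.tailed_rev = P7_TAIL + pair.rev
    pair.tails_attached = True
    return pair
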