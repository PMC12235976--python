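"""Microsatellite (SSR) detection in shotgun reads.

Finds maximal perfect tandem repeats of 2-5 bp units, requiring a minimum
repeat count per unit length (default 10 for 2mers, 8 for 3mers, 4 for
4/5mers) and flanking sequence strictly longer than 20 bp on both sides.
Units that are themselves periodic (e.g. ACAC as a 4mer) are reported at
their smallest period only; homopolymers are never mined.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping

from .io import SequenceRecord

DEFAULT_THRESHOLDS: dict[int, int] = {2: 10, 3: 8, 4: 4, 5: 4}
DEFAULT_MIN_FLANK = 20

#: Unit lengths forwarded to primer design; shorter units slip too readily
#: under Taq polymerase to make robust markers.
PRIMER_DESIGN_UNIT_LENGTHS = (4, 5)


@dataclass(frozen=True)
class SsrCandidate:
    """One maximal perfect tandem run on a read."""

    read_id: str
    motif: str  # canonical: lexicographically minimal rotation, read strand
    unit_len: int
    n_repeats: int
    start: int
    end: int  # half-open span on read; end - start == unit_len * n_repeats
    left_flank_len: int
    right_flank_len: int


def canonical_rotation(unit: str) -> str:
    """Lexicographically minimal rotation of a repeat unit (read strand only)."""
    doubled = unit + unit
    return min(doubled[i : i + len(unit)] for i in range(len(unit)))


def smallest_period(unit: str) -> int:
    """Smallest p dividing len(unit) such that unit is p-periodic."""
    n = len(unit)
    for p in range(1, n):
        if n % p == 0 and unit == unit[:p] * (n // p):
            return p
    return n


def scan_read(
    rec: SequenceRecord,
    thresholds: Mapping[int, int] | None = None,
    min_flank: int = DEFAULT_MIN_FLANK,
) -> list[SsrCandidate]:
    """Report every maximal perfect tandem run meeting its unit-length
    threshold with both flanks strictly longer than ``min_flank``.

    Runs containing N are terminated at the N. A run whose unit is periodic
    with a smaller period is reported only at that smaller period.
    """
    if thresholds is None:
        thresholds = DEFAULT_THRESHOLDS
    seq = rec.seq
    n = len(seq)
    out: list[SsrCandidate] = []
    for unit_len, min_rep in sorted(thresholds.items()):
        if unit_len < 2:
            continue  # homopolymers are not mined
        p = unit_len
        # m[x]: position x continues a period-p stretch (N breaks it)
        x = p
        while x < n:
            if seq[x] != seq[x - p] or seq[x] == "N":
                x += 1
                continue
            a = x  # maximal interval [a, b) of continuing positions
            while x < n and seq[x] == seq[x - p] and seq[x] != "N":
                x += 1
            b = x
            start = a - p
            n_rep = (b - start) // p
            unit = seq[start : start + p]
            if n_rep < max(min_rep, 2) or "N" in unit or smallest_period(unit) != p:
                continue
            end = start + n_rep * p
            left, right = start, n - end
            if left > min_flank and right > min_flank:
                out.append(
                    SsrCandidate(
                        read_id=rec.id,
                        motif=canonical_rotation(unit),
                        unit_len=p,
                        n_repeats=n_rep,
                        start=start,
                        end=end,
                        left_flank_len=left,
                        right_flank_len=right,
                    )
                )
    out.sort(key=lambda c: (c.start, c.unit_len))
    return out


def scan_reads(
    reads: Iterable[SequenceRecord],
    thresholds: Mapping[int, int] | None = None,
    min_flank: int = DEFAULT_MIN_FLANK,
) -> list[SsrCandidate]:
    candidates: list[SsrCandidate] = []
    for rec in reads:
        candidates.extend(scan_read(rec, thresholds, min_flank))
    return candidates


def classify_counts(candidates: Iterable[SsrCandidate]) -> dict[int, int]:
    """Reads per unit-length class; a read counts once per class in which it
    has at least one candidate (so a read with a 2mer and a 4mer counts in
    both)."""
    per_class: dict[int, set[str]] = {u: set() for u in (2, 3, 4, 5)}
    for c in candidates:
        per_class.setdefault(c.unit_len, set()).add(c.read_id)
    return {u: len(ids) for u, ids in sorted(per_class.items())}


def motif_summary(candidates: Iterable[SsrCandidate]) -> Counter:
    """Counts of canonical motifs across candidates."""
    return Counter(c.motif for c in candidates)
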