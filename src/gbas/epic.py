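"""Exon-primed intron-crossing (EPIC) marker mining.

Workflow: select contiguous exon pairs from an annotated donor genome whose
exons are long enough to host primers (> 20 bp) and whose intervening intron
is short (< 400 bp); locate each pair on a target genome by exact k-mer
seeding plus local affine-gap alignment; and mark fully conserved windows
within the aligned exon footprints where primers may sit.

Exons are conserved across related species while introns diverge, so primers
anchored in 100%-identical exon windows amplify a variable intron in both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio import Align

from .io import GeneModel, SequenceRecord, revcomp

logger = logging.getLogger("gbas")

DEFAULT_MAX_INTRON = 400
DEFAULT_MIN_EXON = 20
DEFAULT_MIN_SEED = 15
#: amplicon window the study's chemistry targets (both MiSeq and NovaSeq
#: 300/250 bp paired reads merge over a ~450 bp product)
DEFAULT_PRODUCT_WINDOW = (425, 470)
MIN_PRIMER_LEN = 18

# alignment scoring for exon placement: match +1, mismatch -2,
# gap open -5, gap extend -2
def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


@dataclass(frozen=True)
class ExonPair:
    """A donor-genome candidate: two contiguous exons around a short intron."""

    gene_id: str
    pair_index: int  # index of the 5' exon within the gene
    exon5: str
    exon3: str
    intron_len: int
    product_compatible: bool  # some primer placement can yield an in-window product


@dataclass
class ExonAlignment:
    """Alignment of one donor exon onto the target region.

    ``columns`` lists (target_pos, donor_base, target_base, match) for aligned
    (non-gap) columns, target_pos in target_region coordinates.
    """

    target_start: int
    target_end: int
    identity: float
    coverage: float  # aligned fraction of the donor exon
    columns: list[tuple[int, str, str, bool]] = field(repr=False, default_factory=list)


@dataclass
class EpicLocus:
    gene_id: str
    donor_exon5: str
    donor_exon3: str
    donor_intron_len: int
    target_region: str
    exon_alignments: list[ExonAlignment]
    conserved_windows: list[tuple[int, int]] = field(default_factory=list)
    target_contig: str = ""
    target_strand: str = "+"
    target_offset: int = 0  # contig coordinate of target_region[0] (on strand)


def product_window_compatible(
    exon5_len: int,
    exon3_len: int,
    intron_len: int,
    product_window: tuple[int, int] = DEFAULT_PRODUCT_WINDOW,
    tolerance: int = 0,
) -> bool:
    """Can any primer placement in the two exons produce a product whose
    length falls inside ``product_window``? The shortest product hugs the
    intron with minimum-length primers; the longest spans both whole exons."""
    lo, hi = product_window[0] - tolerance, product_window[1] + tolerance
    shortest = intron_len + 2 * MIN_PRIMER_LEN
    longest = exon5_len + intron_len + exon3_len
    return shortest <= hi and longest >= lo


def select_exon_pairs(
    genes: Sequence[GeneModel],
    genome: Mapping[str, SequenceRecord],
    max_intron: int = DEFAULT_MAX_INTRON,
    min_exon: int = DEFAULT_MIN_EXON,
    product_window: tuple[int, int] = DEFAULT_PRODUCT_WINDOW,
    product_tolerance: int = 0,
) -> list[ExonPair]:
    """Emit every consecutive exon pair with both exon lengths > ``min_exon``
    and intron length < ``max_intron`` (both strict). A gene may emit several
    pairs; genes with no qualifying pair contribute nothing."""
    out: list[ExonPair] = []
    for gene in genes:
        exon_seqs = gene.exon_seqs(genome)
        intron_lens = gene.intron_lengths()
        for i, intron_len in enumerate(intron_lens):
            e5, e3 = exon_seqs[i], exon_seqs[i + 1]
            if len(e5) > min_exon and len(e3) > min_exon and intron_len < max_intron:
                compat = product_window_compatible(
                    len(e5), len(e3), intron_len, product_window, product_tolerance
                )
                out.append(ExonPair(gene.gene_id, i, e5, e3, intron_len, compat))
    return out


def _seed_hits(query: str, target: str, k: int) -> list[int]:
    """Target positions of exact k-mer seeds taken from the query."""
    index: dict[str, list[int]] = {}
    for i in range(len(target) - k + 1):
        index.setdefault(target[i : i + k], []).append(i)
    hits: set[int] = set()
    for q in range(0, len(query) - k + 1, max(1, k // 3)):
        kmer = query[q : q + k]
        for t in index.get(kmer, ()):
            hits.add(t - q)  # approximate start of the full query in target
    return sorted(hits)


def _cluster_diagonals(starts: list[int], slack: int) -> list[int]:
    """Collapse nearby approximate start positions into candidate placements."""
    clusters: list[int] = []
    for s in starts:
        if clusters and s - clusters[-1] <= slack:
            continue
        clusters.append(s)
    return clusters


def _align_exon(
    aligner: Align.PairwiseAligner, exon: str, region: str, region_offset: int
) -> ExonAlignment | None:
    if not region:
        return None
    alns = aligner.align(exon, region)
    if len(alns) == 0:
        return None
    aln = alns[0]
    columns: list[tuple[int, str, str, bool]] = []
    matches = 0
    aligned_q = 0
    for (qs, qe), (ts, te) in zip(*aln.aligned):
        for dq in range(qe - qs):
            db, tb = exon[qs + dq], region[ts + dq]
            ok = db == tb
            matches += ok
            columns.append((region_offset + ts + dq, db, tb, ok))
        aligned_q += qe - qs
    if aligned_q == 0:
        return None
    identity = matches / aligned_q
    coverage = aligned_q / len(exon)
    t_start = aln.aligned[1][0][0] + region_offset
    t_end = aln.aligned[1][-1][1] + region_offset
    return ExonAlignment(t_start, t_end, identity, coverage, columns)


def map_to_target(
    pair: ExonPair,
    target_genome: Mapping[str, SequenceRecord],
    min_seed: int = DEFAULT_MIN_SEED,
    min_identity: float = 0.70,
    min_coverage: float = 0.80,
    intron_slack: float = 1.5,
) -> EpicLocus | None:
    """Place a donor exon pair on the target genome.

    The 5' exon is located by exact ``min_seed``-mer seeds (both strands) and
    banded local alignment; the region is extended rightwards to cover the
    homologous intron (allowing ``intron_slack`` x the donor intron length)
    and the 3' exon, which is re-aligned within the extension. Returns None
    when either exon falls below the identity/coverage floor, when no seed
    hits exist, or when two placements score equally (duplication suspect).
    """
    aligner = _make_aligner()
    margin = 50
    ext_len = int(pair.intron_len * intron_slack) + len(pair.exon3) + margin

    candidates: list[tuple[float, str, str, int, ExonAlignment, str]] = []
    for contig_id, rec in target_genome.items():
        for strand in "+-":
            seq = rec.seq if strand == "+" else revcomp(rec.seq)
            starts = _cluster_diagonals(
                _seed_hits(pair.exon5, seq, min_seed), slack=len(pair.exon5)
            )
            for s in starts:
                w_lo = max(0, s - margin)
                w_hi = min(len(seq), s + len(pair.exon5) + margin)
                aln5 = _align_exon(aligner, pair.exon5, seq[w_lo:w_hi], w_lo)
                if aln5 is None:
                    continue
                score = sum(1 if m else -2 for _, _, _, m in aln5.columns)
                candidates.append((score, contig_id, strand, s, aln5, seq))

    if not candidates:
        return None
    candidates.sort(key=lambda c: -c[0])
    if len(candidates) > 1 and candidates[0][0] == candidates[1][0]:
        logger.warning(
            "gene %s: ambiguous placement (duplication suspect), dropped", pair.gene_id
        )
        return None
    _, contig_id, strand, _, aln5, seq = candidates[0]
    if aln5.identity < min_identity or aln5.coverage < min_coverage:
        return None

    region_start = aln5.target_start
    region_hi = min(len(seq), aln5.target_end + ext_len)
    aln3 = _align_exon(
        aligner, pair.exon3, seq[aln5.target_end : region_hi], aln5.target_end
    )
    if aln3 is None or aln3.identity < min_identity or aln3.coverage < min_coverage:
        return None
    region_end = aln3.target_end
    target_region = seq[region_start:region_end]

    def shift(a: ExonAlignment) -> ExonAlignment:
        return ExonAlignment(
            a.target_start - region_start,
            a.target_end - region_start,
            a.identity,
            a.coverage,
            [(p - region_start, d, t, m) for p, d, t, m in a.columns],
        )

    locus = EpicLocus(
        gene_id=pair.gene_id,
        donor_exon5=pair.exon5,
        donor_exon3=pair.exon3,
        donor_intron_len=pair.intron_len,
        target_region=target_region,
        exon_alignments=[shift(aln5), shift(aln3)],
        target_contig=contig_id,
        target_strand=strand,
        target_offset=region_start,
    )
    locus.conserved_windows = find_conserved_windows(locus)
    return locus


def find_conserved_windows(locus: EpicLocus, min_len: int = MIN_PRIMER_LEN) -> list[tuple[int, int]]:
    """Maximal runs of donor/target-identical alignment columns of length
    >= ``min_len``, restricted to exon footprints, as (start, end) intervals
    on ``target_region``. A gap or mismatch column breaks the run."""
    windows: list[tuple[int, int]] = []
    for aln in locus.exon_alignments:
        run_start: int | None = None
        prev_pos: int | None = None

        def flush(end_pos: int) -> None:
            nonlocal run_start
            if run_start is not None and end_pos - run_start >= min_len:
                windows.append((run_start, end_pos))
            run_start = None

        for pos, _, _, match in aln.columns:
            if prev_pos is not None and pos != prev_pos + 1:
                flush(prev_pos + 1)  # gap in target coordinates breaks the run
            if match:
                if run_start is None:
                    run_start = pos
            else:
                flush(pos)
            prev_pos = pos
        if prev_pos is not None:
            flush(prev_pos + 1)
    return sorted(windows)


def mine_epic_loci(
    genes: Sequence[GeneModel],
    donor_genome: Mapping[str, SequenceRecord],
    target_genome: Mapping[str, SequenceRecord],
    max_intron: int = DEFAULT_MAX_INTRON,
    min_exon: int = DEFAULT_MIN_EXON,
    min_seed: int = DEFAULT_MIN_SEED,
    product_window: tuple[int, int] = DEFAULT_PRODUCT_WINDOW,
    product_tolerance: int = 0,
    require_product_compatible: bool = True,
) -> list[EpicLocus]:
    """Full mining pass: exon-pair selection, product-window triage, target
    placement and conserved-window annotation."""
    pairs = select_exon_pairs(
        genes, donor_genome, max_intron, min_exon, product_window, product_tolerance
    )
    loci: list[EpicLocus] = []
    for pair in pairs:
        if require_product_compatible and not pair.product_compatible:
            continue
        locus = map_to_target(pair, target_genome, min_seed=min_seed)
        if locus is not None:
            loci.append(locus)
    return loci
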