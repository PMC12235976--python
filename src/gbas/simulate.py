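"""Seeded generators for every pipeline input.

Three simulators: (i) island-model diploid genotypes — per-locus ancestral
allele frequencies drawn from a symmetric Dirichlet, per-population
frequencies drawn Balding-Nichols with drift parameter F (whose expectation
equals FST), genotypes drawn under within-population Hardy-Weinberg, with
optional null alleles and extra missingness; (ii) amplicon read sets for a
primer panel with sequencing error and SSR stutter; (iii) toy donor/target
genome pairs with exon-conserved / intron-divergent gene models and planted
SSR motifs. Every generator is bit-reproducible under a fixed seed and
returns a truth record sufficient to score the corresponding pipeline stage.

Default scale mirrors the study design: five populations of 6, 5, 9, 5 and
16 individuals and 30 co-dominant loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io import AlleleLabel, Call, GenotypeMatrix, SequenceRecord, revcomp
from .primers import PrimerPair
from .ssr import smallest_period

BASES = "ACGT"


@dataclass
class SimConfig:
    """Shared knobs for all generators. Rates are probabilities in [0, 1];
    ``F`` in [0, 1) is the Balding-Nichols drift parameter."""

    seed: int
    # genotypes
    pop_sizes: tuple[int, ...] = (6, 5, 9, 5, 16)
    n_loci: int = 30
    n_alleles: int = 6
    F: float = 0.1
    null_rate: float = 0.0
    missing_rate: float = 0.0
    snp_variant_frac: float = 0.3  # loci with a same-length SNP variant pair
    # amplicons
    depth_mean: float = 100.0
    depth_dispersion: float | None = 10.0  # None: constant depth = depth_mean
    error_rate: float = 0.001
    stutter_rate: float = 0.05
    read_len: int = 300
    ssr_unit: int = 4
    core_flank_total: int = 340  # flank bp around the repeat in allele cores
    base_repeats: int = 6
    # genome pairs
    n_genes: int = 12
    n_qualifying: int = 6
    exon_divergence: float = 0.0
    intron_divergence: float = 0.1
    spacer_len: int = 300
    spacer_divergence: float = 0.3
    n_planted_ssr: int = 5
    planted_ssr_repeats: int = 8
    planted_ssr_flank: int = 30

    def __post_init__(self) -> None:
        for name in (
            "F",
            "null_rate",
            "missing_rate",
            "error_rate",
            "stutter_rate",
            "snp_variant_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.F < 1.0:
            raise ValueError("F must be in [0, 1)")
        if self.n_loci < 1 or self.n_alleles < 1 or not self.pop_sizes:
            raise ValueError("infeasible config: need >= 1 locus, allele, population")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def _aperiodic_unit(rng: np.random.Generator, unit_len: int) -> str:
    while True:
        unit = _random_seq(rng, unit_len)
        if smallest_period(unit) == unit_len and len(set(unit)) > 1:
            return unit


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    chars = list(seq)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for i in hits:
        alternatives = [b for b in BASES if b != chars[i]]
        chars[i] = alternatives[int(rng.integers(3))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# allele definitions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlleleDef:
    """A simulated allele: SSR-style core = left + unit x repeats + right.
    SNP variants share repeat count but differ at one flank position."""

    seq: str
    left: str
    unit: str
    repeats: int
    right: str

    @property
    def length(self) -> int:
        return len(self.seq)

    def stuttered(self) -> str:
        return self.left + self.unit * (self.repeats - 1) + self.right


def _make_locus_alleles(rng: np.random.Generator, cfg: SimConfig) -> list[AlleleDef]:
    unit = _aperiodic_unit(rng, cfg.ssr_unit)
    half = cfg.core_flank_total // 2
    left = _random_seq(rng, half)
    right = _random_seq(rng, cfg.core_flank_total - half)
    defs: list[AlleleDef] = []
    for i in range(cfg.n_alleles):
        reps = cfg.base_repeats + i
        defs.append(AlleleDef(left + unit * reps + right, left, unit, reps, right))
    if cfg.n_alleles >= 2 and rng.random() < cfg.snp_variant_frac:
        # replace the last allele with a same-length SNP variant of the first
        donor = defs[0]
        pos = int(rng.integers(len(donor.left)))
        alt = [b for b in BASES if b != donor.left[pos]][int(rng.integers(3))]
        new_left = donor.left[:pos] + alt + donor.left[pos + 1 :]
        defs[-1] = AlleleDef(
            new_left + donor.unit * donor.repeats + donor.right,
            new_left,
            donor.unit,
            donor.repeats,
            donor.right,
        )
    return defs


def _labels_for(defs: Sequence[AlleleDef]) -> list[AlleleLabel]:
    """Deterministic AlleleLabels: unique lengths get variant 0; duplicated
    lengths get 1..n in lexicographic sequence order."""
    by_len: dict[int, list[str]] = {}
    for d in defs:
        by_len.setdefault(d.length, []).append(d.seq)
    labels = []
    for d in defs:
        seqs = sorted(set(by_len[d.length]))
        vid = 0 if len(seqs) == 1 else seqs.index(d.seq) + 1
        labels.append(AlleleLabel(d.length, vid, d.seq))
    return labels


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeTruth:
    allele_defs: dict[str, list[AlleleDef]]
    allele_labels: dict[str, list[AlleleLabel]]
    ancestral_freqs: dict[str, np.ndarray]
    pop_freqs: dict[tuple[str, str], np.ndarray]
    true_genotypes: dict[tuple[str, str], tuple[int, int]]  # allele indices
    null_cells: set[tuple[str, str]] = field(default_factory=set)  # one null copy
    null_missing: set[tuple[str, str]] = field(default_factory=set)  # null/null
    extra_missing: set[tuple[str, str]] = field(default_factory=set)
    apparent: "GenotypeMatrix | None" = None


def simulate_genotypes(cfg: SimConfig) -> tuple[GenotypeMatrix, GenotypeTruth]:
    """Balding-Nichols structured diploid genotypes.

    Null alleles act per transmitted copy at ``null_rate``: null/null cells
    become missing, null/visible cells appear as visible homozygotes. The
    returned matrix is the apparent (corrupted) one; the truth record keeps
    the latent state.
    """
    rng = np.random.default_rng(cfg.seed)
    pops = [f"pop{i + 1}" for i in range(len(cfg.pop_sizes))]
    individuals = [
        (f"{pop}_{j + 1:02d}", pop)
        for pop, size in zip(pops, cfg.pop_sizes)
        for j in range(size)
    ]
    loci = [f"L{i + 1:03d}" for i in range(cfg.n_loci)]

    truth = GenotypeTruth({}, {}, {}, {}, {})
    calls: dict[tuple[str, str], Call] = {}
    for locus in loci:
        defs = _make_locus_alleles(rng, cfg)
        labels = _labels_for(defs)
        truth.allele_defs[locus] = defs
        truth.allele_labels[locus] = labels
        anc = rng.dirichlet(np.ones(cfg.n_alleles))
        truth.ancestral_freqs[locus] = anc
        for pop in pops:
            if cfg.F == 0:
                p = anc.copy()
            else:
                p = rng.dirichlet(anc * (1 - cfg.F) / cfg.F)
            truth.pop_freqs[(pop, locus)] = p
        for sample, pop in individuals:
            p = truth.pop_freqs[(pop, locus)]
            i, j = rng.choice(cfg.n_alleles, size=2, p=p)
            truth.true_genotypes[(sample, locus)] = (int(i), int(j))
            null_i = rng.random() < cfg.null_rate
            null_j = rng.random() < cfg.null_rate
            cell = (sample, locus)
            if null_i and null_j:
                truth.null_missing.add(cell)
                continue
            if null_i or null_j:
                truth.null_cells.add(cell)
                vis = int(j) if null_i else int(i)
                pair = (labels[vis], labels[vis])
            else:
                pair = (labels[int(i)], labels[int(j)])
            if rng.random() < cfg.missing_rate:
                truth.extra_missing.add(cell)
                continue
            calls[cell] = tuple(sorted(pair))  # type: ignore[assignment]
    matrix = GenotypeMatrix(individuals, loci, calls)
    truth.apparent = matrix
    return matrix, truth


# ---------------------------------------------------------------------------
# amplicon reads
# ---------------------------------------------------------------------------


def make_panel(truth: GenotypeTruth, seed: int, primer_len: int = 20) -> list[PrimerPair]:
    """Deterministic synthetic primer panel for the simulated loci: random
    GC-balanced primers, mutually distant so demultiplexing is unambiguous."""
    rng = np.random.default_rng(seed)
    used: list[str] = []

    def fresh() -> str:
        while True:
            seq = _random_seq(rng, primer_len)
            gc = (seq.count("G") + seq.count("C")) / primer_len
            if not 0.4 <= gc <= 0.6:
                continue
            if all(sum(a != b for a, b in zip(seq, u)) > 6 for u in used):
                used.append(seq)
                return seq

    panel = []
    for locus in truth.allele_defs:
        fwd, rev = fresh(), fresh()
        mean_len = int(np.mean([d.length for d in truth.allele_defs[locus]]))
        panel.append(
            PrimerPair(
                locus_id=locus,
                fwd=fwd,
                rev=rev,
                tm_fwd=55.0,
                tm_rev=55.0,
                gc_fwd=0.5,
                gc_rev=0.5,
                product_len=mean_len + 2 * primer_len,
            )
        )
    return panel


@dataclass
class AmpliconTruth:
    depths: dict[tuple[str, str], tuple[int, int]]  # reads drawn per allele
    stutter_reads: dict[tuple[str, str], int]
    unmergeable: set[str] = field(default_factory=set)  # loci too long to merge


def simulate_amplicons(
    m: GenotypeMatrix,
    panel: Sequence[PrimerPair],
    truth: GenotypeTruth,
    cfg: SimConfig,
    min_overlap: int = 20,
) -> tuple[dict[str, list[tuple[SequenceRecord, SequenceRecord]]], AmpliconTruth]:
    """Paired amplicon reads per sample for every non-missing call.

    Depth is negative-binomial (mean ``depth_mean``), reads split binomially
    between the two alleles, substitution errors applied per base, and SSR
    stutter reads (one repeat unit shorter) emitted at ``stutter_rate``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    primers = {p.locus_id: p for p in panel}
    label_to_def: dict[tuple[str, int, int], AlleleDef] = {}
    for locus, labels in truth.allele_labels.items():
        for lab, d in zip(labels, truth.allele_defs[locus]):
            label_to_def[(locus, lab.length, lab.variant_id)] = d
    amp_truth = AmpliconTruth({}, {})
    reads: dict[str, list[tuple[SequenceRecord, SequenceRecord]]] = {
        s: [] for s in m.sample_ids
    }
    if cfg.depth_dispersion is not None:
        nb_n = cfg.depth_dispersion
        nb_p = nb_n / (nb_n + cfg.depth_mean)
    for (sample, locus), pair in sorted(m.calls.items()):
        prim = primers[locus]
        if cfg.depth_dispersion is None:
            depth = int(round(cfg.depth_mean))
        else:
            depth = int(rng.negative_binomial(nb_n, nb_p))
        if depth == 0:
            continue
        d1 = int(rng.binomial(depth, 0.5)) if pair[0] != pair[1] else depth
        counts = [(pair[0], d1), (pair[1], depth - d1)] if pair[0] != pair[1] else [
            (pair[0], depth)
        ]
        amp_truth.depths[(sample, locus)] = (
            (d1, depth - d1) if pair[0] != pair[1] else (depth, 0)
        )
        n_stutter = 0
        for lab, n_reads in counts:
            adef = label_to_def[(locus, lab.length, lab.variant_id)]
            amplicon_len = len(prim.fwd) + adef.length + len(prim.rev)
            if amplicon_len > 2 * cfg.read_len - min_overlap:
                amp_truth.unmergeable.add(locus)
            for k in range(n_reads):
                core = adef.seq
                if (
                    cfg.stutter_rate > 0
                    and adef.repeats >= 2
                    and rng.random() < cfg.stutter_rate
                ):
                    core = adef.stuttered()
                    n_stutter += 1
                amplicon = prim.fwd + core + revcomp(prim.rev)
                amplicon = _mutate(rng, amplicon, cfg.error_rate)
                r1 = amplicon[: cfg.read_len]
                r2 = revcomp(amplicon)[: cfg.read_len]
                rid = f"{sample}:{locus}:{k}"
                reads[sample].append(
                    (
                        SequenceRecord(rid, r1, [37] * len(r1)),
                        SequenceRecord(rid, r2, [37] * len(r2)),
                    )
                )
        if n_stutter:
            amp_truth.stutter_reads[(sample, locus)] = n_stutter
    return reads, amp_truth


def calls_match_by_sequence(truth_m: GenotypeMatrix, called_m: GenotypeMatrix) -> bool:
    """Cell-by-cell equality on (length, canonical sequence) — robust to the
    caller's depth-based variant-id numbering."""

    def key(pair: Call) -> tuple:
        return tuple(
            sorted((a.length, a.canonical_seq or "") for a in pair)
        )

    if set(truth_m.sample_ids) != set(called_m.sample_ids):
        return False
    if set(truth_m.loci) != set(called_m.loci):
        return False
    for s in truth_m.sample_ids:
        for l in truth_m.loci:
            a, b = truth_m.get(s, l), called_m.get(s, l)
            if (a is None) != (b is None):
                return False
            if a is not None and key(a) != key(b):
                return False
    return True


# ---------------------------------------------------------------------------
# donor/target genome pairs
# ---------------------------------------------------------------------------


@dataclass
class GenomeTruth:
    qualifying_genes: list[str]  # genes expected from EPIC mining
    gene_structures: dict[str, dict]  # exon/intron lengths, strand
    planted_ssrs: list[dict]  # contig, start, unit, repeats


def simulate_genome_pair(
    cfg: SimConfig,
) -> tuple[
    dict[str, SequenceRecord],
    list,
    dict[str, SequenceRecord],
    GenomeTruth,
]:
    """A donor genome with annotated two-exon genes, a diverged target genome,
    and planted SSR motifs in intergenic spacers.

    The first ``n_qualifying`` genes satisfy the EPIC criteria (both exons
    > 20 bp, intron < 400 bp, feasible 425-470 bp product); the rest violate
    one criterion each. Exons diverge at ``exon_divergence``, introns at
    ``intron_divergence``, spacers at ``spacer_divergence``.
    """
    from .io import GeneModel  # local import to avoid cycle in type checking

    rng = np.random.default_rng(cfg.seed + 2)
    donor_parts: list[str] = []
    target_parts: list[str] = []
    genes: list[GeneModel] = []
    truth = GenomeTruth([], {}, [])
    pos = 0

    def add_spacer(length: int, plant_ssr: bool = False) -> None:
        nonlocal pos
        spacer = _random_seq(rng, length)
        if plant_ssr:
            unit = _aperiodic_unit(rng, cfg.ssr_unit)
            motif = unit * cfg.planted_ssr_repeats
            at = cfg.planted_ssr_flank
            if len(spacer) >= at + len(motif) + cfg.planted_ssr_flank:
                # break periodicity at both boundaries so the run starts and
                # ends exactly where planted
                before = [b for b in BASES if b != unit[-1]][int(rng.integers(3))]
                after = [b for b in BASES if b != unit[0]][int(rng.integers(3))]
                spacer = (
                    spacer[: at - 1] + before + motif + after + spacer[at + len(motif) + 1 :]
                )
                truth.planted_ssrs.append(
                    {
                        "contig": "chr1",
                        "start": pos + at,
                        "unit": unit,
                        "repeats": cfg.planted_ssr_repeats,
                    }
                )
        donor_parts.append(spacer)
        target_parts.append(_mutate(rng, spacer, cfg.spacer_divergence))
        pos += len(spacer)

    n_ssr_left = cfg.n_planted_ssr
    for g in range(cfg.n_genes):
        add_spacer(cfg.spacer_len, plant_ssr=n_ssr_left > 0)
        n_ssr_left -= 1
        qualifying = g < cfg.n_qualifying
        if qualifying:
            while True:
                e5 = int(rng.integers(120, 251))
                e3 = int(rng.integers(120, 251))
                intron = int(rng.integers(150, 380))
                if e5 + intron + e3 >= 440:
                    break
        else:
            # violate exactly one criterion, alternating
            if g % 2 == 0:
                e5, e3 = int(rng.integers(120, 251)), int(rng.integers(120, 251))
                intron = int(rng.integers(400, 600))  # intron too long
            else:
                e5, e3 = int(rng.integers(8, 20)), int(rng.integers(120, 251))
                intron = int(rng.integers(150, 380))  # 5' exon too short
        strand = "+" if g % 3 != 2 else "-"
        exon5_seq = _random_seq(rng, e5)
        intron_seq = _random_seq(rng, intron)
        exon3_seq = _random_seq(rng, e3)
        gene_tx = exon5_seq + intron_seq + exon3_seq
        target_tx = (
            _mutate(rng, exon5_seq, cfg.exon_divergence)
            + _mutate(rng, intron_seq, cfg.intron_divergence)
            + _mutate(rng, exon3_seq, cfg.exon_divergence)
        )
        genomic = gene_tx if strand == "+" else revcomp(gene_tx)
        target_genomic = target_tx if strand == "+" else revcomp(target_tx)
        gene_id = f"gene{g + 1}"
        if strand == "+":
            ex = [(pos, pos + e5), (pos + e5 + intron, pos + e5 + intron + e3)]
        else:
            # transcription order on minus strand: 5' exon is genomically last
            ex = [
                (pos + intron + e3, pos + e3 + intron + e5),
                (pos, pos + e3),
            ]
        genes.append(GeneModel(gene_id, "chr1", strand, ex))
        truth.gene_structures[gene_id] = {
            "exon5": e5,
            "exon3": e3,
            "intron": intron,
            "strand": strand,
            "qualifying": qualifying,
        }
        if qualifying:
            truth.qualifying_genes.append(gene_id)
        donor_parts.append(genomic)
        target_parts.append(target_genomic)
        pos += len(genomic)
    add_spacer(cfg.spacer_len)

    donor = {"chr1": SequenceRecord("chr1", "".join(donor_parts))}
    target = {"chr1": SequenceRecord("chr1", "".join(target_parts))}
    return donor, genes, target, truth
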