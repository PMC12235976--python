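"""Readers, writers and the shared data model.

All genomic coordinates are 0-based half-open internally; the GFF3 reader
converts from the standard's 1-based inclusive convention at the boundary.
Genotype matrices use the GenAlEx co-dominant CSV layout with allele tokens
``<length>`` or ``<length>.<variant_id>`` and ``0`` for missing.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger("gbas")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_BASES = frozenset("ACGTN")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named DNA sequence with optional Phred qualities."""

    id: str
    seq: str
    qual: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError(f"empty sequence for record {self.id!r}")
        self.seq = self.seq.upper()
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise ValueError(f"record {self.id!r}: invalid bases {sorted(bad)}")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: qual length {len(self.qual)} != seq length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """A protein-coding gene as an ordered exon chain.

    ``exons`` are genomic (contig-coordinate) 0-based half-open intervals in
    transcription order: ascending for ``+`` genes, descending for ``-`` genes.
    """

    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: no exons")
        for s, e in self.exons:
            if e - s < 1:
                raise ValueError(f"gene {self.gene_id}: exon shorter than 1 bp")
        starts = [s for s, _ in self.exons]
        expected = sorted(starts, reverse=self.strand == "-")
        if starts != expected:
            raise ValueError(f"gene {self.gene_id}: exons not in transcription order")
        genomic = sorted(self.exons)
        for (_, e1), (s2, _) in zip(genomic, genomic[1:]):
            if s2 < e1:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def intron_lengths(self) -> list[int]:
        """Intron lengths between consecutive transcription-order exons."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            gap = s2 - e1 if self.strand == "+" else s1 - e2
            out.append(gap)
        return out

    def exon_seqs(self, genome: Mapping[str, SequenceRecord]) -> list[str]:
        """Exon sequences in transcription orientation (minus strand revcomp'd)."""
        contig = genome[self.contig].seq
        seqs = [contig[s:e] for s, e in self.exons]
        if self.strand == "-":
            seqs = [revcomp(s) for s in seqs]
        return seqs

    def intron_seqs(self, genome: Mapping[str, SequenceRecord]) -> list[str]:
        contig = genome[self.contig].seq
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if self.strand == "+":
                out.append(contig[e1:s2])
            else:
                out.append(revcomp(contig[e2:s1]))
        return out


@dataclass(frozen=True, order=True)
class AlleleLabel:
    """An allele identity: amplicon length plus a sequence-variant id.

    ``variant_id`` 0 means the only variant observed at that length; lengths
    carrying several sequence variants use ids 1..n. ``canonical_seq`` does not
    participate in identity.
    """

    length: int
    variant_id: int = 0
    canonical_seq: str | None = field(default=None, compare=False, hash=False)

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("allele length must be positive")

    def token(self) -> str:
        return str(self.length) if self.variant_id == 0 else f"{self.length}.{self.variant_id}"

    @staticmethod
    def from_token(tok: str) -> "AlleleLabel | None":
        tok = tok.strip()
        if tok in ("", "0"):
            return None
        if "." in tok:
            length, variant = tok.split(".", 1)
            return AlleleLabel(int(length), int(variant))
        return AlleleLabel(int(tok))


Call = tuple[AlleleLabel, AlleleLabel]


def _sort_pair(pair: Iterable[AlleleLabel]) -> Call:
    a, b = sorted(pair)
    return (a, b)


@dataclass
class GenotypeMatrix:
    """Individuals x loci co-dominant diploid genotype matrix.

    ``calls`` maps (sample_id, locus_id) to an ordered pair of AlleleLabels;
    missing cells are simply absent. Homozygotes repeat the label.
    """

    individuals: list[tuple[str, str]]  # (sample_id, population_id)
    loci: list[str]
    calls: dict[tuple[str, str], Call]

    def __post_init__(self) -> None:
        if len(set(self.loci)) != len(self.loci):
            raise ValueError("locus ids not unique")
        sample_ids = [s for s, _ in self.individuals]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("sample ids not unique")
        known = set(sample_ids)
        known_loci = set(self.loci)
        for (s, l), pair in self.calls.items():
            if s not in known:
                raise ValueError(f"call references unknown sample {s!r}")
            if l not in known_loci:
                raise ValueError(f"call references unknown locus {l!r}")
            if len(pair) != 2:
                raise ValueError("each call must carry exactly two allele labels")
            self.calls[(s, l)] = _sort_pair(pair)

    # -- basic accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return [s for s, _ in self.individuals]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for _, p in self.individuals:
            seen.setdefault(p)
        return list(seen)

    def population_of(self, sample_id: str) -> str:
        for s, p in self.individuals:
            if s == sample_id:
                return p
        raise KeyError(sample_id)

    def samples_in(self, population: str) -> list[str]:
        return [s for s, p in self.individuals if p == population]

    def get(self, sample_id: str, locus_id: str) -> Call | None:
        return self.calls.get((sample_id, locus_id))

    # -- missingness -----------------------------------------------------

    def missing_fraction_sample(self, sample_id: str) -> float:
        if not self.loci:
            return 0.0
        n = sum(1 for l in self.loci if (sample_id, l) not in self.calls)
        return n / len(self.loci)

    def missing_fraction_locus(self, locus_id: str) -> float:
        if not self.individuals:
            return 0.0
        n = sum(1 for s, _ in self.individuals if (s, locus_id) not in self.calls)
        return n / len(self.individuals)

    # -- subsetting ------------------------------------------------------

    def subset(
        self,
        samples: Sequence[str] | None = None,
        loci: Sequence[str] | None = None,
    ) -> "GenotypeMatrix":
        keep_s = set(samples) if samples is not None else set(self.sample_ids)
        keep_l = set(loci) if loci is not None else set(self.loci)
        inds = [(s, p) for s, p in self.individuals if s in keep_s]
        locs = [l for l in self.loci if l in keep_l]
        calls = {
            (s, l): pair
            for (s, l), pair in self.calls.items()
            if s in keep_s and l in keep_l
        }
        return GenotypeMatrix(inds, locs, calls)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.individuals == other.individuals
            and self.loci == other.loci
            and self.calls == other.calls
        )


# ---------------------------------------------------------------------------
# FASTA / FASTQ
# ---------------------------------------------------------------------------


def read_fastx(path: str | Path, fmt: str | None = None) -> Iterator[SequenceRecord]:
    """Stream SequenceRecords from a FASTA or FASTQ file (format by extension
    unless given). FASTQ qualities are decoded as Phred+33."""
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    fmt = fmt.lower()
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {fmt!r}")
    try:
        for rec in SeqIO.parse(str(path), fmt):
            qual = None
            if fmt == "fastq":
                qual = list(rec.letter_annotations["phred_quality"])
            yield SequenceRecord(rec.id, str(rec.seq), qual)
    except ValueError as exc:  # Biopython signals malformed records this way
        raise ValueError(f"parse error in {path}: {exc}") from exc


def write_fastx(records: Iterable[SequenceRecord], path: str | Path, fmt: str | None = None) -> None:
    path = Path(path)
    if fmt is None:
        fmt = "fastq" if path.suffix.lower() in (".fastq", ".fq") else "fasta"
    fmt = fmt.lower()
    with open(path, "w") as fh:
        for rec in records:
            if fmt == "fasta":
                fh.write(f">{rec.id}\n{rec.seq}\n")
            else:
                qual = rec.qual if rec.qual is not None else [40] * len(rec.seq)
                qstr = "".join(chr(q + 33) for q in qual)
                fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qstr}\n")


def read_fasta_dict(path: str | Path) -> dict[str, SequenceRecord]:
    return {rec.id: rec for rec in read_fastx(path, "fasta")}


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3_genes(
    path: str | Path,
    genome: Mapping[str, SequenceRecord],
) -> list[GeneModel]:
    """Load protein-coding gene models from GFF3.

    Only protein-coding genes are kept (``biotype``/``gene_biotype`` equal to
    ``protein_coding``, or — when no biotype is annotated — genes carrying an
    mRNA or CDS child). The first annotated transcript per gene is used. GFF3's
    1-based inclusive exon coordinates are converted to 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        biotype = (
            gene.attributes.get("biotype", gene.attributes.get("gene_biotype", [None]))
        )[0]
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if biotype is not None:
            if biotype != "protein_coding":
                continue
        else:
            has_cds = any(True for _ in db.children(gene, featuretype="CDS"))
            if not mrnas and not has_cds:
                continue
        parent = mrnas[0] if mrnas else gene
        exons = [
            (f.start - 1, f.end)  # 1-based inclusive -> 0-based half-open
            for f in db.children(parent, featuretype="exon", order_by="start")
        ]
        if not exons:
            logger.warning("gene %s has no exons; skipped", gene.id)
            continue
        contig = gene.seqid
        if contig not in genome:
            raise ValueError(f"gene {gene.id}: contig {contig!r} not in genome")
        clen = len(genome[contig].seq)
        for s, e in exons:
            if s < 0 or e > clen:
                raise ValueError(
                    f"gene {gene.id}: exon ({s},{e}) outside contig {contig} (len {clen})"
                )
        if gene.strand == "-":
            exons = exons[::-1]
        genes.append(GeneModel(gene.id, contig, gene.strand, exons))
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as minimal gene/mRNA/exon GFF3 (for simulators)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            genomic = sorted(g.exons)
            gs, ge = genomic[0][0] + 1, genomic[-1][1]
            fh.write(
                f"{g.contig}\tgbas\tgene\t{gs}\t{ge}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id};biotype=protein_coding\n"
            )
            fh.write(
                f"{g.contig}\tgbas\tmRNA\t{gs}\t{ge}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(genomic, 1):
                fh.write(
                    f"{g.contig}\tgbas\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.e{i};Parent={g.gene_id}.t1\n"
                )


# ---------------------------------------------------------------------------
# GenAlEx-style co-dominant genotype CSV
# ---------------------------------------------------------------------------


def write_genotype_matrix(m: GenotypeMatrix, path: str | Path, title: str = "gbas") -> None:
    pops = m.populations
    sizes = [len(m.samples_in(p)) for p in pops]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([len(m.loci), len(m.individuals), len(pops), *sizes])
        w.writerow([title, "", "", *pops])
        header = ["Sample", "Pop"]
        for locus in m.loci:
            header.extend([locus, ""])
        w.writerow(header)
        for sample, pop in m.individuals:
            row: list[str] = [sample, pop]
            for locus in m.loci:
                pair = m.calls.get((sample, locus))
                if pair is None:
                    row.extend(["0", "0"])
                else:
                    row.extend([pair[0].token(), pair[1].token()])
            w.writerow(row)


def _is_counts_row(cells: list[str]) -> bool:
    if len(cells) < 3:
        return False
    try:
        return all(int(c) >= 0 for c in cells[:3])
    except ValueError:
        return False


def read_genotype_matrix(
    path: str | Path,
    pop_map: Mapping[str, str] | None = None,
    skip_rows: int = 0,
) -> GenotypeMatrix:
    """Read a GenAlEx-style co-dominant CSV.

    Leading metadata rows are tolerated: the reader scans for the counts row
    (three leading integers). ``pop_map`` (sample_id -> population) overrides
    in-file population assignments when given.
    """
    with open(path, newline="") as fh:
        rows = [row for row in csv.reader(fh)]
    rows = rows[skip_rows:]
    start = next((i for i, r in enumerate(rows) if _is_counts_row(r)), None)
    if start is None:
        raise ValueError(f"{path}: no GenAlEx counts row found")
    counts = rows[start]
    n_loci, n_samples, n_pops = (int(c) for c in counts[:3])
    declared_pops = [c for c in rows[start + 1][3 : 3 + n_pops] if c] if len(rows) > start + 1 else []
    header = rows[start + 2]
    loci = [header[2 + 2 * i] for i in range(n_loci)]
    if any(not l for l in loci):
        raise ValueError(f"{path}: locus header incomplete (odd column layout?)")
    individuals: list[tuple[str, str]] = []
    calls: dict[tuple[str, str], Call] = {}
    for row in rows[start + 3 :]:
        if not row or not row[0].strip():
            continue
        if len(row) < 2 + 2 * n_loci:
            raise ValueError(
                f"{path}: row for {row[0]!r} has {len(row)} columns, "
                f"expected {2 + 2 * n_loci} (two per locus)"
            )
        sample, pop = row[0].strip(), row[1].strip()
        if pop_map is not None:
            pop = pop_map.get(sample, pop)
        elif declared_pops and pop not in declared_pops:
            raise ValueError(f"{path}: sample {sample!r} has unknown population {pop!r}")
        individuals.append((sample, pop))
        for i, locus in enumerate(loci):
            a = AlleleLabel.from_token(row[2 + 2 * i])
            b = AlleleLabel.from_token(row[3 + 2 * i])
            if (a is None) != (b is None):
                raise ValueError(
                    f"{path}: half-missing call at sample {sample!r}, locus {locus!r}"
                )
            if a is not None and b is not None:
                calls[(sample, locus)] = _sort_pair((a, b))
    if len(individuals) != n_samples:
        logger.warning(
            "%s: header declares %d samples, found %d", path, n_samples, len(individuals)
        )
    return GenotypeMatrix(individuals, loci, calls)


def read_pop_map(path: str | Path) -> dict[str, str]:
    """Two-column sample -> population TSV."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            sample, pop = line.split("\t")[:2]
            out[sample] = pop
    return out
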