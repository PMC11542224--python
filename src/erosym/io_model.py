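"""Domain types and readers/writers for the formats the pipeline touches.

Coordinates follow the GFF3 convention throughout: 1-based, inclusive on
both ends. Strand-aware sequence extraction reverse-complements features on
the minus strand. BED-like interval files (0-based, half-open) are converted
to this convention on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_VALID_BASES = set("ACGTN")

HIT_TABLE_COLUMNS = ["gene_id", "subject_title", "pident", "qlen", "slen"]


class GenomeFormatError(ValueError):
    """Raised when an input file violates the genome/annotation contracts."""


@dataclass(frozen=True)
class Replicon:
    """One chromosome or plasmid: an id, a DNA sequence over {A,C,G,T,N}."""

    id: str
    sequence: str
    topology: str = "linear"  # "circular" or "linear"

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise GenomeFormatError(f"replicon {self.id!r}: empty sequence")
        if self.topology not in ("circular", "linear"):
            raise GenomeFormatError(f"replicon {self.id!r}: bad topology {self.topology!r}")
        bad = set(self.sequence.upper()) - _VALID_BASES
        if bad:
            raise GenomeFormatError(
                f"replicon {self.id!r}: ambiguity codes other than N rejected: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GeneRecord:
    """A gene call: 1-based inclusive coordinates on a named replicon."""

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str = "+"
    is_pseudogene: bool = False
    cog_category: Optional[str] = None
    product_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise GenomeFormatError(
                f"gene {self.gene_id!r}: malformed coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise GenomeFormatError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class Genome:
    """A named set of replicons plus the gene records annotated on them."""

    genome_id: str
    replicons: list[Replicon]
    genes: list[GeneRecord] = field(default_factory=list)
    lifestyle_label: Optional[str] = None  # "symbiotic" | "free_living" | None

    def __post_init__(self) -> None:
        ids = [r.id for r in self.replicons]
        if len(set(ids)) != len(ids):
            raise GenomeFormatError(f"genome {self.genome_id!r}: duplicate replicon ids")
        by_id = {r.id: r for r in self.replicons}
        seen_genes: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen_genes:
                raise GenomeFormatError(f"genome {self.genome_id!r}: duplicate gene id {g.gene_id!r}")
            seen_genes.add(g.gene_id)
            rep = by_id.get(g.replicon_id)
            if rep is None:
                raise GenomeFormatError(
                    f"genome {self.genome_id!r}: gene {g.gene_id!r} on unknown replicon "
                    f"{g.replicon_id!r}"
                )
            if g.end > len(rep):
                raise GenomeFormatError(
                    f"genome {self.genome_id!r}: gene {g.gene_id!r} end {g.end} exceeds "
                    f"replicon {rep.id!r} length {len(rep)}"
                )

    @property
    def size(self) -> int:
        """Genome size in bp: the sum of replicon lengths."""
        return sum(len(r) for r in self.replicons)

    def replicon(self, replicon_id: str) -> Replicon:
        for r in self.replicons:
            if r.id == replicon_id:
                return r
        raise KeyError(replicon_id)

    def gene_sequence(self, gene: GeneRecord) -> str:
        """Extract a gene's DNA, reverse-complemented on the minus strand."""
        seq = self.replicon(gene.replicon_id).sequence[gene.start - 1 : gene.end]
        if gene.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


@dataclass(frozen=True)
class HitRecord:
    """A gene's best protein hit (diamond/BLASTP-style tabular fields)."""

    gene_id: str
    subject_title: str
    percent_identity: float
    query_len_aa: int
    subject_len_aa: int

    def __post_init__(self) -> None:
        if self.query_len_aa <= 0 or self.subject_len_aa <= 0:
            raise ValueError(f"hit for {self.gene_id!r}: nonpositive length")
        if not (0.0 <= self.percent_identity <= 100.0):
            raise ValueError(f"hit for {self.gene_id!r}: pident outside [0,100]")


@dataclass
class IntervalSet:
    """1-based inclusive intervals on named replicons (e.g. a BGC span)."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def validate_against(self, genome: Genome) -> None:
        for rep_id, start, end in self.intervals:
            rep = genome.replicon(rep_id)
            if not (1 <= start <= end <= len(rep)):
                raise GenomeFormatError(
                    f"interval {rep_id}:{start}-{end} outside replicon bounds (len {len(rep)})"
                )

    def covers(self, rep_id: str, pos: int) -> bool:
        return any(r == rep_id and s <= pos <= e for r, s, e in self.intervals)


# ---------------------------------------------------------------------------
# Genome I/O: FASTA + GFF3


def read_genome(fasta_path, gff3_path, genome_id: Optional[str] = None) -> Genome:
    """Load a genome from a FASTA file and its GFF3 annotation.

    The pseudogene flag is taken from a ``pseudo=true`` attribute or a
    ``pseudogene`` feature type; COG category from a ``cog_category``
    attribute; product label from ``product``. Coordinate violations are
    hard errors, never clamped.
    """
    fasta_path = Path(fasta_path)
    replicons = [
        Replicon(rec.id, str(rec.seq).upper(), topology="linear")
        for rec in SeqIO.parse(str(fasta_path), "fasta")
    ]
    if not replicons:
        raise GenomeFormatError(f"{fasta_path}: no FASTA records")
    rep_len = {r.id: len(r) for r in replicons}

    genes: list[GeneRecord] = []
    with open(gff3_path) as fh:
        first = fh.readline()
        if not first.startswith("##gff-version 3"):
            raise GenomeFormatError(f"{gff3_path}: missing '##gff-version 3' header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise GenomeFormatError(f"{gff3_path}:{lineno}: expected 9 columns")
            seqid, _src, ftype, start_s, end_s, _score, strand, _phase, attrs_s = parts
            if ftype not in ("gene", "pseudogene", "CDS"):
                continue
            if ftype == "CDS":
                # gene/pseudogene features carry the records; CDS lines are redundant here
                continue
            if seqid not in rep_len:
                raise GenomeFormatError(
                    f"{gff3_path}:{lineno}: unknown replicon id {seqid!r}"
                )
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise GenomeFormatError(f"{gff3_path}:{lineno}: malformed coordinates") from exc
            if not (1 <= start <= end <= rep_len[seqid]):
                raise GenomeFormatError(
                    f"{gff3_path}:{lineno}: coordinates {start}..{end} outside "
                    f"replicon {seqid!r} (length {rep_len[seqid]})"
                )
            attrs = _parse_gff3_attributes(attrs_s)
            gene_id = attrs.get("ID")
            if not gene_id:
                raise GenomeFormatError(f"{gff3_path}:{lineno}: feature without ID attribute")
            pseudo = ftype == "pseudogene" or attrs.get("pseudo", "").lower() == "true"
            genes.append(
                GeneRecord(
                    gene_id=gene_id,
                    replicon_id=seqid,
                    start=start,
                    end=end,
                    strand=strand if strand in ("+", "-") else "+",
                    is_pseudogene=pseudo,
                    cog_category=attrs.get("cog_category") or None,
                    product_label=attrs.get("product") or None,
                )
            )
    return Genome(genome_id or fasta_path.stem, replicons, genes)


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in text.split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" not in chunk:
            raise GenomeFormatError(f"malformed GFF3 attribute {chunk!r}")
        k, v = chunk.split("=", 1)
        out[k] = v
    return out


def write_genome(genome: Genome, fasta_path, gff3_path) -> None:
    """Write FASTA (80-column wrapped) and GFF3 for a genome."""
    records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in genome.replicons
    ]
    with open(fasta_path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in genome.replicons:
            fh.write(f"##sequence-region {r.id} 1 {len(r)}\n")
        for g in genome.genes:
            ftype = "pseudogene" if g.is_pseudogene else "gene"
            attrs = [f"ID={g.gene_id}"]
            if g.is_pseudogene:
                attrs.append("pseudo=true")
            if g.cog_category:
                attrs.append(f"cog_category={g.cog_category}")
            if g.product_label:
                attrs.append(f"product={g.product_label}")
            fh.write(
                "\t".join(
                    [
                        g.replicon_id,
                        "erosym",
                        ftype,
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Elementary statistics


def gc_percent(genome: Genome | str) -> float:
    """GC content in percent: 100·(G+C)/(A+C+G+T). N is excluded entirely."""
    if isinstance(genome, Genome):
        seq = "".join(r.sequence for r in genome.replicons)
    else:
        seq = genome
    seq = seq.upper()
    gc = seq.count("G") + seq.count("C")
    denom = gc + seq.count("A") + seq.count("T")
    if denom == 0:
        raise ValueError("no unambiguous bases")
    return 100.0 * gc / denom


# ---------------------------------------------------------------------------
# Trees


def read_tree(path_or_string) -> dendropy.Tree:
    """Read a Newick tree. Duplicate tip labels are rejected."""
    text = str(path_or_string)
    try:
        p = Path(text)
        if p.exists():
            text = p.read_text()
    except OSError:  # e.g. a Newick string too long to be a path
        pass
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"Newick parse error: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise ValueError(f"duplicate tip labels: {sorted(dupes)}")
    return tree


def write_tree(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(
        tree.as_string(schema="newick", unquoted_underscores=True, suppress_rooting=True)
    )


# ---------------------------------------------------------------------------
# Tabular formats


def read_hit_table(path) -> list[HitRecord]:
    """Read a tab-separated best-hit table with header gene_id/subject_title/pident/qlen/slen."""
    df = pd.read_csv(path, sep="\t")
    missing = set(HIT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: hit table missing columns {sorted(missing)}")
    return [
        HitRecord(
            gene_id=str(row.gene_id),
            subject_title=str(row.subject_title),
            percent_identity=float(row.pident),
            query_len_aa=int(row.qlen),
            subject_len_aa=int(row.slen),
        )
        for row in df.itertuples()
    ]


def write_hit_table(hits: Iterable[HitRecord], path) -> None:
    df = pd.DataFrame(
        [
            (h.gene_id, h.subject_title, h.percent_identity, h.query_len_aa, h.subject_len_aa)
            for h in hits
        ],
        columns=HIT_TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_intervals_bed(path) -> IntervalSet:
    """Read a BED-like file (0-based half-open) into 1-based inclusive intervals."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line needs >=3 columns")
            rep, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            if end0 <= start0:
                raise ValueError(f"{path}:{lineno}: empty interval")
            out.append((rep, start0 + 1, end0))
    return IntervalSet(out)


def write_intervals_bed(intervals: IntervalSet, path) -> None:
    with open(path, "w") as fh:
        for rep, start, end in intervals:
            fh.write(f"{rep}\t{start - 1}\t{end}\n")
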