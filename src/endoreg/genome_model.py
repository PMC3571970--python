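"""Data model and I/O for circular annotated bacterial genomes.

Coordinates are 0-based, half-open internally.  GFF3 input (1-based,
closed) is converted on read and written back in GFF3 convention.
Genomes default to circular, the normal case for a bacterial
chromosome; all position arithmetic then wraps modulo the sequence
length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeValidationError",
    "GeneRecord",
    "TURecord",
    "OrthologyMap",
    "AnnotatedGenome",
    "AnchoredWindow",
    "read_genome",
    "read_gene_table",
    "read_tu_table",
    "read_orthology",
    "write_genome_fasta",
    "write_gene_table",
    "write_tu_table",
    "write_orthology",
    "upstream_region",
    "anchored_windows",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGT")


class GenomeValidationError(ValueError):
    """Raised when a genome, annotation or TU table violates an invariant."""


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneRecord:
    """A gene interval: 0-based half-open [start, end) on strand '+' or '-'."""

    id: str
    start: int
    end: int
    strand: str
    kind: str = "coding"  # {"coding", "non-coding"}

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise GenomeValidationError(
                f"gene {self.id!r}: unknown strand symbol {self.strand!r}"
            )
        if self.start >= self.end:
            raise GenomeValidationError(
                f"gene {self.id!r}: start {self.start} >= end {self.end}"
            )
        if self.kind not in ("coding", "non-coding"):
            raise GenomeValidationError(
                f"gene {self.id!r}: unknown kind {self.kind!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TURecord:
    """A transcription unit: ordered, consecutive, same-strand genes."""

    id: str
    gene_ids: tuple
    strand: str

    def __post_init__(self):
        if len(self.gene_ids) < 1:
            raise GenomeValidationError(f"TU {self.id!r} has no members")
        if self.strand not in ("+", "-"):
            raise GenomeValidationError(
                f"TU {self.id!r}: unknown strand symbol {self.strand!r}"
            )


@dataclass(frozen=True)
class OrthologyMap:
    """One-to-one gene correspondence between an ancestor and a descendant."""

    pairs: frozenset

    def __post_init__(self):
        anc = [a for a, _ in self.pairs]
        dsc = [d for _, d in self.pairs]
        if len(set(anc)) != len(anc) or len(set(dsc)) != len(dsc):
            raise GenomeValidationError("orthology map is not one-to-one")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple]) -> "OrthologyMap":
        return cls(frozenset((str(a), str(d)) for a, d in pairs))

    def to_descendant(self) -> dict:
        """Mapping ancestor gene id -> descendant gene id."""
        return {a: d for a, d in self.pairs}

    def to_ancestor(self) -> dict:
        return {d: a for a, d in self.pairs}

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class AnnotatedGenome:
    """A single circular (or linear) replicon with genes, TUs and categories.

    Parameters
    ----------
    sequence
        Uppercase DNA over {A,C,G,T}.  Ambiguity codes are rejected;
        ``N`` is accepted only with ``allow_n=True`` and downstream
        profile calculators mask windows that touch it.
    genes
        Gene records; stored sorted by start coordinate.
    tus
        Transcription units; every member must exist, and members must
        be consecutive genes on a single strand.
    categories
        Free-string functional labels per gene id (pre-flattened; no
        ontology hierarchy is modelled).
    """

    sequence: str
    genes: list = field(default_factory=list)
    tus: list = field(default_factory=list)
    categories: dict = field(default_factory=dict)
    circular: bool = True
    id: str = "genome"
    allow_n: bool = False

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if len(self.sequence) == 0:
            raise GenomeValidationError("empty genome sequence")
        allowed = VALID_BASES | ({"N"} if self.allow_n else set())
        bad = set(self.sequence) - allowed
        if bad:
            raise GenomeValidationError(
                f"sequence contains disallowed symbols: {sorted(bad)}"
            )
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        ids = [g.id for g in self.genes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise GenomeValidationError(f"duplicate gene id(s): {dup}")
        n = len(self.sequence)
        for g in self.genes:
            if g.start < 0 or g.end > n:
                raise GenomeValidationError(
                    f"gene {g.id!r} [{g.start},{g.end}) outside sequence of length {n}"
                )
        self._index = {g.id: g for g in self.genes}
        self._validate_tus()

    def _validate_tus(self):
        order = {g.id: i for i, g in enumerate(self.genes)}
        for tu in self.tus:
            ranks = []
            for gid in tu.gene_ids:
                if gid not in self._index:
                    raise GenomeValidationError(
                        f"TU {tu.id!r} references unknown gene {gid!r}"
                    )
                g = self._index[gid]
                if g.strand != tu.strand:
                    raise GenomeValidationError(
                        f"TU {tu.id!r}: gene {gid!r} strand {g.strand} != TU strand {tu.strand}"
                    )
                ranks.append(order[gid])
            ranks = sorted(ranks)
            n = len(self.genes)
            gaps = [b - a for a, b in zip(ranks, ranks[1:])]
            consecutive = all(g == 1 for g in gaps)
            if not consecutive and self.circular and len(ranks) > 1:
                # allow wrap across the origin
                wrapped = gaps.count(1) == len(gaps) - 1 and (
                    ranks[0] + n - ranks[-1] == 1
                )
                consecutive = wrapped
            if not consecutive:
                raise GenomeValidationError(
                    f"TU {tu.id!r}: member genes are not consecutive on the genome"
                )

    # -- basic accessors -------------------------------------------------

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def gene(self, gene_id: str) -> GeneRecord:
        try:
            return self._index[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene id {gene_id!r}") from None

    def gene_ids(self) -> list:
        return [g.id for g in self.genes]

    def coding_genes(self) -> list:
        return [g for g in self.genes if g.kind == "coding"]

    @property
    def gc_content(self) -> float:
        s = self.sequence
        acgt = sum(s.count(b) for b in "ACGT")
        return (s.count("G") + s.count("C")) / acgt if acgt else 0.0

    def tu_of(self) -> dict:
        """Mapping gene id -> TU id (genes outside any TU are absent)."""
        out = {}
        for tu in self.tus:
            for gid in tu.gene_ids:
                out[gid] = tu.id
        return out

    # -- sequence extraction --------------------------------------------

    def fetch(self, start: int, end: int) -> str:
        """Sequence of [start, end); wraps modulo length when circular.

        ``start`` may be negative and ``end`` may exceed the length on a
        circular genome.  On a linear genome the interval is clipped.
        """
        n = len(self.sequence)
        if self.circular:
            if end - start > n:
                raise GenomeValidationError(
                    f"interval [{start},{end}) longer than circular genome ({n} bp)"
                )
            s = start % n
            e = s + (end - start)
            if e <= n:
                return self.sequence[s:e]
            return self.sequence[s:] + self.sequence[: e - n]
        return self.sequence[max(0, start): min(n, end)]


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _parse_gff3(path) -> tuple:
    genes = []
    categories = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise GenomeValidationError(
                    f"{path}:{ln}: expected 9 GFF3 columns, got {len(parts)}"
                )
            _seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            if ftype not in ("gene", "CDS", "ncRNA", "tRNA", "rRNA"):
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gid = attr.get("ID")
            if gid is None:
                raise GenomeValidationError(f"{path}:{ln}: feature without ID attribute")
            kind = "coding" if ftype in ("gene", "CDS") else "non-coding"
            # GFF3 is 1-based closed -> 0-based half-open
            genes.append(GeneRecord(gid, int(start) - 1, int(end), strand, kind))
            if "categories" in attr:
                categories[gid] = set(attr["categories"].split(","))
    return genes, categories


def _parse_gene_table(path) -> tuple:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"id", "start", "end", "strand", "kind"}
    missing = required - set(df.columns)
    if missing:
        raise GenomeValidationError(f"{path}: gene table missing columns {sorted(missing)}")
    genes, categories = [], {}
    for row in df.itertuples(index=False):
        genes.append(
            GeneRecord(str(row.id), int(row.start), int(row.end), str(row.strand), str(row.kind))
        )
        cats = getattr(row, "categories", None)
        if isinstance(cats, str) and cats:
            categories[str(row.id)] = set(cats.split(";"))
    return genes, categories


def read_gene_table(path) -> tuple:
    """Read an annotation file (GFF3 by extension, else the minimal TSV)."""
    p = Path(path)
    if p.suffix.lower() in (".gff", ".gff3"):
        return _parse_gff3(p)
    return _parse_gene_table(p)


def read_tu_table(path) -> "list[tuple]":
    """Read a TU table (tu_id, gene_id, rank) into ordered member lists."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"tu_id", "gene_id", "rank"}
    missing = required - set(df.columns)
    if missing:
        raise GenomeValidationError(f"{path}: TU table missing columns {sorted(missing)}")
    out = []
    for tu_id, grp in df.groupby("tu_id", sort=False):
        grp = grp.sort_values("rank", key=lambda s: s.astype(int))
        out.append((str(tu_id), [str(g) for g in grp["gene_id"]]))
    return out


def read_orthology(path) -> OrthologyMap:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    cols = list(df.columns)
    if len(cols) < 2:
        raise GenomeValidationError(f"{path}: orthology table needs two columns")
    return OrthologyMap.from_pairs(zip(df[cols[0]], df[cols[1]]))


def read_genome(fasta_path, annotation_path=None, tu_path=None,
                circular: bool = True, allow_n: bool = False) -> AnnotatedGenome:
    """Load a genome from FASTA plus optional annotation and TU tables.

    The FASTA must contain exactly one record (single replicon).
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise GenomeValidationError(
            f"{fasta_path}: expected exactly one FASTA record, found {len(records)}"
        )
    rec = records[0]
    genes, categories = ([], {})
    if annotation_path is not None:
        genes, categories = read_gene_table(annotation_path)
    genome = AnnotatedGenome(
        sequence=str(rec.seq),
        genes=genes,
        categories=categories,
        circular=circular,
        id=rec.id,
        allow_n=allow_n,
    )
    if tu_path is not None:
        strand_of = {g.id: g.strand for g in genome.genes}
        tus = []
        for tu_id, members in read_tu_table(tu_path):
            for m in members:
                if m not in strand_of:
                    raise GenomeValidationError(
                        f"TU {tu_id!r} references unknown gene {m!r}"
                    )
            tus.append(TURecord(tu_id, tuple(members), strand_of[members[0]]))
        genome.tus = tus
        genome._validate_tus()
    return genome


def write_genome_fasta(genome: AnnotatedGenome, path, description: str = ""):
    rec = SeqRecord(Seq(genome.sequence), id=genome.id, description=description)
    SeqIO.write([rec], str(path), "fasta")


def write_gene_table(genome: AnnotatedGenome, path):
    rows = []
    for g in genome.genes:
        cats = ";".join(sorted(genome.categories.get(g.id, ())))
        rows.append((g.id, g.start, g.end, g.strand, g.kind, cats))
    pd.DataFrame(
        rows, columns=["id", "start", "end", "strand", "kind", "categories"]
    ).to_csv(path, sep="\t", index=False)


def write_tu_table(genome: AnnotatedGenome, path):
    rows = []
    for tu in genome.tus:
        for rank, gid in enumerate(tu.gene_ids):
            rows.append((tu.id, gid, rank))
    pd.DataFrame(rows, columns=["tu_id", "gene_id", "rank"]).to_csv(
        path, sep="\t", index=False
    )


def write_orthology(orthology: OrthologyMap, path):
    rows = sorted(orthology.pairs)
    pd.DataFrame(rows, columns=["ancestor_id", "descendant_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Region extraction
# ---------------------------------------------------------------------------

def upstream_region(genome: AnnotatedGenome, gene_id: str, length_bp: int) -> str:
    """The ``length_bp`` bases 5' of a gene start, on the gene's strand.

    For a '-'-strand gene the forward-strand interval downstream of the
    gene end is taken and reverse-complemented.  Wraps through the
    origin on circular genomes; on linear genomes the window is
    truncated at the sequence edge (a warning is emitted).
    """
    if length_bp < 1:
        raise ValueError("length_bp must be >= 1")
    g = genome.gene(gene_id)
    if g.strand == "+":
        start, end = g.start - length_bp, g.start
    else:
        start, end = g.end, g.end + length_bp
    seq = genome.fetch(start, end)
    if not genome.circular and len(seq) < length_bp:
        warnings.warn(
            f"upstream window of gene {gene_id!r} truncated to {len(seq)} bp "
            "at the sequence edge",
            stacklevel=2,
        )
    return revcomp(seq) if g.strand == "-" else seq


@dataclass(frozen=True)
class AnchoredWindow:
    """A strand-oriented window around a gene anchor.

    Offset 0 is the first base of the start codon; offset ``-k`` is k bp
    upstream on the gene's strand.  ``positions(n)`` maps each offset in
    ``[-span_up, span_down)`` to a forward-strand coordinate (modulo the
    genome length when circular); truncated offsets map to -1.
    """

    gene_id: str
    strand: str
    anchor: int           # forward-strand coordinate of the start codon base
    span_up: int
    span_down: int
    truncated: bool = False

    @property
    def offsets(self):
        import numpy as np

        return np.arange(-self.span_up, self.span_down)

    def genomic_positions(self, genome_length: int, circular: bool):
        import numpy as np

        off = self.offsets
        if self.strand == "+":
            pos = self.anchor + off
        else:
            pos = self.anchor - off
        if circular:
            return pos % genome_length
        out = pos.copy()
        out[(pos < 0) | (pos >= genome_length)] = -1
        return out


def anchored_windows(genome: AnnotatedGenome, span_up: int, span_down: int,
                     gene_ids: Sequence = None) -> "list[AnchoredWindow]":
    """One oriented window per coding gene, anchored at the start codon."""
    if span_up < 0 or span_down < 0:
        raise ValueError("span_up and span_down must be >= 0")
    out = []
    genes = genome.coding_genes()
    if gene_ids is not None:
        wanted = set(gene_ids)
        genes = [g for g in genes if g.id in wanted]
    n = len(genome)
    for g in genes:
        anchor = g.start if g.strand == "+" else g.end - 1
        truncated = False
        if not genome.circular:
            if g.strand == "+":
                truncated = anchor - span_up < 0 or anchor + span_down > n
            else:
                truncated = anchor + span_up >= n or anchor - span_down < -1
        out.append(AnchoredWindow(g.id, g.strand, anchor, span_up, span_down, truncated))
    return out
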