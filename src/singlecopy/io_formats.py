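"""Readers and writers for the on-disk formats the pipeline touches.

FASTA (protein / CDS / unspliced gene), tab-separated gene-position tables,
12-column tabular similarity-hit files (the classic BLAST ``outfmt 6``
dialect), and phylogenetic supermatrix exports (relaxed PHYLIP or FASTA with
a RAxML-style partition file).

Gene identifiers are namespaced ``genomeId|geneId`` internally so that
identifiers reused between genome releases remain globally unique.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .similarity import SimilarityHit

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# standard genetic code, DNA alphabet
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


class FormatError(ValueError):
    """Malformed input file; the message names the offending line."""


def translate_cds(cds: str) -> str:
    """Translate a CDS (no terminal stop) with the standard code.

    Codons containing characters outside ACGT translate to ``X``.
    """
    prot = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        prot.append(CODON_TABLE.get(cds[i : i + 3], "X"))
    return "".join(prot)


def trim_terminal_stop(cds: str) -> str:
    cds = cds.upper()
    if len(cds) >= 3 and cds[-3:] in STOP_CODONS:
        return cds[:-3]
    return cds


@dataclass(frozen=True)
class GenePosition:
    chromosome: str
    rank: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.rank < 0:
            raise ValueError(f"negative gene rank {self.rank}")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"strand must be + or -, got {self.strand!r}")


@dataclass
class GeneRecord:
    """A gene: sequences plus its position along a chromosome.

    ``rank`` is the 0-based ordinal of the gene along its chromosome, not a
    base-pair coordinate — collinearity is computed over gene order.
    """

    gene_id: str
    genome_id: str
    protein: str = ""
    cds: str = ""
    gene_seq: str = ""  # unspliced (exons + introns); optional
    position: GenePosition | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        self.cds = trim_terminal_stop(self.cds) if self.cds else ""
        if self.cds and len(self.cds) % 3 != 0:
            raise ValueError(
                f"{self.key}: CDS length {len(self.cds)} not divisible by 3"
            )

    @property
    def key(self) -> str:
        """Globally unique ``genome|gene`` identifier."""
        return f"{self.genome_id}|{self.gene_id}"

    def validate(self) -> None:
        """Check that the CDS translates to the stored protein."""
        if self.cds and self.protein:
            tr = translate_cds(self.cds)
            if tr != self.protein:
                for i, (a, b) in enumerate(zip(tr, self.protein)):
                    if a != b:
                        raise ValueError(
                            f"{self.key}: translated CDS differs from protein "
                            f"at residue {i} ({a!r} != {b!r})"
                        )
                raise ValueError(
                    f"{self.key}: translated CDS length {len(tr)} != "
                    f"protein length {len(self.protein)}"
                )


@dataclass
class GenomeSet:
    """Ordered collection of genomes, each a list of :class:`GeneRecord`."""

    genomes: dict[str, list[GeneRecord]] = field(default_factory=dict)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.genomes)

    def add(self, record: GeneRecord) -> None:
        self.genomes.setdefault(record.genome_id, []).append(record)

    def gene(self, key: str) -> GeneRecord:
        genome_id, gene_id = key.split("|", 1)
        for rec in self.genomes[genome_id]:
            if rec.gene_id == gene_id:
                return rec
        raise KeyError(key)

    def records(self) -> Iterable[GeneRecord]:
        for recs in self.genomes.values():
            yield from recs

    def index(self) -> dict[str, GeneRecord]:
        out: dict[str, GeneRecord] = {}
        for rec in self.records():
            if rec.key in out:
                raise ValueError(f"duplicate gene key {rec.key}")
            out[rec.key] = rec
        return out


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, kind: str = "protein") -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of ``(id, sequence)``.

    ``kind`` is one of ``protein``, ``cds``, ``gene``; it is recorded for the
    caller's benefit (no per-kind validation happens here beyond
    uppercasing).  Raises :class:`FormatError` for an empty file, sequence
    before the first header, or a duplicate identifier.
    """
    if kind not in {"protein", "cds", "gene"}:
        raise ValueError(f"unknown FASTA kind {kind!r}")
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    name: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if name is not None:
                    records.append((name, "".join(chunks).upper()))
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                if name in seen:
                    raise FormatError(f"{path}:{lineno}: duplicate id {name!r}")
                seen.add(name)
                chunks = []
            else:
                if name is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence before first header"
                    )
                chunks.append(line)
    if name is not None:
        records.append((name, "".join(chunks).upper()))
    if not records:
        raise FormatError(f"{path}: empty FASTA file")
    return records


def write_fasta(records: Sequence[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, max(len(seq), 1), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene position tables


def read_positions(path: str | Path) -> dict[str, GenePosition]:
    """Read a TSV of ``gene_id genome_id chromosome rank strand``.

    Gene keys in the result are namespaced ``genome|gene``.  Within a genome
    no two genes may share a ``(chromosome, rank)`` slot.
    """
    out: dict[str, GenePosition] = {}
    used: set[tuple[str, str, int]] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(
                    f"{path}:{lineno}: expected 5 tab-separated columns, got {len(parts)}"
                )
            gene_id, genome_id, chrom, rank_s, strand = parts
            try:
                rank = int(rank_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad rank {rank_s!r}") from exc
            slot = (genome_id, chrom, rank)
            if slot in used:
                raise FormatError(
                    f"{path}:{lineno}: duplicate position {chrom}:{rank} in {genome_id}"
                )
            used.add(slot)
            out[f"{genome_id}|{gene_id}"] = GenePosition(chrom, rank, strand)
    return out


def write_positions(positions: dict[str, GenePosition], path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, pos in positions.items():
            genome_id, gene_id = key.split("|", 1)
            fh.write(
                f"{gene_id}\t{genome_id}\t{pos.chromosome}\t{pos.rank}\t{pos.strand}\n"
            )


# ---------------------------------------------------------------------------
# 12-column tabular hits (BLAST outfmt 6 dialect)

_HIT_COLUMNS = 12


def read_hit_table(path: str | Path) -> list[SimilarityHit]:
    """Read a 12-column tabular hit file.

    Columns: query, subject, %identity, alignment length, mismatches, gap
    opens, qstart, qend, sstart, send, evalue, bitscore.  Query coverage is
    derived from qstart/qend relative to the query length, which the caller
    supplies later; here it is stored as a fraction of the aligned query
    span over ``qend`` (recomputed downstream when lengths are known).
    """
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != _HIT_COLUMNS:
                raise FormatError(
                    f"{path}:{lineno}: expected {_HIT_COLUMNS} columns, got {len(parts)}"
                )
            (q, s, ident, alen, _mm, _go, qs, qe, _ss, _se, ev, bits) = parts
            try:
                hits.append(
                    SimilarityHit(
                        query=q,
                        subject=s,
                        identity=float(ident),
                        aln_length=int(alen),
                        query_coverage=(int(qe) - int(qs) + 1) / max(int(qe), 1),
                        score=float(bits),
                        bitscore=float(bits),
                        evalue=float(ev),
                    )
                )
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad numeric field") from exc
    return hits


def write_hit_table(hits: Sequence[SimilarityHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            span = max(1, round(h.query_coverage * h.aln_length)) if h.aln_length else 1
            fh.write(
                "\t".join(
                    [
                        h.query,
                        h.subject,
                        f"{h.identity:.2f}",
                        str(h.aln_length),
                        "0",
                        "0",
                        "1",
                        str(span),
                        "1",
                        str(h.aln_length),
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Supermatrix export


def sanitize_taxon(name: str) -> str:
    """Deterministic taxon-name sanitization for PHYLIP/newick output."""
    return re.sub(r"[\s,:;()\[\]']+", "_", name.strip())


def write_supermatrix(
    matrix: dict[str, str],
    path: str | Path,
    fmt: str = "relaxed-phylip",
) -> None:
    """Write aligned taxon rows as relaxed PHYLIP or FASTA.

    All rows must share one aligned length.
    """
    lengths = {len(s) for s in matrix.values()}
    if len(lengths) > 1:
        raise ValueError(f"ragged supermatrix rows: lengths {sorted(lengths)}")
    if fmt == "relaxed-phylip":
        n = len(matrix)
        length = lengths.pop() if lengths else 0
        with open(path, "w") as fh:
            fh.write(f"{n} {length}\n")
            for taxon, seq in matrix.items():
                fh.write(f"{sanitize_taxon(taxon)}  {seq}\n")
    elif fmt == "fasta":
        write_fasta([(sanitize_taxon(t), s) for t, s in matrix.items()], path)
    else:
        raise ValueError(f"unknown supermatrix format {fmt!r}")


def read_supermatrix(path: str | Path, fmt: str = "relaxed-phylip") -> dict[str, str]:
    if fmt == "fasta":
        return dict(read_fasta(path, kind="gene"))
    out: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise FormatError(f"{path}: bad PHYLIP header")
        n, length = int(header[0]), int(header[1])
        for raw in fh:
            if not raw.strip():
                continue
            taxon, seq = raw.split(None, 1)
            out[taxon] = seq.strip()
    if len(out) != n or any(len(s) != length for s in out.values()):
        raise FormatError(f"{path}: PHYLIP body disagrees with header")
    return out


def write_partitions(
    partitions: Sequence[tuple[str, int, int]], path: str | Path, datatype: str = "DNA"
) -> None:
    """Write per-gene 1-based inclusive ranges, RAxML style."""
    with open(path, "w") as fh:
        for name, start, end in partitions:
            fh.write(f"{datatype}, {name} = {start}-{end}\n")


def read_partitions(path: str | Path) -> list[tuple[str, int, int]]:
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            _dt, rest = line.split(",", 1)
            name, rng = rest.split("=")
            start, end = rng.strip().split("-")
            out.append((name.strip(), int(start), int(end)))
    return out
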