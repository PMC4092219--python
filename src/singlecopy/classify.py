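"""Copy-number classification of genes across genomes.

Three nested categories drive the whole analysis:

* **single copy** (within a genome): a gene with no non-self hit passing the
  stringent self-search filter (E ≤ 1e-10) — i.e. no detectable in-paralog;
* **singleton**: a single-copy gene with no filtered cross-genome hit at all
  (no detectable ortholog in any other analyzed genome);
* **shared single copy**: a confirmed ortholog cluster containing exactly one
  member from every analyzed genome (strict 1:1:…:1).

Family size is the connected-component size of the non-self self-hit graph,
i.e. 1 + the number of in-paralogs reachable through passing hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .io_formats import GeneRecord
from .similarity import SimilarityHit


@dataclass
class CopyStatus:
    gene: str  # namespaced genome|gene key
    genome: str
    single_copy: bool
    family_size: int
    singleton: bool = False
    shared_single_copy: bool = False

    def __post_init__(self) -> None:
        if (self.family_size == 1) != self.single_copy:
            raise ValueError(
                f"{self.gene}: family_size {self.family_size} inconsistent "
                f"with single_copy={self.single_copy}"
            )
        if self.singleton and not self.single_copy:
            raise ValueError(f"{self.gene}: singleton requires single_copy")


@dataclass
class OrthoCluster:
    cluster_id: str
    members: list[str]

    def per_genome_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for key in self.members:
            genome = key.split("|", 1)[0]
            counts[genome] = counts.get(genome, 0) + 1
        return counts


@dataclass
class GenomeSummary:
    genome_id: str
    total_genes: int
    n_single_copy: int
    n_singletons: int
    n_blocks: int

    @property
    def pct_single_copy(self) -> float:
        return 100.0 * self.n_single_copy / self.total_genes

    @property
    def singleton_ratio(self) -> float | None:
        """Singletons as a percentage of single-copy genes (None when 0/0)."""
        if self.n_single_copy == 0:
            return None
        return 100.0 * self.n_singletons / self.n_single_copy


def collapse_transcripts(genes: Sequence[GeneRecord]) -> list[GeneRecord]:
    """Keep one representative transcript per locus: the longest protein.

    Transcripts are grouped by the locus prefix before the last '.' in the
    gene id (ids without a '.' are their own locus).  Ties go to the
    lexicographically smallest transcript id.
    """
    by_locus: dict[str, GeneRecord] = {}
    for rec in genes:
        locus = rec.gene_id.rsplit(".", 1)[0]
        prev = by_locus.get(locus)
        if (
            prev is None
            or len(rec.protein) > len(prev.protein)
            or (len(rec.protein) == len(prev.protein) and rec.gene_id < prev.gene_id)
        ):
            by_locus[locus] = rec
    return list(by_locus.values())


def within_genome_single_copy(
    self_hits: Iterable[SimilarityHit], genome: Sequence[GeneRecord]
) -> dict[str, CopyStatus]:
    """Classify each gene of one genome as single- or multi-copy.

    A gene is single copy iff it has no non-self hit passing the self-search
    cutoff; its family size is the size of its connected component in the
    non-self hit graph.
    """
    known = {rec.key for rec in genome}
    g = nx.Graph()
    g.add_nodes_from(known)
    for h in self_hits:
        if h.query not in known or h.subject not in known:
            raise ValueError(f"hit references unknown gene {h.query}->{h.subject}")
        if not h.is_self:
            g.add_edge(h.query, h.subject)
    out: dict[str, CopyStatus] = {}
    for comp in nx.connected_components(g):
        size = len(comp)
        for key in comp:
            out[key] = CopyStatus(
                gene=key,
                genome=key.split("|", 1)[0],
                single_copy=size == 1,
                family_size=size,
            )
    return out


def confirm_clusters(
    clusters: Sequence[Sequence[str]],
    cross_hits: Iterable[SimilarityHit],
    rounds: int = 3,
) -> list[OrthoCluster]:
    """Reciprocal-hit confirmation of raw MCL clusters.

    Within each cluster, a member is kept only if it has a reciprocal
    (both-direction) filtered hit with at least one member from every OTHER
    genome represented in the cluster.  Removal is iterated to a fixed point
    or for at most ``rounds`` passes — the mutual-confirmation step that
    guards the clusters against inflation artifacts.
    """
    directed: set[tuple[str, str]] = {(h.query, h.subject) for h in cross_hits}
    reciprocal = {(a, b) for a, b in directed if (b, a) in directed}
    confirmed: list[OrthoCluster] = []
    for ci, members_in in enumerate(clusters):
        members = list(members_in)
        for _ in range(rounds):
            genomes = {m.split("|", 1)[0] for m in members}
            if len(genomes) <= 1:
                break
            keep = []
            for m in members:
                mine = m.split("|", 1)[0]
                others = genomes - {mine}
                ok = all(
                    any(
                        (m, n) in reciprocal
                        for n in members
                        if n.split("|", 1)[0] == g
                    )
                    for g in others
                )
                if ok:
                    keep.append(m)
            if keep == members:
                break
            members = keep
        if members:
            confirmed.append(OrthoCluster(cluster_id=f"C{ci:05d}", members=sorted(members)))
    return confirmed


def shared_single_copy(
    clusters: Sequence[OrthoCluster], genome_ids: Sequence[str]
) -> list[OrthoCluster]:
    """Clusters with exactly one member from every genome (strict 1:1:…:1)."""
    if not genome_ids:
        raise ValueError("genome list must be non-empty")
    want = set(genome_ids)
    out = []
    for c in clusters:
        counts = c.per_genome_counts()
        if set(counts) == want and all(v == 1 for v in counts.values()):
            out.append(c)
    return out


def find_singletons(
    statuses: Mapping[str, CopyStatus], cross_hits: Iterable[SimilarityHit]
) -> None:
    """Flag singletons in-place: single copy and zero filtered cross hits."""
    has_cross: set[str] = set()
    for h in cross_hits:
        has_cross.add(h.query)
        has_cross.add(h.subject)
    for key, st in statuses.items():
        st.singleton = st.single_copy and key not in has_cross


def flag_shared(
    statuses: Mapping[str, CopyStatus], shared: Sequence[OrthoCluster]
) -> None:
    members = {m for c in shared for m in c.members}
    for key, st in statuses.items():
        st.shared_single_copy = key in members


def summarize(
    genome_sizes: Mapping[str, int],
    statuses: Mapping[str, CopyStatus],
    block_counts: Mapping[str, int] | None = None,
) -> list[GenomeSummary]:
    """Per-genome summary: totals, single-copy and singleton counts, blocks."""
    block_counts = block_counts or {}
    per_genome: dict[str, list[CopyStatus]] = {g: [] for g in genome_sizes}
    for st in statuses.values():
        per_genome.setdefault(st.genome, []).append(st)
    out = []
    for genome, total in genome_sizes.items():
        sts = per_genome.get(genome, [])
        out.append(
            GenomeSummary(
                genome_id=genome,
                total_genes=total,
                n_single_copy=sum(s.single_copy for s in sts),
                n_singletons=sum(s.singleton for s in sts),
                n_blocks=block_counts.get(genome, 0),
            )
        )
    return out


def write_summary_tsv(summaries: Sequence[GenomeSummary], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "genome\ttotal_genes\tn_single_copy\tn_singletons\tn_blocks"
            "\tpct_single_copy\tsingleton_ratio\n"
        )
        for s in summaries:
            ratio = "" if s.singleton_ratio is None else f"{s.singleton_ratio:.2f}"
            fh.write(
                f"{s.genome_id}\t{s.total_genes}\t{s.n_single_copy}\t"
                f"{s.n_singletons}\t{s.n_blocks}\t{s.pct_single_copy:.2f}\t{ratio}\n"
            )
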