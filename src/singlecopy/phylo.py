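"""Supermatrix construction and distance-based phylogenetics.

Shared single-copy clusters are aligned per gene (progressive global
alignment with affine gaps, center-star merge under "once a gap, always a
gap"), concatenated into a partitioned supermatrix — from CDS only or from
unspliced gene sequences so that intron columns are included — and analyzed
with neighbor joining under p- or Jukes–Cantor distances, with nonparametric
bootstrap supports from column resampling.  Likelihood inference is export-
only: the supermatrix and partition files are written for an external ML
tool.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .similarity import SearchParams, _make_aligner

DNA = "ACGT"


# ---------------------------------------------------------------------------
# Progressive multiple alignment (desk scale)


def _pairwise_global(a: str, b: str, params: SearchParams | None = None):
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    return aligner.align(a, b)


def _merge_into_profile(profile: list[str], new_seq: str) -> list[str]:
    """Align ``new_seq`` against the profile's first (center) row and merge
    under once-a-gap-always-a-gap."""
    center = profile[0]
    degapped = center.replace("-", "")
    alignment = next(iter(_pairwise_global(degapped, new_seq)))
    ac, an = str(alignment[0]), str(alignment[1])
    # map center's degapped coordinates onto profile columns
    out_profile = [[] for _ in profile]
    out_new: list[str] = []
    pi = 0  # profile column index
    for cc, cn in zip(ac, an):
        if cc == "-":
            for row, buf in zip(profile, out_profile):
                buf.append("-")
            out_new.append(cn)
        else:
            # advance to the profile column holding this center residue
            while profile[0][pi] == "-":
                for row, buf in zip(profile, out_profile):
                    buf.append(row[pi])
                out_new.append("-")
                pi += 1
            for row, buf in zip(profile, out_profile):
                buf.append(row[pi])
            out_new.append(cn)
            pi += 1
    while pi < len(profile[0]):
        for row, buf in zip(profile, out_profile):
            buf.append(row[pi])
        out_new.append("-")
        pi += 1
    merged = ["".join(buf) for buf in out_profile]
    merged.append("".join(out_new))
    return merged


def gene_alignment(sequences: Mapping[str, str]) -> dict[str, str]:
    """Progressive multiple alignment of one gene across taxa.

    The center sequence (highest total pairwise alignment score) is chosen
    as the guide; remaining sequences join in decreasing score-to-center
    order.  Deterministic for a fixed input.
    """
    taxa = list(sequences)
    if any(not s for s in sequences.values()):
        missing = [t for t, s in sequences.items() if not s]
        raise ValueError(f"missing sequence for taxa {missing}")
    if len(taxa) == 1:
        return dict(sequences)
    scores: dict[str, float] = {t: 0.0 for t in taxa}
    pair_score: dict[tuple[str, str], float] = {}
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            s = float(_pairwise_global(sequences[a], sequences[b]).score)
            pair_score[(a, b)] = pair_score[(b, a)] = s
            scores[a] += s
            scores[b] += s
    center = max(taxa, key=lambda t: (scores[t], t))
    rest = sorted(
        (t for t in taxa if t != center),
        key=lambda t: (-pair_score[(center, t)], t),
    )
    order = [center] + rest
    profile = [sequences[center]]
    for t in rest:
        profile = _merge_into_profile(profile, sequences[t])
    return {t: row for t, row in zip(order, profile)}


def sum_of_pairs_score(alignment: Mapping[str, str], match: float = 2.0,
                       mismatch: float = -1.0, gap: float = -1.0) -> float:
    """Simple sum-of-pairs score of a multiple alignment (gap-gap = 0)."""
    rows = list(alignment.values())
    total = 0.0
    for i, a in enumerate(rows):
        for b in rows[i + 1 :]:
            for ca, cb in zip(a, b):
                if ca == "-" and cb == "-":
                    continue
                if ca == "-" or cb == "-":
                    total += gap
                elif ca == cb:
                    total += match
                else:
                    total += mismatch
    return total


# ---------------------------------------------------------------------------
# Supermatrix


@dataclass
class Supermatrix:
    taxa: list[str]
    rows: dict[str, str]
    partitions: list[tuple[str, int, int]]  # (gene, start, end) 1-based incl.

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("ragged supermatrix")
        exp = 1
        for _, start, end in self.partitions:
            if start != exp or end < start:
                raise ValueError("partitions must tile the matrix without overlap")
            exp = end + 1
        if self.rows and exp - 1 != next(iter(lengths)):
            raise ValueError("partitions do not cover the full length")

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


def concatenate(
    alignments: Mapping[str, Mapping[str, str]], taxa_order: Sequence[str]
) -> Supermatrix:
    """Concatenate per-gene alignments over a fixed taxon order."""
    rows = {t: [] for t in taxa_order}
    partitions = []
    pos = 1
    for gene in alignments:
        aln = alignments[gene]
        missing = [t for t in taxa_order if t not in aln]
        if missing:
            raise ValueError(f"gene {gene}: missing taxa {missing}")
        length = len(next(iter(aln.values())))
        partitions.append((gene, pos, pos + length - 1))
        pos += length
        for t in taxa_order:
            rows[t].append(aln[t])
    return Supermatrix(
        taxa=list(taxa_order),
        rows={t: "".join(parts) for t, parts in rows.items()},
        partitions=partitions,
    )


# ---------------------------------------------------------------------------
# Distances


def distance_matrix(
    sm: Supermatrix, model: str = "JC", complete_deletion: bool = False
) -> np.ndarray:
    """Pairwise distances between taxa rows.

    ``p``: proportion of differing sites; ``JC``: Jukes–Cantor correction
    d = −(3/4)·ln(1 − (4/3)p).  Gap or ambiguous columns are removed
    pairwise (default) or across all taxa (``complete_deletion``).
    """
    if model not in {"p", "JC"}:
        raise ValueError(f"unknown distance model {model!r}")
    taxa = sm.taxa
    if len(taxa) < 2:
        raise ValueError("need at least 2 taxa")
    seqs = [sm.rows[t] for t in taxa]
    arr = np.frombuffer("".join(seqs).encode(), dtype="S1").reshape(len(taxa), -1)
    valid = np.isin(arr, [b.encode() for b in DNA])
    if complete_deletion:
        keep = valid.all(axis=0)
        arr = arr[:, keep]
        valid = valid[:, keep]
    n = len(taxa)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            nsites = int(both.sum())
            if nsites == 0:
                raise ValueError(f"no comparable sites between {taxa[i]} and {taxa[j]}")
            p = float((arr[i, both] != arr[j, both]).sum() / nsites)
            if model == "p":
                dist = p
            else:
                if p >= 0.75:
                    raise ValueError(
                        f"JC distance undefined (saturation) for {taxa[i]},{taxa[j]}"
                    )
                dist = -0.75 * math.log(1 - 4 * p / 3)
            d[i, j] = d[j, i] = dist
    return d


# ---------------------------------------------------------------------------
# Neighbor joining


@dataclass
class TreeNode:
    name: str = ""
    children: list["TreeNode"] = field(default_factory=list)
    length: float = 0.0
    support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, with_support: bool = True) -> str:
        return self._nwk(with_support) + ";"

    def _nwk(self, ws: bool) -> str:
        if not self.children:
            return f"{self.name}:{self.length:.6f}"
        inner = ",".join(c._nwk(ws) for c in self.children)
        label = ""
        if ws and self.support is not None:
            label = f"{self.support:.0f}"
        return f"({inner}){label}:{self.length:.6f}"


def nj_tree(distances: np.ndarray, taxa: Sequence[str]) -> TreeNode:
    """Canonical neighbor joining; deterministic lexicographic tie-break.

    Returns an unrooted tree represented with a trifurcating root.
    """
    n = len(taxa)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if distances.shape != (n, n):
        raise ValueError("distance matrix shape mismatch")
    nodes: list[TreeNode] = [TreeNode(name=t) for t in taxa]
    d = distances.astype(float).copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, min(nodes[i].leaves()[0], nodes[j].leaves()[0]),
                       max(nodes[i].leaves()[0], nodes[j].leaves()[0]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        vi = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        vj = d[i, j] - vi
        parent = TreeNode()
        ni, nj_ = nodes[i], nodes[j]
        ni.length = max(vi, 0.0)
        nj_.length = max(vj, 0.0)
        parent.children = [ni, nj_]
        # distances from the new node
        knew = len(nodes)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[knew, k] = d[k, knew] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [knew]
    i, j, k = active
    root = TreeNode()
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(ln, 0.0)
        root.children.append(nodes[idx])
    return root


def root_on_outgroup(tree: TreeNode, outgroups: Sequence[str]) -> str:
    """Root the unrooted NJ tree on the outgroup set; returns rooted newick.

    The outgroups must form one side of some edge of the unrooted topology
    (monophyly); otherwise a ValueError reports the conflict rather than
    silently rerooting elsewhere.
    """
    import dendropy

    og = set(outgroups)
    leaves = set(tree.leaves())
    if not og <= leaves:
        raise ValueError(f"unknown outgroup taxa {sorted(og - leaves)}")
    if og == leaves:
        raise ValueError("outgroups cover all taxa")
    monophyletic = any(
        side == og or (set(leaves) - side) == og
        for side in (set(s) for s in _all_splits(tree))
    ) or len(og) == 1
    if not monophyletic:
        raise ValueError("outgroups are not monophyletic in the unrooted tree")
    dt = dendropy.Tree.get(data=tree.newick(), schema="newick")
    dt.is_rooted = True  # monophyly was checked above on the unrooted splits
    # reroot at the edge whose bipartition separates the outgroup set
    target = None
    for node in dt.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if below == og or (leaves - below) == og:
            target = node
            break
    if target is None:  # og split across the basal trifurcation
        target = dt.find_node_with_taxon_label(sorted(og)[0])
    dt.reroot_at_edge(target.edge, update_bipartitions=False)
    return dt.as_string(schema="newick").strip()


def _all_splits(tree: TreeNode) -> list[frozenset[str]]:
    out: list[frozenset[str]] = []

    def rec(node: TreeNode):
        for child in node.children:
            out.append(frozenset(child.leaves()))
            rec(child)

    rec(tree)
    return out


# ---------------------------------------------------------------------------
# Bootstrap


def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Non-trivial leaf bipartitions (as the smaller/canonical side)."""
    leaves = frozenset(tree.leaves())
    out: set[frozenset[str]] = set()

    def rec(node: TreeNode):
        for child in node.children:
            side = frozenset(child.leaves())
            if 1 < len(side) < len(leaves) - 1:
                other = leaves - side
                out.add(min(side, other, key=lambda s: (len(s), sorted(s))))
            rec(child)

    rec(tree)
    return out


def bootstrap(
    sm: Supermatrix,
    replicates: int = 100,
    seed: int = 0,
    model: str = "JC",
) -> TreeNode:
    """NJ tree with bootstrap supports from column resampling.

    Support of an internal edge = percentage of replicate NJ trees whose
    topology contains the same leaf bipartition.  Seeded and reproducible.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    base_d = distance_matrix(sm, model=model)
    tree = nj_tree(base_d, sm.taxa)
    counts: dict[frozenset[str], int] = {bp: 0 for bp in bipartitions(tree)}
    rng = np.random.default_rng(seed)
    length = sm.length
    seqs = np.frombuffer(
        "".join(sm.rows[t] for t in sm.taxa).encode(), dtype="S1"
    ).reshape(len(sm.taxa), -1)
    for _ in range(replicates):
        cols = rng.integers(0, length, size=length)
        resampled = seqs[:, cols]
        rows = {
            t: resampled[i].tobytes().decode() for i, t in enumerate(sm.taxa)
        }
        rep_sm = Supermatrix(
            taxa=sm.taxa, rows=rows, partitions=[("all", 1, length)]
        )
        try:
            rep_tree = nj_tree(distance_matrix(rep_sm, model=model), sm.taxa)
        except ValueError:
            continue  # saturated replicate: contributes no support
        rep_bps = bipartitions(rep_tree)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    leaves = frozenset(tree.leaves())

    def annotate(node: TreeNode):
        for child in node.children:
            side = frozenset(child.leaves())
            if 1 < len(side) < len(leaves) - 1:
                canon = min(side, leaves - side, key=lambda s: (len(s), sorted(s)))
                child.support = 100.0 * counts.get(canon, 0) / replicates
            annotate(child)

    annotate(tree)
    return tree


def robinson_foulds(newick_a: str, newick_b: str) -> int:
    """Unweighted RF distance between two trees given as newick strings."""
    import dendropy

    tns = dendropy.TaxonNamespace()
    ta = dendropy.Tree.get(data=newick_a, schema="newick", taxon_namespace=tns)
    tb = dendropy.Tree.get(data=newick_b, schema="newick", taxon_namespace=tns)
    ta.encode_bipartitions()
    tb.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(ta, tb))
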