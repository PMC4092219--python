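"""Within-genome collinear duplicate-block detection.

Paralog pairs passing the stringent self-search filter (E ≤ 1e-10) act as
anchors; blocks are maximal chains of anchors whose gene ranks run strictly
monotonically along both chromosome copies, with at most ``max_gap``
intervening genes between consecutive anchors on each chromosome and at
least ``min_pairs`` anchors per block.  Gap is counted in genes (rank
difference − 1), per chromosome, matching gene-rank synteny semantics.

Chains are extracted greedily: the best chain (most anchors; ties by
leftmost start) is found by dynamic programming per chromosome pair and
orientation, its anchors are retired, and the search repeats until no chain
of ``min_pairs`` anchors remains.  Tandem arrays (consecutive-rank genes
hitting each other) are collapsed to one representative before chaining.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .io_formats import GenePosition
from .similarity import SimilarityHit

MIN_PAIRS_DEFAULT = 5
MAX_GAP_DEFAULT = 20


@dataclass(frozen=True)
class AnchorPair:
    gene_a: str
    gene_b: str
    evalue: float

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"anchor pairs a gene with itself: {self.gene_a}")
        if self.gene_a > self.gene_b:
            raise ValueError("anchor pair must be stored canonically (a < b)")


@dataclass
class CollinearBlock:
    chrom_a: str
    chrom_b: str
    orientation: str  # "same" | "inverted"
    anchors: list[AnchorPair]

    @property
    def n_pairs(self) -> int:
        return len(self.anchors)


def paralog_anchors(
    self_hits: Iterable[SimilarityHit],
    positions: Mapping[str, GenePosition] | None = None,
) -> tuple[list[AnchorPair], int]:
    """Canonical unordered paralog pairs from self-search hits.

    Reciprocal hits collapse to one anchor keeping the best (lowest)
    E-value.  Pairs whose genes lack positions are dropped; the count of
    dropped pairs is returned alongside the anchors.
    """
    best: dict[tuple[str, str], float] = {}
    for h in self_hits:
        if h.is_self:
            continue
        key = (h.query, h.subject) if h.query < h.subject else (h.subject, h.query)
        if key not in best or h.evalue < best[key]:
            best[key] = h.evalue
    dropped = 0
    anchors = []
    for (a, b), ev in sorted(best.items()):
        if positions is not None and (a not in positions or b not in positions):
            dropped += 1
            continue
        anchors.append(AnchorPair(a, b, ev))
    return anchors, dropped


def _collapse_tandem(
    anchors: Sequence[AnchorPair], positions: Mapping[str, GenePosition]
) -> list[AnchorPair]:
    """Drop anchors that pair adjacent genes on one chromosome (tandem
    arrays); the remaining anchors are the array representatives."""
    out = []
    for a in anchors:
        pa, pb = positions[a.gene_a], positions[a.gene_b]
        if pa.chromosome == pb.chromosome and abs(pa.rank - pb.rank) == 1:
            continue
        out.append(a)
    return out


def _oriented_pairs(
    anchors: Sequence[AnchorPair], positions: Mapping[str, GenePosition]
) -> dict[tuple[str, str], list[tuple[int, int, AnchorPair]]]:
    """Group anchors by (sorted) chromosome pair as (rank_a, rank_b) points.

    For a within-chromosome pair the lower rank is placed first so each
    anchor yields one canonical point.
    """
    groups: dict[tuple[str, str], list[tuple[int, int, AnchorPair]]] = {}
    for anc in anchors:
        pa, pb = positions[anc.gene_a], positions[anc.gene_b]
        ca, cb = pa.chromosome, pb.chromosome
        ra, rb = pa.rank, pb.rank
        if (cb, rb) < (ca, ra):
            ca, cb, ra, rb = cb, ca, rb, ra
        groups.setdefault((ca, cb), []).append((ra, rb, anc))
    return groups


def _best_chain(
    points: Sequence[tuple[int, int, AnchorPair]], orientation: str, max_gap: int
) -> list[int]:
    """Longest valid chain (indices into ``points``) by DP.

    Valid transition: strictly increasing rank on chromosome A, strictly
    increasing (same) or strictly decreasing (inverted) on B, gap ≤ max_gap
    genes on each chromosome.  Ties broken toward the leftmost starting
    anchor (then second coordinate) for determinism.
    """
    n = len(points)
    if n == 0:
        return []
    order = sorted(range(n), key=lambda i: (points[i][0], points[i][1]))
    best_len = [1] * n  # indexed by position in `order`
    prev = [-1] * n
    for oi in range(n):
        ra, rb, _ = points[order[oi]]
        for oj in range(oi):
            qa, qb, _ = points[order[oj]]
            if qa >= ra or ra - qa - 1 > max_gap:
                continue
            if orientation == "same":
                if qb >= rb or rb - qb - 1 > max_gap:
                    continue
            else:
                if qb <= rb or qb - rb - 1 > max_gap:
                    continue
            cand = best_len[oj] + 1
            if cand > best_len[oi] or (
                cand == best_len[oi]
                and prev[oi] != -1
                and points[order[oj]][:2] < points[order[prev[oi]]][:2]
            ):
                best_len[oi] = cand
                prev[oi] = oj
    end = max(range(n), key=lambda oi: (best_len[oi], [-c for c in points[order[oi]][:2]]))
    chain_pos = []
    oi = end
    while oi != -1:
        chain_pos.append(oi)
        oi = prev[oi]
    chain_pos.reverse()
    return [order[oi] for oi in chain_pos]


def chain_blocks(
    anchors: Sequence[AnchorPair],
    positions: Mapping[str, GenePosition],
    min_pairs: int = MIN_PAIRS_DEFAULT,
    max_gap: int = MAX_GAP_DEFAULT,
    collapse_tandem: bool = True,
) -> list[CollinearBlock]:
    """Chain anchors into collinear blocks (≥ ``min_pairs`` anchors, gaps ≤
    ``max_gap`` intervening genes on each chromosome).

    Same- and inverted-orientation chains are found separately; each anchor
    belongs to at most one block (greedy by chain length, deterministic
    tie-break by leftmost start; same orientation considered first).
    """
    if collapse_tandem:
        anchors = _collapse_tandem(anchors, positions)
    blocks: list[CollinearBlock] = []
    for (ca, cb), pts in sorted(_oriented_pairs(anchors, positions).items()):
        available = list(pts)
        while True:
            candidates = []
            for orientation in ("same", "inverted"):
                chain = _best_chain(available, orientation, max_gap)
                if len(chain) >= min_pairs:
                    start = min((available[i][0], available[i][1]) for i in chain)
                    candidates.append((len(chain), orientation, start, chain))
            if not candidates:
                break
            # longest chain wins; ties: same orientation first, then leftmost
            candidates.sort(key=lambda c: (-c[0], c[1] != "same", c[2]))
            _, orientation, _, chain = candidates[0]
            chosen = [available[i] for i in chain]
            blocks.append(
                CollinearBlock(
                    chrom_a=ca,
                    chrom_b=cb,
                    orientation=orientation,
                    anchors=[p[2] for p in chosen],
                )
            )
            chain_set = set(chain)
            available = [p for i, p in enumerate(available) if i not in chain_set]
    return blocks


def validate_block(
    block: CollinearBlock, positions: Mapping[str, GenePosition], min_pairs: int, max_gap: int
) -> None:
    """Raise if a block violates its chain invariants."""
    if block.n_pairs < min_pairs:
        raise ValueError(f"block has {block.n_pairs} < {min_pairs} pairs")
    pts = []
    for anc in block.anchors:
        pa, pb = positions[anc.gene_a], positions[anc.gene_b]
        ra, rb = pa.rank, pb.rank
        if (pb.chromosome, rb) < (pa.chromosome, ra):
            ra, rb = rb, ra
        pts.append((ra, rb))
    for (a0, b0), (a1, b1) in zip(pts, pts[1:]):
        if a1 <= a0 or a1 - a0 - 1 > max_gap:
            raise ValueError("rank order or gap violated on chromosome A")
        if block.orientation == "same":
            if b1 <= b0 or b1 - b0 - 1 > max_gap:
                raise ValueError("rank order or gap violated on chromosome B")
        else:
            if b1 >= b0 or b0 - b1 - 1 > max_gap:
                raise ValueError("rank order or gap violated on chromosome B")


def block_counts(
    blocks_by_genome: Mapping[str, Sequence[CollinearBlock]]
) -> dict[str, int]:
    """Number of detected blocks per genome."""
    return {g: len(b) for g, b in blocks_by_genome.items()}


def write_blocks_tsv(
    blocks: Sequence[CollinearBlock], path, genome: str = ""
) -> None:
    with open(path, "w") as fh:
        fh.write("block_id\tgenome\tchrom_a\tchrom_b\torientation\tn_pairs\tanchors\n")
        for i, b in enumerate(blocks):
            pairs = ";".join(f"{a.gene_a},{a.gene_b}" for a in b.anchors)
            fh.write(
                f"B{i:04d}\t{genome}\t{b.chrom_a}\t{b.chrom_b}\t"
                f"{b.orientation}\t{b.n_pairs}\t{pairs}\n"
            )
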