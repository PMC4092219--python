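"""Pairwise Ka/Ks between best-hit homolog pairs (NG86 counting method).

Homolog pairs are reciprocal best hits between two genomes; each pair is
aligned at the protein level (global affine-gap) and the alignment is
mapped back onto the CDS codon-wise.  Synonymous and nonsynonymous sites
are counted per codon by the 1/3-per-position mutation-path rule and
averaged between the two sequences; differences per codon are averaged over
all minimal mutational pathways (pathways through stop codons excluded);
the raw proportions are corrected for multiple hits with Jukes–Cantor,
d = −(3/4)·ln(1 − (4/3)·p).

This deterministic counting estimator stands in for likelihood-based codon
models; results carry a ``method`` tag so downstream consumers know which
estimator produced them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import permutations
from typing import Iterable, Mapping, Sequence

from .io_formats import CODON_TABLE, GeneRecord
from .similarity import SearchParams, SimilarityHit, _make_aligner

METHOD = "NG86"

BASES = "ACGT"


@dataclass
class CodonAlignment:
    """Two gapped CDS of equal length; every column is a whole codon."""

    seq_a: str
    seq_b: str
    pair: tuple[str, str] = ("", "")

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned CDS lengths differ")
        if len(self.seq_a) % 3 != 0:
            raise ValueError("aligned length not divisible by 3")

    def codon_columns(self) -> Iterable[tuple[str, str]]:
        for i in range(0, len(self.seq_a), 3):
            yield self.seq_a[i : i + 3], self.seq_b[i : i + 3]


@dataclass
class KaKsResult:
    gene_a: str
    gene_b: str
    ka: float | None
    ks: float | None
    n_codons: int
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float
    method: str = METHOD
    flags: list[str] = field(default_factory=list)

    @property
    def omega(self) -> float | None:
        if self.ka is None or self.ks is None or self.ks == 0:
            return None
        return self.ka / self.ks


def best_hit_pairs(
    cross_hits: Iterable[SimilarityHit],
    genome_a: str,
    genome_b: str,
) -> list[tuple[str, str]]:
    """Reciprocal best hits between two genomes.

    Per query the best subject is the lowest E-value (ties: higher score,
    then lexicographic subject id); a pair is kept only when A's best is a B
    gene whose own best is that A gene.
    """
    best: dict[str, SimilarityHit] = {}
    for h in cross_hits:
        qg = h.query.split("|", 1)[0]
        sg = h.subject.split("|", 1)[0]
        if {qg, sg} != {genome_a, genome_b} or qg == sg:
            continue
        cur = best.get(h.query)
        if cur is None or (h.evalue, -h.score, h.subject) < (
            cur.evalue,
            -cur.score,
            cur.subject,
        ):
            best[h.query] = h
    pairs = []
    for q, h in best.items():
        if q.split("|", 1)[0] != genome_a:
            continue
        back = best.get(h.subject)
        if back is not None and back.subject == q:
            pairs.append((q, h.subject))
    return sorted(pairs)


def codon_align(
    prot_a: str, prot_b: str, cds_a: str, cds_b: str, params: SearchParams | None = None
) -> CodonAlignment:
    """Global protein alignment back-translated onto the two CDS."""
    params = params or SearchParams()
    for label, prot, cds in (("A", prot_a, cds_a), ("B", prot_b, cds_b)):
        if len(cds) != 3 * len(prot):
            raise ValueError(
                f"sequence {label}: CDS length {len(cds)} != 3 x protein "
                f"length {len(prot)}"
            )
        for i, aa in enumerate(prot):
            codon = cds[3 * i : 3 * i + 3]
            tr = CODON_TABLE.get(codon, "X")
            if tr != aa and aa != "X" and tr != "X":
                raise ValueError(
                    f"sequence {label}: codon {codon} at position {i} "
                    f"translates to {tr}, protein has {aa}"
                )
    aligner = _make_aligner(params, "global")
    alignment = next(iter(aligner.align(prot_a, prot_b)))
    ga, gb = str(alignment[0]), str(alignment[1])
    out_a, out_b = [], []
    ia = ib = 0
    for ca, cb in zip(ga, gb):
        if ca == "-":
            out_a.append("---")
        else:
            out_a.append(cds_a[3 * ia : 3 * ia + 3])
            ia += 1
        if cb == "-":
            out_b.append("---")
        else:
            out_b.append(cds_b[3 * ib : 3 * ib + 3])
            ib += 1
    return CodonAlignment("".join(out_a), "".join(out_b))


def _is_sense(codon: str) -> bool:
    return CODON_TABLE.get(codon, "*") != "*" and all(b in BASES for b in codon)


def syn_nonsyn_sites(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts of one codon (1/3-path rule).

    Each position contributes 1/3 site per alternative base; a change to a
    stop codon counts as nonsynonymous potential removed from neither class
    in the classic formulation — here mutations to stops are counted as
    nonsynonymous, the standard counting convention.
    """
    syn = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1 :]
            if CODON_TABLE[mutant] == CODON_TABLE[codon]:
                syn += 1 / 3
    return syn, 3.0 - syn


def pathway_diffs(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous differences between two codons over
    all minimal mutational pathways; pathways passing through a stop codon
    are excluded.  Returns (syn, nonsyn); their sum equals the number of
    differing positions (when any stop-free pathway exists)."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    totals = []
    for order in permutations(diff_pos):
        cur = codon_a
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if CODON_TABLE[nxt] == "*":
                ok = False
                break
            if CODON_TABLE[nxt] == CODON_TABLE[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            totals.append((syn, nonsyn))
    if not totals:
        # all pathways pass through stops; fall back to counting every
        # differing position as nonsynonymous
        return 0.0, float(len(diff_pos))
    s = sum(t[0] for t in totals) / len(totals)
    n = sum(t[1] for t in totals) / len(totals)
    return s, n


def jukes_cantor(p: float) -> float | None:
    """Multiple-hit correction d = −(3/4)·ln(1 − (4/3)p); None at saturation."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1 - 4 * p / 3)


def ng86(alignment: CodonAlignment) -> KaKsResult:
    """NG86 counting estimate of Ka and Ks over a codon alignment.

    Columns with gaps, ambiguity characters or stop codons are excluded
    pairwise (stop columns add a flag).  Symmetric in its two sequences.
    """
    syn_sites_a = syn_sites_b = 0.0
    syn_d = nonsyn_d = 0.0
    n_codons = 0
    flags: list[str] = []
    for ca, cb in alignment.codon_columns():
        if "-" in ca or "-" in cb:
            continue
        if not all(b in BASES for b in ca + cb):
            continue
        if CODON_TABLE[ca] == "*" or CODON_TABLE[cb] == "*":
            if "stop_column_excluded" not in flags:
                flags.append("stop_column_excluded")
            continue
        n_codons += 1
        sa, _ = syn_nonsyn_sites(ca)
        sb, _ = syn_nonsyn_sites(cb)
        syn_sites_a += sa
        syn_sites_b += sb
        ds, dn = pathway_diffs(ca, cb)
        syn_d += ds
        nonsyn_d += dn
    if n_codons == 0:
        raise ValueError("no ungapped sense codon columns in alignment")
    syn_sites = (syn_sites_a + syn_sites_b) / 2
    nonsyn_sites = 3.0 * n_codons - syn_sites
    ps = syn_d / syn_sites if syn_sites > 0 else 0.0
    pn = nonsyn_d / nonsyn_sites if nonsyn_sites > 0 else 0.0
    ks = jukes_cantor(ps)
    ka = jukes_cantor(pn)
    if ks is None:
        flags.append("ks_saturated")
    if ka is None:
        flags.append("ka_saturated")
    return KaKsResult(
        gene_a=alignment.pair[0],
        gene_b=alignment.pair[1],
        ka=ka,
        ks=ks,
        n_codons=n_codons,
        syn_sites=syn_sites,
        nonsyn_sites=nonsyn_sites,
        syn_diffs=syn_d,
        nonsyn_diffs=nonsyn_d,
        flags=flags,
    )


def pair_kaks(
    pairs: Sequence[tuple[str, str]],
    genes: Mapping[str, GeneRecord],
    params: SearchParams | None = None,
) -> list[KaKsResult]:
    """Align and estimate Ka/Ks for each reciprocal-best-hit pair."""
    out = []
    for a, b in pairs:
        ra, rb = genes[a], genes[b]
        aln = codon_align(ra.protein, rb.protein, ra.cds, rb.cds, params)
        aln.pair = (a, b)
        out.append(ng86(aln))
    return out


def write_kaks_tsv(results: Sequence[KaKsResult], path) -> None:
    def fmt(x: float | None) -> str:
        return "" if x is None else f"{x:.6f}"

    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tKa\tKs\tomega\tn_codons\tmethod\tflags\n")
        for r in results:
            fh.write(
                f"{r.gene_a}\t{r.gene_b}\t{fmt(r.ka)}\t{fmt(r.ks)}\t"
                f"{fmt(r.omega)}\t{r.n_codons}\t{r.method}\t{','.join(r.flags)}\n"
            )
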