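"""All-vs-all protein similarity search at desk scale.

Exact affine-gap local alignment (BLOSUM62) with Karlin–Altschul E-values,
plus the two filter regimes used throughout the pipeline:

* self-search (within one genome): E ≤ 1e-10, at most 200 subjects per query;
* cross-search (between genomes): E ≤ 1e-5, query coverage ≥ 70 %,
  identity ≥ 30 %.

The same filters apply unchanged to hit tables ingested from an external
search tool, so the built-in search and the ingest path are interchangeable
downstream.  A shared-4-mer prefilter skips obviously unrelated pairs; exact
dynamic programming remains the reference path (``prefilter=False``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

if TYPE_CHECKING:  # pragma: no cover
    from .io_formats import GeneRecord

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

LN2 = math.log(2.0)


@dataclass(frozen=True)
class SimilarityHit:
    """One filtered pairwise match between two proteins."""

    query: str
    subject: str
    identity: float  # percent, 0–100
    aln_length: int  # aligned columns
    query_coverage: float  # fraction of query residues aligned, 0–1
    score: float  # raw alignment score
    bitscore: float
    evalue: float

    @property
    def is_self(self) -> bool:
        return self.query == self.subject

    def __post_init__(self) -> None:
        if self.identity > 100.0 + 1e-9:
            raise ValueError(f"identity {self.identity} > 100")
        if self.query_coverage > 1.0 + 1e-9:
            raise ValueError(f"coverage {self.query_coverage} > 1")
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue}")


@dataclass(frozen=True)
class SearchParams:
    """Scoring scheme, statistics constants and filter cutoffs.

    Defaults follow standard gapped protein-search practice (BLOSUM62,
    gap open 11 / extend 1, lambda 0.267, K 0.041) with the pipeline's
    canonical cutoffs: self-search at E ≤ 1e-10 with up to 200 alignments
    per query, cross-search at E ≤ 1e-5, ≥ 70 % query coverage and ≥ 30 %
    identity.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0  # cost of a length-1 gap is gap_open + gap_extend
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    max_targets: int = 200
    self_evalue: float = 1e-10
    cross_evalue: float = 1e-5
    min_coverage: float = 0.70
    min_identity: float = 30.0
    prefilter_kmer: int = 4

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ValueError("Karlin–Altschul constants must be positive")
        if self.max_targets < 1:
            raise ValueError("max_targets must be >= 1")


def _check_protein(seq: str, label: str) -> None:
    if not seq:
        raise ValueError(f"{label}: empty protein sequence")
    bad = set(seq) - AA_ALPHABET
    if bad:
        raise ValueError(f"{label}: non-amino-acid characters {sorted(bad)}")


def _make_aligner(params: SearchParams, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(params.matrix_name)
    # affine gap of length k costs gap_open + k * gap_extend
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    if mode == "global":
        # terminal gaps cost the same as internal ones (true global alignment)
        aligner.open_end_gap_score = aligner.open_gap_score
        aligner.extend_end_gap_score = aligner.extend_gap_score
    return aligner


def _alignment_stats(alignment) -> tuple[int, int, int, int]:
    """(identities, columns, aligned residues of seq A, of seq B)."""
    a, b = alignment[0], alignment[1]
    ident = cols = ares = bres = 0
    for ca, cb in zip(a, b):
        if ca == "-" and cb == "-":
            continue
        cols += 1
        if ca != "-":
            ares += 1
        if cb != "-":
            bres += 1
        if ca == cb and ca != "-":
            ident += 1
    return ident, cols, ares, bres


def local_align(
    a: str, b: str, params: SearchParams | None = None
) -> tuple[float, float, int, float] | None:
    """Optimal affine-gap local alignment of protein ``a`` (query) vs ``b``.

    Returns ``(score, identity_percent, aln_length, query_coverage)`` or
    ``None`` when no positive-scoring local alignment exists.
    """
    params = params or SearchParams()
    _check_protein(a, "query")
    _check_protein(b, "subject")
    aligner = _make_aligner(params, "local")
    score = aligner.score(a, b)
    if score <= 0:
        return None
    alignment = next(iter(aligner.align(a, b)))
    ident, cols, ares, _bres = _alignment_stats(alignment)
    identity = 100.0 * ident / cols if cols else 0.0
    coverage = ares / len(a)
    return float(score), identity, cols, coverage


def global_align_score(a: str, b: str, params: SearchParams | None = None) -> float:
    """Optimal affine-gap global (Needleman–Wunsch) protein score."""
    params = params or SearchParams()
    _check_protein(a, "query")
    _check_protein(b, "subject")
    return float(_make_aligner(params, "global").score(a, b))


def estimate_evalue(
    score: float, query_len: int, db_residues: int, params: SearchParams | None = None
) -> float:
    """Karlin–Altschul expectation: E = K · m · n · exp(−lambda · S)."""
    params = params or SearchParams()
    if query_len <= 0 or db_residues <= 0:
        raise ValueError("query and database lengths must be positive")
    if score <= 0:
        raise ValueError("score must be positive")
    return params.karlin_k * query_len * db_residues * math.exp(
        -params.karlin_lambda * score
    )


def bit_score(score: float, params: SearchParams | None = None) -> float:
    params = params or SearchParams()
    return (params.karlin_lambda * score - math.log(params.karlin_k)) / LN2


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _pair_hits(
    q: "GeneRecord",
    s: "GeneRecord",
    db_residues: int,
    params: SearchParams,
    aligner: Align.PairwiseAligner,
    both_directions: bool,
) -> list[SimilarityHit]:
    """Align one pair; emit the q→s hit (and the mirrored s→q hit when
    ``both_directions``) from a single optimal local alignment."""
    score = aligner.score(q.protein, s.protein)
    if score <= 0:
        return []
    ev_cut = max(params.self_evalue, params.cross_evalue)
    ev_q = estimate_evalue(score, len(q.protein), db_residues, params)
    ev_s = (
        estimate_evalue(score, len(s.protein), db_residues, params)
        if both_directions
        else math.inf
    )
    if ev_q > ev_cut and ev_s > ev_cut:
        return []  # cannot pass any regime; skip the costly traceback
    alignment = next(iter(aligner.align(q.protein, s.protein)))
    ident, cols, qres, sres = _alignment_stats(alignment)
    identity = 100.0 * ident / cols if cols else 0.0
    bits = bit_score(score, params)
    out = [
        SimilarityHit(
            query=q.key,
            subject=s.key,
            identity=identity,
            aln_length=cols,
            query_coverage=qres / len(q.protein),
            score=float(score),
            bitscore=bits,
            evalue=ev_q,
        )
    ]
    if both_directions and q.key != s.key:
        out.append(
            SimilarityHit(
                query=s.key,
                subject=q.key,
                identity=identity,
                aln_length=cols,
                query_coverage=sres / len(s.protein),
                score=float(score),
                bitscore=bits,
                evalue=ev_s,
            )
        )
    return out


def _search(
    queries: Sequence["GeneRecord"],
    subjects: Sequence["GeneRecord"],
    params: SearchParams,
    prefilter: bool,
    symmetric: bool,
) -> list[SimilarityHit]:
    """All-vs-all alignment; when ``symmetric``, queries and subjects are the
    same list and each unordered pair is aligned once, emitting both
    directions."""
    db_residues = sum(len(s.protein) for s in subjects)
    aligner = _make_aligner(params, "local")
    kmer = params.prefilter_kmer
    if prefilter:
        kmaps = {r.key: _kmers(r.protein, kmer) for r in list(queries) + list(subjects)}
    hits: list[SimilarityHit] = []
    for qi, q in enumerate(queries):
        subj_iter = subjects[qi:] if symmetric else subjects
        for s in subj_iter:
            if q.key != s.key and prefilter and not (kmaps[q.key] & kmaps[s.key]):
                continue
            hits.extend(
                _pair_hits(q, s, db_residues, params, aligner, both_directions=symmetric)
            )
    return hits


def _cap_targets(hits: Iterable[SimilarityHit], max_targets: int) -> list[SimilarityHit]:
    """Keep at most ``max_targets`` non-self subjects per query.

    Order: best E-value first, ties by higher score, then subject id.  The
    self-hit never counts against the cap.
    """
    by_query: dict[str, list[SimilarityHit]] = {}
    for h in hits:
        by_query.setdefault(h.query, []).append(h)
    out: list[SimilarityHit] = []
    for q in sorted(by_query):
        rows = sorted(by_query[q], key=lambda h: (h.evalue, -h.score, h.subject))
        kept = 0
        for h in rows:
            if h.is_self:
                out.append(h)
            elif kept < max_targets:
                out.append(h)
                kept += 1
    return out


def self_search(
    genome: Sequence["GeneRecord"],
    params: SearchParams | None = None,
    prefilter: bool = True,
) -> list[SimilarityHit]:
    """Within-genome all-vs-all search at the self regime (E ≤ 1e-10).

    At most ``max_targets`` (default 200) non-self subjects are reported per
    query; self-hits are retained and flaggable via :attr:`SimilarityHit.is_self`.
    """
    params = params or SearchParams()
    if not genome:
        raise ValueError("empty genome")
    raw = _search(list(genome), list(genome), params, prefilter, symmetric=True)
    passing = [h for h in raw if h.evalue <= params.self_evalue]
    return _cap_targets(passing, params.max_targets)


def cross_filter(hits: Iterable[SimilarityHit], params: SearchParams | None = None) -> list[SimilarityHit]:
    """The cross-genome filter: E ≤ 1e-5, coverage ≥ 0.70, identity ≥ 30.

    Pure and idempotent; applied identically to built-in and ingested hits.
    """
    params = params or SearchParams()
    return [
        h
        for h in hits
        if not h.is_self
        and h.evalue <= params.cross_evalue
        and h.query_coverage >= params.min_coverage
        and h.identity >= params.min_identity
    ]


def cross_search(
    genome_a: Sequence["GeneRecord"],
    genome_b: Sequence["GeneRecord"],
    params: SearchParams | None = None,
    prefilter: bool = True,
) -> list[SimilarityHit]:
    """Between-genome search at the cross regime (both directions).

    Only hits passing ALL of E ≤ 1e-5, query coverage ≥ 70 % and identity
    ≥ 30 % are returned.
    """
    params = params or SearchParams()
    if not genome_a or not genome_b:
        raise ValueError("empty genome")
    ga = {g.genome_id for g in genome_a}
    gb = {g.genome_id for g in genome_b}
    if ga == gb:
        raise ValueError("cross_search requires two distinct genomes")
    fwd = _search(list(genome_a), list(genome_b), params, prefilter, symmetric=False)
    rev = _search(list(genome_b), list(genome_a), params, prefilter, symmetric=False)
    return cross_filter(fwd, params) + cross_filter(rev, params)
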