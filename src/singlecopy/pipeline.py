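"""End-to-end orchestration: search → cluster → classify → blocks → report.

`run_all` wires the stages together over an in-memory :class:`GenomeSet`
and returns a result bundle holding every intermediate product, so the
analysis scripts (and tests) can inspect any stage.  `report_summary`
produces the per-genome summary table plus the derived statistics used in
the comparative analysis: the range of single-copy percentages, the
singleton/single-copy ratio range, and the Spearman correlation between
per-genome collinear-block counts and single-copy abundance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import classify, collinearity, mcl
from .classify import CopyStatus, GenomeSummary, OrthoCluster
from .collinearity import CollinearBlock
from .io_formats import GenePosition, GenomeSet
from .similarity import SearchParams, SimilarityHit, cross_search, self_search
from .stats import spearman


@dataclass
class PipelineConfig:
    params: SearchParams = field(default_factory=SearchParams)
    mcl_params: mcl.MclParams = field(default_factory=mcl.MclParams)
    min_pairs: int = collinearity.MIN_PAIRS_DEFAULT
    max_gap: int = collinearity.MAX_GAP_DEFAULT
    confirm_rounds: int = 3
    prefilter: bool = True


@dataclass
class PipelineResult:
    genome_set: GenomeSet
    self_hits: dict[str, list[SimilarityHit]]
    cross_hits: list[SimilarityHit]
    statuses: dict[str, CopyStatus]
    clusters: list[OrthoCluster]
    shared: list[OrthoCluster]
    blocks: dict[str, list[CollinearBlock]]
    summaries: list[GenomeSummary]


def run_all(
    genome_set: GenomeSet,
    positions: Mapping[str, GenePosition] | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full comparative pipeline over a genome set.

    With a single genome the cross-genome stages are skipped (no clusters,
    no singleton flags beyond the trivial all-singleton case).
    """
    config = config or PipelineConfig()
    genome_ids = genome_set.genome_ids
    if not genome_ids:
        raise ValueError("empty genome set")
    params = config.params

    # stage 1: within-genome self search + classification
    self_hits: dict[str, list[SimilarityHit]] = {}
    statuses: dict[str, CopyStatus] = {}
    for gid in genome_ids:
        genes = genome_set.genomes[gid]
        hits = self_search(genes, params, prefilter=config.prefilter)
        self_hits[gid] = hits
        statuses.update(classify.within_genome_single_copy(hits, genes))

    # stage 2: cross-genome search
    cross_hits: list[SimilarityHit] = []
    for i, ga in enumerate(genome_ids):
        for gb in genome_ids[i + 1 :]:
            cross_hits.extend(
                cross_search(
                    genome_set.genomes[ga],
                    genome_set.genomes[gb],
                    params,
                    prefilter=config.prefilter,
                )
            )

    # stage 3: MCL clustering + mutual confirmation + shared single copy
    clusters: list[OrthoCluster] = []
    shared: list[OrthoCluster] = []
    if len(genome_ids) > 1:
        graph = mcl.graph_from_hits(cross_hits)
        raw = mcl.mcl(graph, config.mcl_params)
        clusters = classify.confirm_clusters(raw, cross_hits, config.confirm_rounds)
        shared = classify.shared_single_copy(clusters, genome_ids)
        classify.find_singletons(statuses, cross_hits)
        classify.flag_shared(statuses, shared)
    else:
        for st in statuses.values():
            st.singleton = st.single_copy

    # stage 4: collinear blocks per genome
    blocks: dict[str, list[CollinearBlock]] = {}
    if positions is not None:
        for gid in genome_ids:
            anchors, _dropped = collinearity.paralog_anchors(
                self_hits[gid], positions
            )
            blocks[gid] = collinearity.chain_blocks(
                anchors, positions, config.min_pairs, config.max_gap
            )

    summaries = classify.summarize(
        {gid: len(genome_set.genomes[gid]) for gid in genome_ids},
        statuses,
        collinearity.block_counts(blocks) if blocks else None,
    )
    return PipelineResult(
        genome_set=genome_set,
        self_hits=self_hits,
        cross_hits=cross_hits,
        statuses=statuses,
        clusters=clusters,
        shared=shared,
        blocks=blocks,
        summaries=summaries,
    )


@dataclass
class SummaryReport:
    summaries: list[GenomeSummary]
    pct_range: tuple[float, float]
    ratio_range: tuple[float, float] | None
    rho_blocks_vs_pct: float | None
    p_blocks_vs_pct: float | None
    rho_blocks_vs_count: float | None
    p_blocks_vs_count: float | None


def report_summary(summaries: Sequence[GenomeSummary]) -> SummaryReport:
    """Derived statistics over per-genome summaries.

    The block correlation is reported against both the single-copy
    percentage and the raw count; with fewer than 3 genomes the
    correlations are omitted (None).
    """
    pcts = [s.pct_single_copy for s in summaries]
    ratios = [s.singleton_ratio for s in summaries if s.singleton_ratio is not None]
    rho_pct = p_pct = rho_cnt = p_cnt = None
    if len(summaries) >= 3:
        blocks = [float(s.n_blocks) for s in summaries]
        rho_pct, p_pct = spearman(blocks, pcts)
        rho_cnt, p_cnt = spearman(
            blocks, [float(s.n_single_copy) for s in summaries]
        )
    return SummaryReport(
        summaries=list(summaries),
        pct_range=(min(pcts), max(pcts)),
        ratio_range=(min(ratios), max(ratios)) if ratios else None,
        rho_blocks_vs_pct=rho_pct,
        p_blocks_vs_pct=p_pct,
        rho_blocks_vs_count=rho_cnt,
        p_blocks_vs_count=p_cnt,
    )
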