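"""Bundled reference tables.

`angiosperm_summary` loads the published per-genome survey of 29 angiosperm
genomes (total annotated genes, within-genome single-copy genes,
species-specific singletons, and collinear duplicate-block counts) used by
the comparative summary statistics.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .classify import GenomeSummary


def angiosperm_summary() -> list[GenomeSummary]:
    """The 29-genome angiosperm survey as :class:`GenomeSummary` rows."""
    with resources.files("singlecopy.data").joinpath(
        "angiosperm_summary.tsv"
    ).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return [
        GenomeSummary(
            genome_id=row.genome,
            total_genes=int(row.total_genes),
            n_single_copy=int(row.n_single_copy),
            n_singletons=int(row.n_singletons),
            n_blocks=int(row.n_blocks),
        )
        for row in df.itertuples()
    ]
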