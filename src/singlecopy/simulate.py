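"""Synthetic multi-genome generator with known truth labels.

Gene complements evolve by birth–death duplication/loss along a species
tree, with optional whole-genome duplication (WGD) events that copy every
gene on a branch and retain each extra copy with a configurable
probability.  A fraction of base families is "duplication-resistant"
(conserved): they neither duplicate nor get lost, carry stronger codon bias
(lower Nc, lower GC3) and evolve under stronger purifying selection (lower
omega) — planting the contrasts between single-copy and family genes that
the analysis pipeline is meant to detect.  Per-lineage orphan genes with
random sequences plant singletons.  Gene order is emitted with WGD copies
laid down as duplicated chromosome segments, so collinear blocks exist at
known locations.  Alternative-splicing event counts are drawn from
family-size-bin-dependent distributions.

Everything is driven by one integer seed; identical seeds give byte-identical
output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .io_formats import (
    CODON_TABLE,
    GenePosition,
    GeneRecord,
    GenomeSet,
    translate_cds,
    write_fasta,
    write_positions,
)
from .codon import FAMILIES

AAS = sorted(FAMILIES)

DEFAULT_TREE = "((A:0.06,B:0.06):0.04,(C:0.06,D:0.06):0.04,E:0.10);"


@dataclass(frozen=True)
class ClassModel:
    """Sequence-evolution parameters of one gene class."""

    omega: float  # Ka/Ks of accepted substitutions
    target_gc3: float  # third-position G+C of the root codon sampler
    codon_bias: float  # preferred-codon boost (1 = none)
    dup_rate: float  # duplications per gene per unit branch length
    loss_rate: float


@dataclass(frozen=True)
class SimConfig:
    species_tree: str = DEFAULT_TREE
    n_base_genes: int = 100
    conserved_fraction: float = 0.5
    conserved: ClassModel = ClassModel(
        omega=0.1, target_gc3=0.30, codon_bias=8.0, dup_rate=0.0, loss_rate=0.0
    )
    duplicable: ClassModel = ClassModel(
        omega=0.5, target_gc3=0.60, codon_bias=1.0, dup_rate=0.35, loss_rate=0.10
    )
    wgd_events: tuple[tuple[str, float], ...] = (("E", 0.25),)
    orphan_rate: float = 0.05
    n_codons: int = 120
    mutation_rate: float = 1.0  # proposals per site per unit branch length
    n_chromosomes: int = 2
    n_introns: int = 2
    intron_length: int = 60
    intron_rate_factor: float = 3.0
    as_means: dict = field(
        default_factory=lambda: {
            "single_copy": 1.2,
            "family_1_10": 2.0,
            "family_gt10": 0.6,
        }
    )
    seed: int = 0


@dataclass
class TruthRow:
    gene: str  # namespaced genome|gene key
    genome: str
    family: int
    family_size: int
    is_single_copy: bool
    is_singleton: bool
    shared_cluster: int | None
    block: str | None
    omega: float
    as_count: int


@dataclass
class SimResult:
    genome_set: GenomeSet
    positions: dict[str, GenePosition]
    truth: list[TruthRow]
    truth_blocks: dict[str, list[list[tuple[str, str]]]]  # genome -> blocks
    config: SimConfig

    def truth_by_gene(self) -> dict[str, TruthRow]:
        return {t.gene: t for t in self.truth}


# ---------------------------------------------------------------------------
# Root sequence sampling


def _codon_weights(model: ClassModel) -> dict[str, np.ndarray]:
    """Per-amino-acid codon sampling weights hitting the class's GC3 target
    and bias level.  Within a family, probability mass target_gc3 goes to
    G/C-ending codons (uniform within the group), the rest to A/T-ending;
    the first codon of the majority group is boosted by ``codon_bias``."""
    weights: dict[str, np.ndarray] = {}
    for aa, fam in FAMILIES.items():
        gc_group = [c for c in fam if c[2] in "GC"]
        at_group = [c for c in fam if c[2] in "AT"]
        w = np.zeros(len(fam))
        for i, c in enumerate(fam):
            if gc_group and at_group:
                w[i] = (
                    model.target_gc3 / len(gc_group)
                    if c in gc_group
                    else (1 - model.target_gc3) / len(at_group)
                )
            else:
                w[i] = 1 / len(fam)
        if len(fam) > 1 and model.codon_bias > 1:
            major = gc_group if model.target_gc3 >= 0.5 and gc_group else at_group or fam
            pref = sorted(major)[0]
            w[fam.index(pref)] *= model.codon_bias
        weights[aa] = w / w.sum()
    return weights


def _sample_cds(n_codons: int, weights: dict[str, np.ndarray], rng) -> str:
    codons = []
    for _ in range(n_codons):
        aa = AAS[rng.integers(len(AAS))]
        fam = FAMILIES[aa]
        codons.append(fam[rng.choice(len(fam), p=weights[aa])])
    return "".join(codons)


def _random_intron(length: int, rng) -> str:
    body = "".join("ACGT"[i] for i in rng.integers(0, 4, size=max(length - 4, 0)))
    return "GT" + body + "AG"


# ---------------------------------------------------------------------------
# Sequence evolution


def evolve_cds(cds: str, t: float, omega: float, rng, rate: float = 1.0) -> str:
    """Evolve a CDS for branch length ``t`` under a simple codon scheme.

    Proposal events arrive at ``rate`` per site; each picks a random site
    and a random alternative base.  Proposals creating stops are rejected,
    synonymous proposals are always accepted, nonsynonymous ones with
    probability ``omega`` — so the accepted-change ratio matches the planted
    omega under uniform mutational pressure.
    """
    seq = list(cds)
    n_events = rng.poisson(rate * len(seq) * t)
    for _ in range(n_events):
        pos = int(rng.integers(len(seq)))
        old = seq[pos]
        alt = "ACGT".replace(old, "")
        new = alt[rng.integers(3)]
        ci = pos - pos % 3
        codon_old = "".join(seq[ci : ci + 3])
        codon_new = codon_old[: pos - ci] + new + codon_old[pos - ci + 1 :]
        if CODON_TABLE[codon_new] == "*":
            continue
        if CODON_TABLE[codon_new] == CODON_TABLE[codon_old]:
            seq[pos] = new
        elif rng.random() < omega:
            seq[pos] = new
    return "".join(seq)


def evolve_neutral(seq: str, t: float, rng, rate: float = 1.0) -> str:
    """Neutral nucleotide evolution (introns)."""
    out = list(seq)
    n_events = rng.poisson(rate * len(out) * t)
    for _ in range(n_events):
        pos = int(rng.integers(len(out)))
        alt = "ACGT".replace(out[pos], "") if out[pos] in "ACGT" else "ACGT"
        out[pos] = alt[rng.integers(len(alt))]
    return "".join(out)


def simulate_codon_pair(
    omega: float, n_codons: int, t: float, seed: int
) -> tuple[str, str]:
    """Two CDS diverged from a common ancestor by total branch length 2·t
    under the planted omega (for estimator-recovery checks)."""
    rng = np.random.default_rng(seed)
    weights = _codon_weights(
        ClassModel(omega=omega, target_gc3=0.5, codon_bias=1.0, dup_rate=0, loss_rate=0)
    )
    root = _sample_cds(n_codons, weights, rng)
    a = evolve_cds(root, t, omega, rng)
    b = evolve_cds(root, t, omega, rng)
    return a, b


# ---------------------------------------------------------------------------
# Gene-family evolution along the species tree


@dataclass
class _Lineage:
    family: int
    cds: str
    introns: list[str]
    origin_chrom: int | None  # ancestral slot (None for small-scale copies)
    origin_rank: int | None
    wgd_level: int = 0  # how many WGD copies separate it from the base slot


def simulate_families(config: SimConfig, rng=None, sequences: bool = True):
    """Run the birth–death/WGD process; returns per-genome lineage lists.

    Sequence evolution happens in the same pass (each surviving lineage's
    CDS and introns evolve along each branch), so the result carries final
    sequences as well as family structure.  ``sequences=False`` skips root
    sampling and per-branch evolution (family structure only; much faster).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    tree = dendropy.Tree.get(data=config.species_tree, schema="newick")
    classes = {}
    conserved_w = _codon_weights(config.conserved)
    duplicable_w = _codon_weights(config.duplicable)
    per_chrom = -(-config.n_base_genes // config.n_chromosomes)
    root_lineages: list[_Lineage] = []
    for f in range(config.n_base_genes):
        conserved = rng.random() < config.conserved_fraction
        classes[f] = config.conserved if conserved else config.duplicable
        if sequences:
            cds = _sample_cds(
                config.n_codons, conserved_w if conserved else duplicable_w, rng
            )
            introns = [
                _random_intron(config.intron_length, rng)
                for _ in range(config.n_introns)
            ]
        else:
            cds, introns = "", []
        root_lineages.append(
            _Lineage(
                family=f,
                cds=cds,
                introns=introns,
                origin_chrom=f // per_chrom,
                origin_rank=f % per_chrom,
            )
        )
    wgd_by_edge = {}
    for label, retention in config.wgd_events:
        wgd_by_edge[label] = retention
    leaf_lineages: dict[str, list[_Lineage]] = {}

    def node_label(node) -> str | None:
        if node.taxon is not None:
            return node.taxon.label
        return node.label

    def descend(node, lineages: list[_Lineage]):
        for child in node.child_nodes():
            t = child.edge.length or 0.0
            state = [replace(lin, introns=list(lin.introns)) for lin in lineages]
            label = node_label(child)
            # WGD on this branch: copy every gene, keep extras with retention p
            if label in wgd_by_edge:
                retention = wgd_by_edge[label]
                extras = []
                for lin in state:
                    if rng.random() < retention:
                        extras.append(
                            replace(
                                lin,
                                introns=list(lin.introns),
                                wgd_level=lin.wgd_level + 1,
                            )
                        )
                state.extend(extras)
            # birth–death per lineage
            nxt: list[_Lineage] = []
            for lin in state:
                model = classes[lin.family]
                if model.loss_rate > 0 and rng.random() < 1 - np.exp(
                    -model.loss_rate * t
                ):
                    continue
                nxt.append(lin)
                n_dup = rng.poisson(model.dup_rate * t)
                for _ in range(n_dup):
                    nxt.append(
                        replace(
                            lin,
                            introns=list(lin.introns),
                            origin_chrom=None,
                            origin_rank=None,
                        )
                    )
            # sequence evolution along the branch
            if sequences:
                for lin in nxt:
                    model = classes[lin.family]
                    lin.cds = evolve_cds(
                        lin.cds, t, model.omega, rng, rate=config.mutation_rate
                    )
                    lin.introns = [
                        evolve_neutral(
                            iv,
                            t,
                            rng,
                            rate=config.mutation_rate * config.intron_rate_factor,
                        )
                        for iv in lin.introns
                    ]
            if child.is_leaf():
                leaf_lineages[child.taxon.label] = nxt
            else:
                descend(child, nxt)

    descend(tree.seed_node, root_lineages)
    omegas = {f: classes[f].omega for f in classes}
    return leaf_lineages, omegas


# ---------------------------------------------------------------------------
# Gene order with planted blocks


def _layout_genome(
    genome_id: str,
    lineages: Sequence[_Lineage],
    config: SimConfig,
    rng,
) -> tuple[list[tuple[str, _Lineage, GenePosition]], list[list[tuple[str, str]]]]:
    """Assign gene ids and positions; returns (records, truth blocks).

    Ancestral-slot genes sit in ancestral order on their chromosome; WGD
    copies form parallel chromosomes named with a ``w`` suffix per level;
    small-scale duplicates and orphans are appended at chromosome ends.
    """
    per_chrom: dict[str, list[tuple[tuple, _Lineage]]] = {}
    copy_counter: dict[int, int] = {}
    named: list[tuple[str, _Lineage]] = []
    for lin in lineages:
        idx = copy_counter.get(lin.family, 0)
        copy_counter[lin.family] = idx + 1
        gene_id = f"g{lin.family:04d}_{idx}"
        named.append((gene_id, lin))
        if lin.origin_chrom is None:
            chrom = f"chr{int(rng.integers(config.n_chromosomes))}"
            sort_key = (1, len(named), 0)
        else:
            chrom = f"chr{lin.origin_chrom}" + "w" * lin.wgd_level
            sort_key = (0, lin.origin_rank, lin.wgd_level)
        per_chrom.setdefault(chrom, []).append((sort_key, (gene_id, lin)))
    records: list[tuple[str, _Lineage, GenePosition]] = []
    ranks: dict[str, dict[str, int]] = {}
    for chrom in sorted(per_chrom):
        entries = sorted(per_chrom[chrom], key=lambda e: e[0])
        for rank, (_, (gene_id, lin)) in enumerate(entries):
            records.append((gene_id, lin, GenePosition(chrom, rank, "+")))
            ranks.setdefault(chrom, {})[gene_id] = rank
    # truth blocks: runs of (ancestral gene, WGD copy) pairs per chromosome pair
    blocks: list[list[tuple[str, str]]] = []
    by_slot: dict[tuple[int, int, int], list[tuple[str, _Lineage]]] = {}
    for gene_id, lin, _pos in records:
        if lin.origin_chrom is not None:
            by_slot.setdefault(
                (lin.origin_chrom, lin.origin_rank, lin.wgd_level), []
            ).append((gene_id, lin))
    levels = sorted({lin.wgd_level for _g, lin, _p in records})
    for level in levels:
        if level == 0:
            continue
        for chrom_idx in range(config.n_chromosomes):
            pairs = []
            # slots having exactly one gene at level 0 and one at `level`
            slots = sorted(
                {
                    orank
                    for (oc, orank, lv) in by_slot
                    if oc == chrom_idx and lv in (0, level)
                }
            )
            for orank in slots:
                base = by_slot.get((chrom_idx, orank, 0), [])
                dup = by_slot.get((chrom_idx, orank, level), [])
                if len(base) == 1 and len(dup) == 1:
                    pairs.append((orank, base[0][0], dup[0][0]))
            pairs.sort()
            chrom_a = f"chr{chrom_idx}"
            chrom_b = f"chr{chrom_idx}" + "w" * level
            run: list[tuple[str, str]] = []
            prev_ra = prev_rb = None
            for orank, ga, gb in pairs:
                ra = ranks.get(chrom_a, {}).get(ga)
                rb = ranks.get(chrom_b, {}).get(gb)
                if ra is None or rb is None:
                    continue
                if (
                    prev_ra is not None
                    and (ra - prev_ra - 1 > 20 or rb - prev_rb - 1 > 20)
                ):
                    if len(run) >= 5:
                        blocks.append(run)
                    run = []
                run.append((ga, gb))
                prev_ra, prev_rb = ra, rb
            if len(run) >= 5:
                blocks.append(run)
    return records, blocks


# ---------------------------------------------------------------------------
# Orchestration


def simulate_as_counts(
    family_sizes: dict[str, int], config: SimConfig, rng
) -> dict[str, int]:
    """Draw per-gene AS event counts from the family-size-bin means."""
    from .stats import family_size_bin

    out = {}
    for gene in sorted(family_sizes):
        mean = config.as_means[family_size_bin(family_sizes[gene])]
        out[gene] = int(rng.poisson(mean))
    return out


def simulate(config: SimConfig | None = None) -> SimResult:
    """Generate the full synthetic data set with truth labels."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    leaf_lineages, omegas = simulate_families(config, rng)
    genome_ids = sorted(leaf_lineages)
    genome_set = GenomeSet()
    positions: dict[str, GenePosition] = {}
    truth_blocks: dict[str, list[list[tuple[str, str]]]] = {}
    gene_family: dict[str, int] = {}
    per_genome_family_counts: dict[str, dict[int, int]] = {}
    gene_records: dict[str, tuple[str, _Lineage]] = {}
    next_orphan_family = 10**6
    for genome in genome_ids:
        lineages = list(leaf_lineages[genome])
        # per-lineage orphans: novel genes with no homologs anywhere
        n_orphans = int(round(config.orphan_rate * config.n_base_genes))
        orphan_w = _codon_weights(config.duplicable)
        for i in range(n_orphans):
            fam = next_orphan_family
            next_orphan_family += 1
            omegas[fam] = config.duplicable.omega
            lineages.append(
                _Lineage(
                    family=fam,
                    cds=_sample_cds(config.n_codons, orphan_w, rng),
                    introns=[
                        _random_intron(config.intron_length, rng)
                        for _ in range(config.n_introns)
                    ],
                    origin_chrom=None,
                    origin_rank=None,
                )
            )
        records, blocks = _layout_genome(genome, lineages, config, rng)
        truth_blocks[genome] = blocks
        counts: dict[int, int] = {}
        for gene_id, lin, pos in records:
            counts[lin.family] = counts.get(lin.family, 0) + 1
        per_genome_family_counts[genome] = counts
        for gene_id, lin, pos in records:
            key = f"{genome}|{gene_id}"
            gene_family[key] = lin.family
            positions[key] = pos
            gene_records[key] = (genome, lin)
            gene_seq = _assemble_gene_seq(lin, config)
            genome_set.add(
                GeneRecord(
                    gene_id=gene_id,
                    genome_id=genome,
                    protein=translate_cds(lin.cds),
                    cds=lin.cds,
                    gene_seq=gene_seq,
                    position=pos,
                )
            )
    # truth labels
    family_presence: dict[int, dict[str, int]] = {}
    for genome, counts in per_genome_family_counts.items():
        for fam, n in counts.items():
            family_presence.setdefault(fam, {})[genome] = n
    shared_families = {
        fam
        for fam, pres in family_presence.items()
        if set(pres) == set(genome_ids) and all(v == 1 for v in pres.values())
    }
    block_of_gene: dict[str, str] = {}
    for genome, blocks in truth_blocks.items():
        for bi, block in enumerate(blocks):
            for ga, gb in block:
                block_of_gene[f"{genome}|{ga}"] = f"{genome}:B{bi}"
                block_of_gene[f"{genome}|{gb}"] = f"{genome}:B{bi}"
    family_sizes = {
        key: per_genome_family_counts[key.split("|", 1)[0]][fam]
        for key, fam in gene_family.items()
    }
    as_counts = simulate_as_counts(family_sizes, config, rng)
    truth: list[TruthRow] = []
    for key in sorted(gene_family):
        genome = key.split("|", 1)[0]
        fam = gene_family[key]
        fsize = family_sizes[key]
        single = fsize == 1
        elsewhere = sum(
            n for g, n in family_presence[fam].items() if g != genome
        )
        truth.append(
            TruthRow(
                gene=key,
                genome=genome,
                family=fam,
                family_size=fsize,
                is_single_copy=single,
                is_singleton=single and elsewhere == 0,
                shared_cluster=fam if fam in shared_families else None,
                block=block_of_gene.get(key),
                omega=omegas[fam],
                as_count=as_counts[key],
            )
        )
    return SimResult(
        genome_set=genome_set,
        positions=positions,
        truth=truth,
        truth_blocks=truth_blocks,
        config=config,
    )


def _assemble_gene_seq(lin: _Lineage, config: SimConfig) -> str:
    """Unspliced gene sequence: exons with introns at evenly spaced conserved
    positions."""
    if not lin.introns:
        return lin.cds
    n = len(lin.introns)
    codons = len(lin.cds) // 3
    cut_points = [3 * ((i + 1) * codons // (n + 1)) for i in range(n)]
    parts = []
    prev = 0
    for cut, intron in zip(cut_points, lin.introns):
        parts.append(lin.cds[prev:cut])
        parts.append(intron)
        prev = cut
    parts.append(lin.cds[prev:])
    return "".join(parts)


def write_dataset(result: SimResult, outdir: str | Path) -> None:
    """Emit per-genome FASTA (protein/CDS/gene), positions and truth TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for genome, recs in result.genome_set.genomes.items():
        write_fasta([(r.gene_id, r.protein) for r in recs], outdir / f"{genome}.pep.fasta")
        write_fasta([(r.gene_id, r.cds) for r in recs], outdir / f"{genome}.cds.fasta")
        write_fasta(
            [(r.gene_id, r.gene_seq) for r in recs], outdir / f"{genome}.gene.fasta"
        )
    write_positions(result.positions, outdir / "positions.tsv")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write(
            "gene\tgenome\tfamily\tfamily_size\tis_single_copy\tis_singleton"
            "\tshared_cluster\tblock\tomega\tas_count\n"
        )
        for t in result.truth:
            fh.write(
                f"{t.gene}\t{t.genome}\t{t.family}\t{t.family_size}\t"
                f"{int(t.is_single_copy)}\t{int(t.is_singleton)}\t"
                f"{'' if t.shared_cluster is None else t.shared_cluster}\t"
                f"{t.block or ''}\t{t.omega}\t{t.as_count}\n"
            )
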