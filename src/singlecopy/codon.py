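"""Per-gene codon-usage indices: codon counts, GC3, RSCU, Wright's Nc, CAI.

Nc (effective number of codons) summarizes codon bias independently of gene
length and amino-acid composition: 20 means one codon per amino acid
(extreme bias), 61 means uniform synonymous usage.  It is estimated from
per-family codon homozygosity F̂ = (n·Σp̂² − 1)/(n − 1) averaged within
redundancy classes, composed as Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆
(the six-fold families Leu/Ser/Arg form their own class), and clamped to
[20, 61] because the finite-sample estimator can exceed the theoretical
maximum slightly.

CAI is the geometric mean of relative-adaptiveness weights w(c) =
RSCU(c)/RSCU_max(family), computed from a user-supplied highly-expressed
reference set; Met, Trp and stops are excluded as non-informative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import CODON_TABLE, STOP_CODONS, trim_terminal_stop

SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c, aa in CODON_TABLE.items() if aa != "*")
)

# synonymous families of the standard code, keyed by amino acid
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TABLE.items():
    if _aa != "*":
        FAMILIES.setdefault(_aa, ())
FAMILIES = {
    aa: tuple(sorted(c for c, a in CODON_TABLE.items() if a == aa and a != "*"))
    for aa in FAMILIES
}

# redundancy classes used by the Nc composition: {family size: (count, weight)}
_NC_CLASS_WEIGHT = {2: 9, 3: 1, 4: 5, 6: 3}

SINGLE_CODON_AAS = frozenset(
    aa for aa, fam in FAMILIES.items() if len(fam) == 1
)  # Met, Trp


@dataclass
class CodonCounts:
    counts: dict[str, int] = field(default_factory=dict)
    n_stop_internal: int = 0
    n_ambiguous: int = 0

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())

    @property
    def has_internal_stop(self) -> bool:
        return self.n_stop_internal > 0


@dataclass
class CodonMetrics:
    gene: str
    nc: float | None
    gc3: float | None
    cai: float | None
    rscu: dict[str, float] = field(default_factory=dict)


def count_codons(cds: str) -> CodonCounts:
    """Count sense codons of a CDS (terminal stop trimmed on entry).

    Codons containing non-ACGT characters are excluded from counts;
    internal stop codons are tallied separately and flag the gene.
    """
    cds = trim_terminal_stop(cds.upper())
    if not cds:
        raise ValueError("empty CDS")
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    cc = CodonCounts()
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if any(b not in "ACGT" for b in codon):
            cc.n_ambiguous += 1
            continue
        if codon in STOP_CODONS:
            cc.n_stop_internal += 1
            continue
        cc.counts[codon] = cc.counts.get(codon, 0) + 1
    return cc


def gc3(counts: CodonCounts) -> float | None:
    """Fraction of counted sense codons whose third base is G or C."""
    total = counts.n_codons
    if total == 0:
        return None
    gc = sum(n for codon, n in counts.counts.items() if codon[2] in "GC")
    return gc / total


def nc(counts: CodonCounts) -> float | None:
    """Wright's effective number of codons, clamped to [20, 61].

    Families observed fewer than twice, or with non-positive homozygosity,
    are excluded from their redundancy-class mean; if an entire class has no
    usable family the estimate is undefined (None).
    """
    class_f: dict[int, list[float]] = {k: [] for k in _NC_CLASS_WEIGHT}
    for aa, fam in FAMILIES.items():
        k = len(fam)
        if k == 1:
            continue
        n = sum(counts.counts.get(c, 0) for c in fam)
        if n < 2:
            continue
        sum_p2 = sum((counts.counts.get(c, 0) / n) ** 2 for c in fam)
        f_hat = (n * sum_p2 - 1) / (n - 1)
        if f_hat <= 0:
            continue
        class_f[k].append(f_hat)
    total = 2.0  # Met + Trp
    for k, weight in _NC_CLASS_WEIGHT.items():
        vals = class_f[k]
        if not vals:
            return None
        total += weight / (sum(vals) / len(vals))
    return min(max(total, 20.0), 61.0)


def rscu(counts: CodonCounts) -> dict[str, float]:
    """Relative synonymous codon usage: observed / family mean.

    Codons of families never observed are absent from the result (RSCU
    undefined); observed families give zero-count codons RSCU 0.
    """
    out: dict[str, float] = {}
    for fam in FAMILIES.values():
        n = sum(counts.counts.get(c, 0) for c in fam)
        if n == 0:
            continue
        mean = n / len(fam)
        for c in fam:
            out[c] = counts.counts.get(c, 0) / mean
    return out


@dataclass
class ReferenceWeights:
    """Relative adaptiveness w(c) ∈ (0, 1] from a highly-expressed set."""

    w: dict[str, float]
    source: str = ""

    def __post_init__(self) -> None:
        for fam in FAMILIES.values():
            present = [self.w[c] for c in fam if c in self.w]
            if present and abs(max(present) - 1.0) > 1e-9:
                raise ValueError("each observed family must have max weight 1")


def reference_weights(
    reference_cds: Sequence[str], source: str = "", pseudocount: float = 0.5
) -> ReferenceWeights:
    """Pool codon counts over a reference CDS set and derive CAI weights.

    w(c) = RSCU(c) / max family RSCU; codons unobserved in the reference are
    smoothed to RSCU ``pseudocount`` (default 0.5, i.e. half the family-mean
    usage) before weighting, so CAI stays defined for genes that use them
    and the weights are invariant to duplicating the reference set.
    """
    if not reference_cds:
        raise ValueError("empty reference set")
    pooled: dict[str, int] = {}
    for cds in reference_cds:
        for codon, n in count_codons(cds).counts.items():
            pooled[codon] = pooled.get(codon, 0) + n
    w: dict[str, float] = {}
    for fam in FAMILIES.values():
        n = sum(pooled.get(c, 0) for c in fam)
        if n == 0:
            continue  # family absent from reference: weights undefined
        mean = n / len(fam)
        rscu_f = {
            c: (pooled.get(c, 0) / mean) if pooled.get(c, 0) else pseudocount
            for c in fam
        }
        mx = max(rscu_f.values())
        for c in fam:
            w[c] = rscu_f[c] / mx
    return ReferenceWeights(w=w, source=source)


def cai(counts: CodonCounts, weights: ReferenceWeights) -> float | None:
    """Codon Adaptation Index: geometric mean of w over sense codons,
    excluding Met, Trp (single-codon families) and any codon without a
    reference weight."""
    log_sum = 0.0
    n = 0
    for codon, count in counts.counts.items():
        if CODON_TABLE[codon] in SINGLE_CODON_AAS:
            continue
        wc = weights.w.get(codon)
        if wc is None:
            continue
        log_sum += count * math.log(wc)
        n += count
    if n == 0:
        return None
    return math.exp(log_sum / n)


def gene_metrics(
    gene: str, cds: str, weights: ReferenceWeights | None = None
) -> CodonMetrics:
    """All per-gene indices in one pass."""
    counts = count_codons(cds)
    return CodonMetrics(
        gene=gene,
        nc=nc(counts),
        gc3=gc3(counts),
        cai=cai(counts, weights) if weights is not None else None,
        rscu=rscu(counts),
    )


def write_metrics_tsv(
    rows: Iterable[tuple[str, str, str, CodonMetrics]], path
) -> None:
    """Rows of (gene, genome, class_label, metrics)."""

    def fmt(x: float | None) -> str:
        return "" if x is None else f"{x:.4f}"

    with open(path, "w") as fh:
        fh.write("gene\tgenome\tclass\tNc\tGC3\tCAI\n")
        for gene, genome, label, m in rows:
            fh.write(
                f"{gene}\t{genome}\t{label}\t{fmt(m.nc)}\t{fmt(m.gc3)}\t{fmt(m.cai)}\n"
            )
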