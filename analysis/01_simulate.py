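"""Generate the default synthetic five-genome data set.

Writes per-genome protein/CDS/gene FASTA, the gene-position table and the
truth table (copy class, family size, planted blocks, omega, AS counts)
under results/sim/.  Every downstream analysis script regenerates the same
data set from the same seed, so the files here are for inspection, not a
hand-off.
"""

import argparse
from pathlib import Path

from singlecopy.simulate import SimConfig, simulate, write_dataset


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/sim"))
    args = ap.parse_args()

    cfg = SimConfig(seed=args.seed)
    res = simulate(cfg)
    write_dataset(res, args.out)

    n_genes = sum(len(v) for v in res.genome_set.genomes.values())
    n_single = sum(t.is_single_copy for t in res.truth)
    n_singleton = sum(t.is_singleton for t in res.truth)
    n_shared = len({t.shared_cluster for t in res.truth if t.shared_cluster is not None})
    print(f"simulated {len(res.genome_set.genomes)} genomes, {n_genes} genes")
    print(f"  single copy (truth): {n_single}")
    print(f"  singletons  (truth): {n_singleton}")
    print(f"  shared 1:1 families: {n_shared}")
    print(f"  planted blocks: { {g: len(b) for g, b in res.truth_blocks.items()} }")
    print(f"wrote {args.out}/")


if __name__ == "__main__":
    main()
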