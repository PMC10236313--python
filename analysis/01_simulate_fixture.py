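#!/usr/bin/env python
"""Generate the default synthetic study: a miniature genome with planted
enhancers, decoys, eRNA loci, CTCF blocks, factor binding sites, promoter
H3K9me2 dynamics, and a two-condition expression matrix.

Writes the fixture (peaks, tagAlign libraries, gene tables, expression
matrix, ground-truth manifest) to results/fixture/.
"""

import argparse
from pathlib import Path

from enhancerkit.simulate import SimulationConfig, simulate_all, write_fixture

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", type=Path, default=ROOT / "results" / "fixture")
    args = parser.parse_args()

    cfg = SimulationConfig(seed=args.seed)
    fix = simulate_all(cfg)
    write_fixture(fix, args.out)

    enh = fix.truth.enhancer_rows()
    genes = fix.truth.gene_rows()
    print(f"fixture written to {args.out}")
    print(f"  chromosomes: {len(cfg.chromosome_lengths)} x "
          f"{cfg.chromosome_lengths[0]:,} bp")
    print(f"  genes: {len(genes)} ({genes.induced.sum()} planted inducible)")
    print(f"  p300 peaks: {len(enh)} "
          f"({int(enh.expected_qualified.sum())} expected to qualify, "
          f"{(~enh.expected_qualified.astype(bool)).sum()} decoys)")
    print(f"  eRNA loci: {(enh.erna_class == 'true').sum()} true, "
          f"{(enh.expected_erna_excluded != '').sum()} decoys")
    print(f"  tag libraries: {len(fix.chip_rna.tags)}")


if __name__ == "__main__":
    main()
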