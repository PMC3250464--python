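#!/usr/bin/env python
"""Simulate the study-scale cohort and write it as a file bundle.

Generates 60 diploid individuals over 12 risk-locus LD blocks (120 SNPs
total), probe-level expression with planted cis-effects at three genes,
gene annotations whose cis windows yield exactly 613 SNP-probe pairs, a
small motif library and cross-species alignments, then writes VCF /
TSV / GFF3 / BED / JASPAR / FASTA under results/fixture/.
"""

import sys
from pathlib import Path

from cll_eqtl import synthetic_data as synth

OUT = Path(__file__).resolve().parent.parent / "results" / "fixture"


def main(seed: int = 11) -> None:
    fx = synth.study_fixture(seed)
    pwms = synth.simulate_pwms(6, 8, seed=seed)
    alignments = []
    for i, gene in enumerate(fx.genes):
        alignments.append(
            synth.simulate_alignment(
                "mouse", gene.chromosome, 999_000, 42_000, identity=0.5,
                seed=seed * 100 + i,
                conserved_span=(900, 1400) if i % 2 == 0 else None,
            )
        )
    manifest = synth.write_fixture_bundle(
        fx.panel, fx.expression, fx.genes, pwms, alignments, OUT
    )
    fx.index_snps.to_csv(OUT / "index_snps.tsv", sep="\t", index=False)
    n_pairs = synth.study_pair_count(fx)
    print(f"cohort: {fx.panel.n_samples} individuals, {len(fx.panel.loci)} SNPs "
          f"in {len(fx.index_snps)} loci; {n_pairs} cis SNP-probe pairs")
    print(f"planted effect genes: {sorted(fx.planted_snps)}")
    print(f"wrote {len(manifest['files']) + 1} files to {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 11)
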