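#!/usr/bin/env python
"""Re-derive the published CLL/SLL eQTL table's FDR adjustment.

Takes the 21 reported SNP–gene associations (raw p-values printed at 3
significant figures), re-runs the Benjamini–Hochberg step-up against
the full test count m = 613, and compares with the printed adjusted
values; then re-counts unique significant SNPs at BH < 0.20.  Writes
the reconstructed table to results/published_reconstruction.tsv.
"""

from pathlib import Path

from cll_eqtl import experiments as ex
from cll_eqtl.pipeline import render_table2

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    recon = ex.published_table_reconstruction()
    table = recon["table"]
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "published_reconstruction.tsv", sep="\t", index=False,
                 float_format="%.6g")
    render_table2(
        table.assign(minor_allele=table["minor_allele"]),
        OUT / "published_reconstruction_display.tsv",
    )
    print(f"max |recomputed − printed| adjusted p: {recon['max_abs_error']:.4f}")
    print(f"unique significant SNPs at BH<0.20: {recon['unique_snps']} "
          f"(SP140: {recon['per_gene']['SP140']}, "
          f"DACT3/GNG8: {recon['dact3_gng8_unique']})")


if __name__ == "__main__":
    main()
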