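"""Readers and writers for the pipeline's file formats.

Genotypes: VCF 4.2 (via cyvcf2) or HapMap-style genotype text.
Expression: TSV, probe rows × sample columns.  Gene models: BED6 or
GFF3.  Motifs: JASPAR count-matrix text (via Bio.motifs).  Alignments:
aligned FASTA pairs (via Bio.SeqIO).  HapMap LD text is supported as an
optional precomputed r² source.

All coordinates are normalized to 1-based on read.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs

from .conservation import PairwiseAlignment
from .eqtl_core import ExpressionMatrix, GeneModel
from .genotype_ld import MISSING, GenotypePanel
from .tfbs_pwm import PWM

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file violates its declared format."""


# --------------------------------------------------------------------------
# VCF
# --------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##source=cll-eqtl
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write a panel as uncompressed VCF 4.2 with phased GT when available."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(_VCF_HEADER)
        contigs = list(dict.fromkeys(panel.loci["chrom"].astype(str)))
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        phased = panel.haplotypes is not None
        for j, locus in panel.loci.iterrows():
            calls = []
            for i in range(panel.n_samples):
                g = panel.genotypes[i, j]
                if g == MISSING:
                    calls.append(".|." if phased else "./.")
                elif phased:
                    a, b = panel.haplotypes[2 * i, j], panel.haplotypes[2 * i + 1, j]
                    calls.append(f"{a}|{b}")
                else:
                    calls.append({0: "0/0", 1: "0/1", 2: "1/1"}[int(g)])
            fh.write(
                f"{locus['chrom']}\t{locus['pos']}\t{locus['snp_id']}\t"
                f"{locus['ref']}\t{locus['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path: str | Path) -> GenotypePanel:
    """Read biallelic SNPs from VCF; keeps haplotypes if all calls are phased."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    n = len(sample_ids)
    loci_rows, geno_cols, hap_cols = [], [], []
    all_phased = True
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            logger.warning("skipping non-biallelic-SNP record at %s:%s", var.CHROM, var.POS)
            continue
        loci_rows.append(
            {
                "snp_id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "ref": var.REF,
                "alt": var.ALT[0],
            }
        )
        g = np.full(n, MISSING, dtype=np.int8)
        h = np.full(2 * n, MISSING, dtype=np.int8)
        for i, call in enumerate(var.genotypes):
            a, b, phased = call[0], call[1], bool(call[2])
            if a < 0 or b < 0:
                all_phased = False
                continue
            g[i] = a + b
            if phased:
                h[2 * i], h[2 * i + 1] = a, b
            else:
                all_phased = False
        geno_cols.append(g)
        hap_cols.append(h)
    if not loci_rows:
        raise FormatError(f"{path}: no biallelic SNP records")
    genotypes = np.stack(geno_cols, axis=1)
    haplotypes = np.stack(hap_cols, axis=1) if all_phased else None
    return GenotypePanel(
        sample_ids=sample_ids,
        loci=pd.DataFrame(loci_rows),
        genotypes=genotypes,
        haplotypes=haplotypes,
    )


# --------------------------------------------------------------------------
# HapMap-style text
# --------------------------------------------------------------------------

def read_hapmap_genotypes(path: str | Path) -> GenotypePanel:
    """HapMap genotype text: header ``rs# alleles chrom pos strand ...``
    then 11 metadata columns followed by per-sample two-letter genotypes
    ('NN' = missing).  Genotypes are unphased."""
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().split()
        if not header or header[0] not in ("rs#", "rs"):
            raise FormatError(f"{path}: not a HapMap genotype file")
        sample_ids = header[11:]
        if not sample_ids:
            raise FormatError(f"{path}: no sample columns")
        loci_rows, geno_cols = [], []
        for ln, line in enumerate(fh, start=2):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 11 + len(sample_ids):
                raise FormatError(f"{path}:{ln}: wrong column count")
            alleles = fields[1].split("/")
            if len(alleles) != 2:
                raise FormatError(f"{path}:{ln}: alleles must be 'X/Y'")
            ref, alt = alleles
            chrom = fields[2]
            g = np.full(len(sample_ids), MISSING, dtype=np.int8)
            for i, call in enumerate(fields[11:]):
                if call == "NN":
                    continue
                g[i] = sum(1 for c in call if c == alt)
                if any(c not in (ref, alt) for c in call):
                    raise FormatError(f"{path}:{ln}: genotype {call} off-allele")
            loci_rows.append(
                {"snp_id": fields[0], "chrom": chrom, "pos": int(fields[3]),
                 "ref": ref, "alt": alt}
            )
            geno_cols.append(g)
    return GenotypePanel(
        sample_ids=sample_ids,
        loci=pd.DataFrame(loci_rows),
        genotypes=np.stack(geno_cols, axis=1),
    )


def read_hapmap_ld(path: str | Path) -> pd.DataFrame:
    """HapMap LD text: pos1 pos2 pop snp1 snp2 dprime r2 lod."""
    df = pd.read_csv(
        path, sep=r"\s+", header=None,
        names=["pos1", "pos2", "pop", "snp_a", "snp_b", "dprime", "r2", "lod"],
    )
    if df["r2"].max() > 1.0 or df["r2"].min() < 0.0:
        raise FormatError(f"{path}: r2 outside [0, 1]")
    return df


# --------------------------------------------------------------------------
# Expression / probe map / index SNPs
# --------------------------------------------------------------------------

def write_expression_tsv(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="probe_id", float_format="%.10g")


def read_expression_tsv(path: str | Path, probe_map: dict[str, str] | None = None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty or df.shape[1] == 0:
        raise FormatError(f"{path}: empty expression matrix")
    return ExpressionMatrix(data=df, probe_to_gene=probe_map or {})


def write_probe_map(probe_to_gene: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(probe_to_gene.items()), columns=["probe_id", "gene_id"]
    ).to_csv(path, sep="\t", index=False)


def read_probe_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["probe_id", "gene_id"]:
        raise FormatError(f"{path}: expected columns probe_id, gene_id")
    return dict(zip(df["probe_id"], df["gene_id"]))


def read_index_snps(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "snp_id" not in df.columns:
        raise FormatError(f"{path}: expected a snp_id column")
    if "risk_allele" not in df.columns:
        df["risk_allele"] = None
    return df[["snp_id", "risk_allele"]]


# --------------------------------------------------------------------------
# Gene models: BED6 and GFF3
# --------------------------------------------------------------------------

def write_bed6(genes: Sequence[GeneModel], path: str | Path) -> None:
    """BED6: 0-based half-open [chromStart, chromEnd), name = gene_id."""
    with Path(path).open("w") as fh:
        for g in genes:
            lo, hi = min(g.tss, g.tes), max(g.tss, g.tes)
            fh.write(f"{g.chromosome}\t{lo - 1}\t{hi}\t{g.gene_id}\t0\t{g.strand}\n")


def read_bed6(path: str | Path, probe_map: dict[str, str] | None = None) -> list[GeneModel]:
    genes = []
    by_gene: dict[str, list[str]] = {}
    for probe, gene in (probe_map or {}).items():
        by_gene.setdefault(gene, []).append(probe)
    with Path(path).open() as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise FormatError(f"{path}:{ln}: BED6 needs 6 columns")
            chrom, start0, end, name, _score, strand = f[:6]
            start1, end1 = int(start0) + 1, int(end)
            tss, tes = (start1, end1) if strand.strip() == "+" else (end1, start1)
            genes.append(
                GeneModel(
                    gene_id=name, chromosome=chrom, strand=strand.strip(),
                    tss=tss, tes=tes,
                    probe_ids=tuple(sorted(by_gene.get(name, ()))),
                )
            )
    return genes


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            lo, hi = min(g.tss, g.tes), max(g.tss, g.tes)
            attrs = f"ID={g.gene_id}"
            if g.probe_ids:
                attrs += ";probes=" + ",".join(g.probe_ids)
            fh.write(
                f"{g.chromosome}\tcll-eqtl\tgene\t{lo}\t{hi}\t.\t{g.strand}\t.\t{attrs}\n"
            )


def read_gff3(path: str | Path, probe_map: dict[str, str] | None = None) -> list[GeneModel]:
    """Gene-type GFF3 records; probes from an ``probes=`` attribute or
    the supplied probe map."""
    by_gene: dict[str, list[str]] = {}
    for probe, gene in (probe_map or {}).items():
        by_gene.setdefault(gene, []).append(probe)
    genes = []
    with Path(path).open() as fh:
        for ln, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise FormatError(f"{path}:{ln}: GFF3 needs 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = f
            if ftype != "gene":
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.strip().split(";") if "=" in kv
            )
            gene_id = attr.get("ID")
            if gene_id is None:
                raise FormatError(f"{path}:{ln}: gene record lacks ID attribute")
            probes = (
                tuple(attr["probes"].split(","))
                if "probes" in attr
                else tuple(sorted(by_gene.get(gene_id, ())))
            )
            start1, end1 = int(start), int(end)
            tss, tes = (start1, end1) if strand == "+" else (end1, start1)
            genes.append(
                GeneModel(
                    gene_id=gene_id, chromosome=chrom, strand=strand,
                    tss=tss, tes=tes, probe_ids=probes,
                )
            )
    return genes


# --------------------------------------------------------------------------
# JASPAR motifs
# --------------------------------------------------------------------------

def write_jaspar(pwms: Sequence[PWM], path: str | Path) -> None:
    """JASPAR 2016-style: '>ID name' then 'A [ ... ]' rows."""
    with Path(path).open("w") as fh:
        for pwm in pwms:
            fh.write(f">{pwm.motif_id} {pwm.name}\n")
            for b, base in enumerate("ACGT"):
                vals = " ".join(f"{v:6.2f}" for v in pwm.counts[:, b])
                fh.write(f"{base} [ {vals} ]\n")


def read_jaspar(
    path: str | Path,
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25),
    pseudocount: float = 0.8,
) -> list[PWM]:
    with Path(path).open() as fh:
        records = bio_motifs.parse(fh, "jaspar")
        pwms = []
        for m in records:
            counts = np.array(
                [[m.counts[base][i] for base in "ACGT"] for i in range(m.length)],
                dtype=float,
            )
            pwms.append(
                PWM(
                    motif_id=m.matrix_id or m.name,
                    name=m.name or m.matrix_id,
                    counts=counts,
                    background=background,
                    pseudocount=pseudocount,
                )
            )
    if not pwms:
        raise FormatError(f"{path}: no motifs parsed")
    return pwms


# --------------------------------------------------------------------------
# Pairwise alignments as aligned FASTA
# --------------------------------------------------------------------------

def write_alignments_fasta(alignments: Sequence[PairwiseAlignment], path: str | Path) -> None:
    """Pairs of records; human header ``human|<chrom>|<start>|<tag>``,
    other header ``<species>|<tag>``."""
    with Path(path).open("w") as fh:
        for k, aln in enumerate(alignments):
            tag = f"aln{k + 1}"
            fh.write(f">human|{aln.chromosome}|{aln.start}|{tag}\n{aln.human}\n")
            fh.write(f">{aln.species}|{tag}\n{aln.other}\n")


def read_alignments_fasta(path: str | Path) -> list[PairwiseAlignment]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) % 2 != 0:
        raise FormatError(f"{path}: expected human/other record pairs")
    alignments = []
    for hum, oth in zip(records[0::2], records[1::2]):
        hfields = hum.id.split("|")
        if len(hfields) < 3 or hfields[0] != "human":
            raise FormatError(f"{path}: bad human header {hum.id!r}")
        species = oth.id.split("|")[0]
        alignments.append(
            PairwiseAlignment(
                species=species,
                chromosome=hfields[1],
                start=int(hfields[2]),
                human=str(hum.seq),
                other=str(oth.seq),
            )
        )
    return alignments


# --------------------------------------------------------------------------
# Published worked example
# --------------------------------------------------------------------------

def load_published_results() -> pd.DataFrame:
    """The 21 published CLL/SLL SNP–gene association records (gene, SNP,
    raw and BH-adjusted p at m=613, direction of expression change)."""
    path = Path(__file__).parent / "data" / "published_cll_eqtl.tsv"
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["gene_id"] = df["gene"]
    return df
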