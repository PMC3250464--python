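"""Synthetic HapMap-like panels with planted cis-effects.

Emulates the data substrate of the CLL/SLL risk-locus screen: 60
unrelated diploid individuals genotyped at biallelic SNPs organised in
LD blocks, a lymphoblastoid-style probe × sample expression matrix with
additive cis-effects and Gaussian noise, gene annotations anchoring cis
windows, a JASPAR-style motif library and pairwise cross-species
alignments.  Everything is reproducible from a single integer seed.

LD blocks use a founder-copy model: each haplotype draws one latent
uniform ``u`` per block and its founder allele at SNP i is
``1{u < freq_i}`` (maximal positive association across SNPs); each
allele is then independently resampled from Bernoulli(freq_i) with
probability ``mutation_rate``.  Marginal allele frequencies are exact;
with equal within-block frequencies the haplotype correlation between
two SNPs is (1 − mutation_rate)², i.e. r² = (1 − mutation_rate)⁴, so
``mutation_rate`` tunes within-block LD and 0 gives perfect copies.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .conservation import PairwiseAlignment
from .eqtl_core import ExpressionMatrix, GeneModel, build_pairs
from .genotype_ld import GenotypePanel
from .tfbs_pwm import PWM


@dataclass(frozen=True)
class BlockSpec:
    """One LD block: SNP count, per-SNP minor-allele frequencies,
    resampling rate controlling within-block LD, and strictly increasing
    1-based positions."""

    n_snps: int
    allele_freq: tuple[float, ...]
    mutation_rate: float
    positions: tuple[int, ...]
    chromosome: str = "1"

    def __post_init__(self) -> None:
        freqs = self.allele_freq
        if np.isscalar(freqs):
            freqs = (float(freqs),) * self.n_snps
        object.__setattr__(self, "allele_freq", tuple(float(f) for f in freqs))
        object.__setattr__(self, "positions", tuple(int(p) for p in self.positions))
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if len(self.allele_freq) != self.n_snps or len(self.positions) != self.n_snps:
            raise ValueError("allele_freq and positions must have n_snps entries")
        if any(not (0.0 < f < 1.0) for f in self.allele_freq):
            raise ValueError("allele_freq must lie strictly in (0, 1)")
        if not (0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("mutation_rate must lie in [0, 1]")
        if any(b <= a for a, b in zip(self.positions, self.positions[1:])):
            raise ValueError("positions must be strictly increasing")


@dataclass(frozen=True)
class EffectSpec:
    """Additive cis-effect: probe mean shifts by ``beta`` per copy of the
    coded (minor) allele of ``snp_id``, with residual sd ``sigma``."""

    snp_id: str
    probe_id: str
    beta: float
    baseline: float = 0.0
    sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


_BASES = np.array(list("ACGT"))


def simulate_panel(
    n_individuals: int,
    blocks: Sequence[BlockSpec],
    seed: int,
    snp_prefix: str = "snp",
) -> GenotypePanel:
    """Phased panel of ``n_individuals`` diploids over independent LD blocks."""
    if n_individuals < 2:
        raise ValueError("n_individuals must be >= 2")
    rng = np.random.default_rng(seed)
    n_hap = 2 * n_individuals
    hap_cols, loci_rows = [], []
    counter = 0
    for b, block in enumerate(blocks):
        freqs = np.array(block.allele_freq)
        u = rng.random(n_hap)[:, None]
        founder = (u < freqs[None, :]).astype(np.int8)
        resample = rng.random((n_hap, block.n_snps)) < block.mutation_rate
        fresh = (rng.random((n_hap, block.n_snps)) < freqs[None, :]).astype(np.int8)
        hap = np.where(resample, fresh, founder).astype(np.int8)
        hap_cols.append(hap)
        ref_alt = rng.permuted(
            np.tile(_BASES, (block.n_snps, 1)), axis=1
        )[:, :2]
        for i in range(block.n_snps):
            counter += 1
            loci_rows.append(
                {
                    "snp_id": f"{snp_prefix}{counter:04d}",
                    "chrom": block.chromosome,
                    "pos": block.positions[i],
                    "ref": ref_alt[i, 0],
                    "alt": ref_alt[i, 1],
                }
            )
    haplotypes = np.concatenate(hap_cols, axis=1)
    genotypes = haplotypes[0::2] + haplotypes[1::2]
    return GenotypePanel(
        sample_ids=[f"NA{i + 1:05d}" for i in range(n_individuals)],
        loci=pd.DataFrame(loci_rows),
        genotypes=genotypes,
        haplotypes=haplotypes,
    )


def simulate_expression(
    panel: GenotypePanel,
    probes: Sequence[str],
    effects: Sequence[EffectSpec],
    seed: int,
    baseline: float = 0.0,
    sigma: float = 1.0,
) -> ExpressionMatrix:
    """Probe × sample matrix: baseline + Σ beta·genotype + N(0, sigma²).

    Per-probe ``baseline``/``sigma`` from an :class:`EffectSpec` override
    the global defaults; probes without effects are pure noise around the
    global baseline.
    """
    probes = list(probes)
    probe_set = set(probes)
    snp_set = set(panel.snp_ids)
    for eff in effects:
        if eff.snp_id not in snp_set:
            raise KeyError(f"effect references unknown SNP {eff.snp_id}")
        if eff.probe_id not in probe_set:
            raise KeyError(f"effect references unknown probe {eff.probe_id}")
    rng = np.random.default_rng(seed)
    n = panel.n_samples
    base = np.full(len(probes), float(baseline))
    sd = np.full(len(probes), float(sigma))
    mean = np.zeros((len(probes), n))
    p_index = {p: i for i, p in enumerate(probes)}
    for eff in effects:
        i = p_index[eff.probe_id]
        base[i] = eff.baseline
        sd[i] = eff.sigma
        mean[i] += eff.beta * panel.genotype_vector(eff.snp_id)
    data = base[:, None] + mean + rng.standard_normal((len(probes), n)) * sd[:, None]
    return ExpressionMatrix(
        data=pd.DataFrame(data, index=probes, columns=panel.sample_ids)
    )


# --------------------------------------------------------------------------
# Study-scale fixture: 12 risk loci, 120 SNPs, 613 cis pairs, 60 samples
# --------------------------------------------------------------------------

# per-locus SNP counts (sum 120) and probe counts chosen so that, with each
# gene's cis window covering its whole block, sum(snps * probes) = 613
STUDY_SNPS_PER_LOCUS = (20, 16, 13, 10, 10, 10, 8, 8, 8, 6, 6, 5)
STUDY_PROBES_PER_LOCUS = (5, 5, 6, 5, 5, 5, 5, 5, 5, 5, 5, 5)
STUDY_N_INDIVIDUALS = 60


@dataclass
class StudyFixture:
    panel: GenotypePanel
    expression: ExpressionMatrix
    genes: list[GeneModel]
    index_snps: pd.DataFrame  # snp_id, risk_allele
    effects: list[EffectSpec]
    planted_snps: dict[str, list[str]]  # gene_id -> SNPs carrying true effects


def study_fixture(
    seed: int,
    mutation_rate: float = 0.0,
    beta: float = 0.8,
    sigma: float = 1.0,
    n_individuals: int = STUDY_N_INDIVIDUALS,
) -> StudyFixture:
    """Panel + expression emulating the study's scale and signal layout.

    120 SNPs in 12 single-gene loci (one locus carries two genes), 60
    individuals, and planted effects at three genes: a SP140-like gene
    whose minor risk-locus alleles lower expression (beta −``beta``) at
    16 SNPs, and a two-gene locus where 3 SNPs raise expression of a
    DACT3-like and a GNG8-like gene.  ``mutation_rate=0`` makes proxies
    perfect copies of their index SNP so the planted significant sets
    are deterministic by construction.
    """
    rng = np.random.default_rng(seed)
    freqs = rng.uniform(0.15, 0.45, size=len(STUDY_SNPS_PER_LOCUS))
    blocks, genes = [], []
    pos0 = 1_000_000
    for k, (n_snps, freq) in enumerate(zip(STUDY_SNPS_PER_LOCUS, freqs)):
        positions = tuple(pos0 + 2_000 * i for i in range(n_snps))
        blocks.append(
            BlockSpec(
                n_snps=n_snps,
                allele_freq=(float(freq),) * n_snps,
                mutation_rate=mutation_rate,
                positions=positions,
                chromosome=f"chr{k + 1}",
            )
        )
    panel = simulate_panel(n_individuals, blocks, seed=seed)

    # genes: window [tss-300k, tes+100k] covers the whole block
    probes: list[str] = []
    probe_to_gene: dict[str, str] = {}
    offset = 0
    locus_snps: list[list[str]] = []
    for k, (n_snps, n_probes) in enumerate(
        zip(STUDY_SNPS_PER_LOCUS, STUDY_PROBES_PER_LOCUS)
    ):
        snp_ids = panel.snp_ids[offset : offset + n_snps]
        locus_snps.append(snp_ids)
        offset += n_snps
        lo = 1_000_000
        hi = 1_000_000 + 2_000 * (n_snps - 1)
        if k == 2:  # two genes share this locus (GNG8/DACT3-like)
            gene_specs = [("geneC1", 3), ("geneC2", 3)]
        else:
            gene_specs = [(f"gene{k + 1:02d}", n_probes)]
        for gene_id, np_g in gene_specs:
            pids = tuple(f"{gene_id}_p{j + 1}" for j in range(np_g))
            probes.extend(pids)
            probe_to_gene.update({p: gene_id for p in pids})
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    chromosome=f"chr{k + 1}",
                    strand="+" if k % 2 == 0 else "-",
                    tss=hi + 50_000 if k % 2 else lo + 50_000,
                    tes=lo + 50_000 if k % 2 else hi + 50_000,
                    probe_ids=pids,
                )
            )

    # planted signal: locus 2 (16 SNPs) lowers gene02 expression;
    # locus 3 (first 3 SNPs) raises both shared-locus genes
    effects: list[EffectSpec] = []
    planted: dict[str, list[str]] = {}
    sp140_like = locus_snps[1]
    g2_probe = "gene02_p1"
    effects.append(EffectSpec(sp140_like[0], g2_probe, beta=-beta, sigma=sigma))
    planted["gene02"] = list(sp140_like)
    up_snps = locus_snps[2]
    effects.append(EffectSpec(up_snps[0], "geneC1_p1", beta=beta, sigma=sigma))
    effects.append(EffectSpec(up_snps[0], "geneC2_p1", beta=beta, sigma=sigma))
    # with mutation_rate=0 every block SNP is a perfect proxy of the
    # effect SNP, so the whole block carries the planted association
    planted["geneC1"] = list(up_snps)
    planted["geneC2"] = list(up_snps)

    expr = simulate_expression(
        panel, probes, effects, seed=seed + 1, baseline=5.0, sigma=sigma
    )
    expr.probe_to_gene = probe_to_gene
    index_snps = pd.DataFrame(
        {
            "snp_id": [snps[0] for snps in locus_snps],
            "risk_allele": [
                str(panel.locus(snps[0])["alt"]) for snps in locus_snps
            ],
        }
    )
    return StudyFixture(panel, expr, genes, index_snps, effects, planted)


def study_pair_count(fixture: StudyFixture) -> int:
    """Number of cis SNP-probe pairs implied by the fixture geometry."""
    return len(build_pairs(fixture.panel.loci, fixture.genes))


# --------------------------------------------------------------------------
# Motifs and alignments
# --------------------------------------------------------------------------


def simulate_pwms(n_motifs: int, length: int, seed: int, concentration: float = 0.3) -> list[PWM]:
    """Random motif library with peaked columns (Dirichlet counts)."""
    rng = np.random.default_rng(seed)
    pwms = []
    for k in range(n_motifs):
        probs = rng.dirichlet([concentration] * 4, size=length)
        counts = np.round(probs * 100).astype(float)
        counts[counts.sum(axis=1) == 0, :] = 1.0
        pwms.append(PWM(motif_id=f"M{k + 1:03d}", name=f"motif{k + 1}", counts=counts))
    return pwms


def simulate_alignment(
    species: str,
    chrom: str,
    start: int,
    length: int,
    identity: float,
    seed: int,
    conserved_span: tuple[int, int] | None = None,
    conserved_identity: float = 1.0,
) -> PairwiseAlignment:
    """Ungapped pairwise alignment with per-column match probability
    ``identity``, optionally boosted to ``conserved_identity`` on the
    0-based column span ``conserved_span`` (half-open)."""
    rng = np.random.default_rng(seed)
    human = rng.choice(_BASES, size=length)
    p_match = np.full(length, identity)
    if conserved_span is not None:
        a, b = conserved_span
        p_match[a:b] = conserved_identity
    match = rng.random(length) < p_match
    other = human.copy()
    for i in np.flatnonzero(~match):
        choices = [b for b in "ACGT" if b != human[i]]
        other[i] = choices[rng.integers(3)]
    return PairwiseAlignment(
        species=species,
        chromosome=chrom,
        start=start,
        human="".join(human),
        other="".join(other),
    )


# --------------------------------------------------------------------------
# Fixture bundle writer (delegates format writing to cll_eqtl.io)
# --------------------------------------------------------------------------


def write_fixture_bundle(
    panel: GenotypePanel,
    expression: ExpressionMatrix,
    gene_models: Sequence[GeneModel],
    pwms: Sequence[PWM],
    alignments: Sequence[PairwiseAlignment],
    out_dir: str | Path,
) -> dict:
    """Write VCF/TSV/BED/GFF3/JASPAR/FASTA files plus a checksum manifest.

    Files round-trip through the package readers at the data-model
    level; the manifest records a sha256 per file so identical inputs
    produce identical bundles.
    """
    from . import io as _io

    if panel.n_samples == 0 or len(panel.loci) == 0:
        raise ValueError("refusing to write an empty panel")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "genotypes.vcf": lambda p: _io.write_vcf(panel, p),
        "expression.tsv": lambda p: _io.write_expression_tsv(expression, p),
        "genes.bed": lambda p: _io.write_bed6(gene_models, p),
        "genes.gff3": lambda p: _io.write_gff3(gene_models, p),
        "probe_map.tsv": lambda p: _io.write_probe_map(expression.probe_to_gene, p),
        "pwms.jaspar": lambda p: _io.write_jaspar(pwms, p),
        "alignments.fasta": lambda p: _io.write_alignments_fasta(alignments, p),
    }
    manifest: dict = {"files": {}}
    for name, writer in files.items():
        path = out / name
        writer(path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        manifest["files"][name] = {"sha256": digest, "bytes": path.stat().st_size}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
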