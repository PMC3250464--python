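"""End-to-end orchestration: proxies → pairs → regression → BH →
significance → risk alleles → TFBS screen → conservation filter.

A :class:`RunConfig` points at the input files and carries every tunable
threshold.  :func:`run_pipeline` executes the stages in order, writes
each stage's table under the output directory, and returns a
:class:`RunReport` whose counts are all re-derivable from the persisted
tables.  Reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, conservation as cons, eqtl_core, genotype_ld as gl, io as _io
from . import tfbs_pwm

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    genotypes: str = ""
    genotype_format: str = "vcf"  # vcf | hapmap
    expression: str = ""
    genes: str = ""
    gene_format: str = "gff3"  # gff3 | bed
    probe_map: str = ""
    index_snps: str = ""
    pwms: str = ""
    alignments: str = ""
    out_dir: str = "results"
    r2_min: float = 0.8
    max_distance_bp: int = 500_000
    cis_upstream: int = 300_000
    cis_downstream: int = 100_000
    fdr_threshold: float = 0.20
    tfbs_alpha: float = 0.05
    tfbs_n_null: int = 10_000
    tfbs_flank: int = 12
    ecr_min_len: int = 100
    ecr_min_identity: float = 0.70
    flank: int = 100
    seed: int = 0
    strand_aware: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.r2_min <= 1):
            raise ValueError("r2_min must lie in [0, 1]")
        if not (0 < self.fdr_threshold <= 1) or not (0 < self.tfbs_alpha <= 1):
            raise ValueError("FDR thresholds must lie in (0, 1]")
        if not (0 < self.ecr_min_identity <= 1):
            raise ValueError("ecr_min_identity must lie in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class LoadedInputs:
    panel: gl.GenotypePanel
    expression: eqtl_core.ExpressionMatrix
    genes: list[eqtl_core.GeneModel]
    index_snps: pd.DataFrame
    pwms: list[tfbs_pwm.PWM]
    alignments: list[cons.PairwiseAlignment]


@dataclass
class RunReport:
    counts: dict = field(default_factory=dict)
    eqtl_results: pd.DataFrame | None = None
    significant: pd.DataFrame | None = None
    tfbs_results: pd.DataFrame | None = None
    conservation_calls: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def load_inputs(config: RunConfig) -> LoadedInputs:
    """Read and cross-validate every configured input file."""
    if config.genotype_format == "vcf":
        panel = _io.read_vcf(config.genotypes)
    elif config.genotype_format == "hapmap":
        panel = _io.read_hapmap_genotypes(config.genotypes)
    else:
        raise ValueError(f"unknown genotype format {config.genotype_format!r}")
    probe_map = _io.read_probe_map(config.probe_map) if config.probe_map else {}
    expression = _io.read_expression_tsv(config.expression, probe_map)
    missing_samples = [s for s in expression.sample_ids if s not in set(panel.sample_ids)]
    if missing_samples:
        raise ValueError(
            "expression samples absent from genotype panel: " + ", ".join(missing_samples)
        )
    reader = _io.read_gff3 if config.gene_format == "gff3" else _io.read_bed6
    genes = reader(config.genes, probe_map)
    index_snps = _io.read_index_snps(config.index_snps)
    unknown = [s for s in index_snps["snp_id"] if s not in set(panel.snp_ids)]
    if unknown:
        raise ValueError("index SNPs absent from panel: " + ", ".join(unknown))
    pwms = _io.read_jaspar(config.pwms) if config.pwms else []
    alignments = (
        _io.read_alignments_fasta(config.alignments) if config.alignments else []
    )
    return LoadedInputs(panel, expression, genes, index_snps, pwms, alignments)


def expand_proxies(
    panel: gl.GenotypePanel, index_snps: pd.DataFrame, config: RunConfig
) -> pd.DataFrame:
    """LD-expand every index SNP; one row per retained (index, proxy)."""
    rows = []
    for row in index_snps.itertuples(index=False):
        for ld in gl.find_proxies(
            panel, row.snp_id, r2_min=config.r2_min,
            max_distance_bp=config.max_distance_bp,
        ):
            risk = getattr(row, "risk_allele", None)
            if risk:
                match = gl.match_risk_allele(panel, row.snp_id, risk, ld.snp_b)
                risk_allele = match.proxy_allele
            else:
                risk_allele = None
            rows.append(
                {
                    "index_snp": row.snp_id,
                    "snp_id": ld.snp_b,
                    "r2_with_index": ld.r2,
                    "risk_allele": risk_allele,
                }
            )
    df = pd.DataFrame(rows, columns=["index_snp", "snp_id", "r2_with_index", "risk_allele"])
    return df.drop_duplicates(subset="snp_id", keep="first").reset_index(drop=True)


def _sequence_context(
    panel: gl.GenotypePanel, snp_id: str, flank: int, rng: np.random.Generator
) -> tfbs_pwm.AlleleContext:
    """Background-sampled flanks around the SNP's two alleles.

    Real runs would cut flanks from a reference FASTA; without one the
    flanks are drawn from the uniform background, which preserves the
    null behaviour of the screen (documented synthetic stand-in).
    """
    locus = panel.locus(snp_id)
    bases = np.array(list("ACGT"))
    left = "".join(rng.choice(bases, size=flank))
    right = "".join(rng.choice(bases, size=flank))
    return tfbs_pwm.AlleleContext(
        snp_id=snp_id,
        flank_left=left,
        flank_right=right,
        allele_a=str(locus["ref"]),
        allele_b=str(locus["alt"]),
    )


def run_pipeline(config: RunConfig, inputs: LoadedInputs | None = None) -> RunReport:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if inputs is None:
        inputs = load_inputs(config)
    panel, expression = inputs.panel, inputs.expression

    logger.info("index SNPs: %d", len(inputs.index_snps))
    proxies = expand_proxies(panel, inputs.index_snps, config)
    logger.info("LD-expanded SNPs (r2 >= %.2f): %d", config.r2_min, len(proxies))
    proxies.to_csv(out / "proxies.tsv", sep="\t", index=False)

    proxy_loci = panel.loci[panel.loci["snp_id"].isin(set(proxies["snp_id"]))]
    pairs = eqtl_core.build_pairs(
        proxy_loci, inputs.genes,
        upstream_bp=config.cis_upstream, downstream_bp=config.cis_downstream,
        strand_aware=config.strand_aware,
    )
    logger.info("SNP-probe pairs in cis windows: %d", len(pairs))

    results = eqtl_core.run_pair_tests(
        panel, expression, pairs, fdr_threshold=config.fdr_threshold
    )
    if not results.empty:
        r2_map = dict(zip(proxies["snp_id"], proxies["r2_with_index"]))
        risk_map = dict(zip(proxies["snp_id"], proxies["risk_allele"]))
        results["r2_with_index"] = results["snp_id"].map(r2_map)
        results["risk_or_minor_allele"] = [
            risk_map.get(s) or m
            for s, m in zip(results["snp_id"], results["minor_allele"])
        ]
    results.to_csv(out / "eqtl_results.tsv", sep="\t", index=False, float_format="%.10g")

    sig, summary = eqtl_core.call_significant(results, config.fdr_threshold)
    sig.to_csv(out / "significant.tsv", sep="\t", index=False, float_format="%.10g")
    render_table2(sig, out / "table_significant.tsv")

    sig_snps = (
        sig.drop_duplicates(subset="snp_id")[["snp_id", "chrom", "pos"]]
        if not sig.empty
        else pd.DataFrame(columns=["snp_id", "chrom", "pos"])
    )

    # TFBS screen on significant SNPs
    tfbs_df = pd.DataFrame()
    if inputs.pwms and not sig_snps.empty:
        rng = np.random.default_rng(config.seed)
        contexts = [
            _sequence_context(panel, s, config.tfbs_flank, rng)
            for s in sig_snps["snp_id"]
        ]
        tfbs_df = tfbs_pwm.screen_library(
            contexts, inputs.pwms, alpha=config.tfbs_alpha,
            n_null=config.tfbs_n_null, seed=config.seed,
        )
    tfbs_df.to_csv(out / "tfbs_results.tsv", sep="\t", index=False, float_format="%.10g")

    # conservation filter on significant SNPs
    calls = []
    for row in sig_snps.itertuples(index=False):
        calls.append(
            cons.snp_in_conserved_region(
                row.snp_id, str(row.chrom), int(row.pos), inputs.alignments,
                flank=config.flank, min_len=config.ecr_min_len,
                min_identity=config.ecr_min_identity,
            )
        )
    cons_df = pd.DataFrame(
        [
            {
                "snp_id": c.snp_id,
                "status": c.status,
                "species": ",".join(c.species),
                "best_identity": c.best_identity,
                "best_interval": "" if c.best_interval is None else f"{c.best_interval[0]}-{c.best_interval[1]}",
            }
            for c in calls
        ],
        columns=["snp_id", "status", "species", "best_identity", "best_interval"],
    )
    cons_df.to_csv(out / "conservation.tsv", sep="\t", index=False, float_format="%.6g")

    n_conserved = sum(c.conserved for c in calls)
    counts = {
        "index_snps": int(len(inputs.index_snps)),
        "proxies": int(len(proxies)),
        "pairs_built": int(len(pairs)),
        "pairs_tested": int(len(results)),
        "significant_pairs": int(len(sig)),
        "unique_significant_snps": summary["unique_snps"],
        "per_gene_unique_snps": summary["per_gene"],
        "conserved_significant_snps": int(n_conserved),
        "conserved_percent": cons.conserved_fraction(calls) if calls else float("nan"),
        "tfbs_predicted": int(tfbs_df["predicted"].sum()) if not tfbs_df.empty else 0,
    }
    report = RunReport(
        counts=counts,
        eqtl_results=results,
        significant=sig,
        tfbs_results=tfbs_df,
        conservation_calls=calls,
        provenance={
            "config": dataclasses.asdict(config),
            "seed": config.seed,
            "version": __version__,
        },
    )
    payload = {"counts": counts, "provenance": report.provenance}
    (out / "report.json").write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default))
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


_ARROW = {"up": "↑", "down": "↓", "undirected": "-"}


def render_table2(results: pd.DataFrame, path: str | Path | None = None) -> pd.DataFrame:
    """Significant-association table in the published layout.

    Raw p to 3 significant figures, BH p to 3 decimals, direction as an
    arrow; rows sorted by gene then SNP id.  Full-precision values stay
    in the machine-readable results TSV.
    """
    cols = [
        "gene", "snp_id", "r2_with_index", "chrom", "pos",
        "risk_or_minor_allele", "raw_p", "adjusted_p_bh", "expression",
    ]
    if results.empty:
        table = pd.DataFrame(columns=cols)
    else:
        df = results.sort_values(["gene_id", "snp_id"]).reset_index(drop=True)
        table = pd.DataFrame(
            {
                "gene": df["gene_id"],
                "snp_id": df["snp_id"],
                "r2_with_index": [
                    "-" if pd.isna(v) else f"{v:.2g}"
                    for v in pd.to_numeric(
                        df.get("r2_with_index", pd.Series([np.nan] * len(df))),
                        errors="coerce",
                    )
                ],
                "chrom": df["chrom"],
                "pos": df["pos"],
                "risk_or_minor_allele": df.get("risk_or_minor_allele", df.get("minor_allele")),
                "raw_p": [f"{p:.2E}" for p in df["raw_p"]],
                "adjusted_p_bh": [f"{p:.3f}" for p in df["adjusted_p"]],
                "expression": [_ARROW[d] for d in df["direction"]],
            }
        )
    if path is not None:
        table.to_csv(path, sep="\t", index=False)
    return table
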