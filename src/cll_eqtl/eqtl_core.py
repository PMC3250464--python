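"""Cis-eQTL testing: window construction, additive regression, BH-FDR.

The association model is the standard additive cis-eQTL regression: for
each SNP–probe pair, expression is regressed on the number of copies of
the coded (minor) allele (0, 1 or 2) by ordinary least squares, with a
two-sided p-value from the t distribution on n−2 degrees of freedom.
Raw p-values across all testable pairs are adjusted with the
Benjamini–Hochberg step-up procedure; pairs are called significant at an
adjusted p below the configured false-discovery threshold (0.20 by
default).

A gene's cis window runs from ``upstream_bp`` (default 300 kb) upstream
of the transcription start site to ``downstream_bp`` (default 100 kb)
downstream of the transcription end site, oriented by strand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneModel:
    """Gene anchor for the cis window.

    ``tss``/``tes`` are 1-based transcription start/end in transcription
    direction: tss ≤ tes on the + strand, tss ≥ tes on the − strand.
    """

    gene_id: str
    chromosome: str
    strand: str
    tss: int
    tes: int
    probe_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.strand == "+" and self.tss > self.tes:
            raise ValueError(f"{self.gene_id}: + strand requires tss <= tes")
        if self.strand == "-" and self.tss < self.tes:
            raise ValueError(f"{self.gene_id}: - strand requires tss >= tes")
        object.__setattr__(self, "probe_ids", tuple(self.probe_ids))


@dataclass(frozen=True)
class CisWindow:
    chromosome: str
    start_bp: int
    end_bp: int

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("cis window start after end")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chromosome and self.start_bp <= pos <= self.end_bp


@dataclass
class ExpressionMatrix:
    """Probe × sample continuous expression with a probe→gene map."""

    data: pd.DataFrame  # index = probe ids, columns = sample ids
    probe_to_gene: dict[str, str] = field(default_factory=dict)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def values_for(self, probe_id: str, sample_ids: Sequence[str]) -> np.ndarray:
        return self.data.loc[probe_id, list(sample_ids)].to_numpy(dtype=float)


class RegressionResult(NamedTuple):
    slope: float
    intercept: float
    standard_error: float
    t_statistic: float
    raw_p: float
    n_used: int


class UntestablePair(ValueError):
    """Pair has no defined test (too few samples or zero genotype variance)."""


def cis_window(
    gene: GeneModel,
    upstream_bp: int = 300_000,
    downstream_bp: int = 100_000,
    strand_aware: bool = True,
) -> CisWindow:
    """Closed 1-based interval around a gene, clipped at position 1.

    Strand-aware (default): upstream extends from the TSS against the
    direction of transcription, downstream from the TES along it.  With
    ``strand_aware=False`` the − strand is treated like +, extending
    ``upstream_bp`` left of min(tss, tes).
    """
    lo, hi = min(gene.tss, gene.tes), max(gene.tss, gene.tes)
    if gene.strand == "+" or not strand_aware:
        start, end = lo - upstream_bp, hi + downstream_bp
    else:
        start, end = lo - downstream_bp, hi + upstream_bp
    return CisWindow(gene.chromosome, max(1, start), end)


def build_pairs(
    snps: pd.DataFrame,
    genes: Iterable[GeneModel],
    upstream_bp: int = 300_000,
    downstream_bp: int = 100_000,
    strand_aware: bool = True,
) -> pd.DataFrame:
    """All (SNP, probe) pairs where the SNP lies in the gene's cis window.

    ``snps`` needs columns ``snp_id, chrom, pos``.  Boundaries are
    inclusive.  Output columns: snp_id, probe_id, gene_id; rows ordered
    by (chromosome, position, probe_id).
    """
    rows = []
    for gene in genes:
        if not gene.probe_ids:
            logger.warning("gene %s has no probes; contributes no pairs", gene.gene_id)
            continue
        win = cis_window(gene, upstream_bp, downstream_bp, strand_aware)
        sel = snps[
            (snps["chrom"].astype(str) == win.chromosome)
            & (snps["pos"] >= win.start_bp)
            & (snps["pos"] <= win.end_bp)
        ]
        for _, snp in sel.iterrows():
            for probe_id in gene.probe_ids:
                rows.append(
                    (str(snp["chrom"]), int(snp["pos"]), snp["snp_id"], probe_id, gene.gene_id)
                )
    rows.sort(key=lambda r: (r[0], r[1], r[3]))
    return pd.DataFrame(
        [(r[2], r[3], r[4]) for r in rows], columns=["snp_id", "probe_id", "gene_id"]
    )


def additive_regression(
    genotype_codes: np.ndarray, expression: np.ndarray
) -> RegressionResult:
    """OLS of expression on minor-allele count with pairwise-complete data.

    Raises :class:`UntestablePair` when fewer than 3 complete pairs
    remain or the genotype has zero variance after dropping.
    """
    g = np.asarray(genotype_codes, dtype=float)
    y = np.asarray(expression, dtype=float)
    if g.shape != y.shape:
        raise ValueError("genotype and expression vectors differ in length")
    keep = ~(np.isnan(g) | np.isnan(y))
    g, y = g[keep], y[keep]
    n = g.size
    if n < 3:
        raise UntestablePair(f"only {n} complete observations")
    if np.ptp(g) == 0:
        raise UntestablePair("zero genotype variance")
    if np.ptp(y) == 0:  # flat response: defined, null fit
        return RegressionResult(0.0, float(y[0]), 0.0, 0.0, 1.0, int(n))
    fit = stats.linregress(g, y)
    raw_p = float(fit.pvalue)
    raw_p = min(max(raw_p, np.finfo(float).tiny), 1.0)
    se = float(fit.stderr)
    t = float(fit.slope / se) if se > 0 else 0.0
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        standard_error=se,
        t_statistic=t,
        raw_p=raw_p,
        n_used=int(n),
    )


def regress_many(G: np.ndarray, Y: np.ndarray) -> dict[str, np.ndarray]:
    """Row-wise simple OLS of Y on G (both m × n, complete data).

    Closed-form slopes, standard errors, t statistics and two-sided
    p-values with n−2 degrees of freedom; used for simulation-scale
    calibration checks.  Agrees with :func:`additive_regression` row by
    row (see tests).  Rows with zero genotype variance get NaN.
    """
    G = np.asarray(G, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if G.shape != Y.shape or G.ndim != 2:
        raise ValueError("G and Y must be matching 2-D arrays")
    m, n = G.shape
    if n < 3:
        raise ValueError("need at least 3 observations per row")
    gc = G - G.mean(axis=1, keepdims=True)
    yc = Y - Y.mean(axis=1, keepdims=True)
    sxx = (gc**2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = (gc * yc).sum(axis=1) / sxx
        resid = yc - slope[:, None] * gc
        sigma2 = (resid**2).sum(axis=1) / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        t = slope / se
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    bad = sxx == 0
    for arr in (slope, se, t, p):
        arr[bad] = np.nan
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return {"slope": slope, "standard_error": se, "t_statistic": t, "raw_p": p}


def bh_adjust(raw_p: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values.

    ``m`` is the total number of tests the correction is run against and
    defaults to ``len(raw_p)``; it may exceed the vector length, which
    adjusts a reported subset against the full test count.  Sorting the
    p-values ascending, adjusted_(i) = min_{j ≥ i} min(1, m p_(j) / j),
    mapped back to input order.
    """
    p = np.asarray(list(raw_p), dtype=float)
    if p.size and (np.any(p <= 0) | np.any(p > 1) | np.any(np.isnan(p))):
        raise ValueError("raw p-values must lie in (0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m={m} smaller than number of p-values ({p.size})")
    if p.size == 0:
        return np.empty(0)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adj = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    out = np.empty_like(adj)
    out[order] = adj
    return out


def effect_direction(slope: float) -> str:
    """'up' / 'down' per copy of the coded allele; exact zero → 'undirected'."""
    if slope > 0:
        return "up"
    if slope < 0:
        return "down"
    return "undirected"


def run_pair_tests(
    panel,
    expression: ExpressionMatrix,
    pairs: pd.DataFrame,
    genes: dict[str, GeneModel] | None = None,
    m: int | None = None,
    fdr_threshold: float = 0.20,
) -> pd.DataFrame:
    """Regress every pair, BH-adjust across testable pairs, flag calls.

    Genotypes are recoded to minor-allele counts per SNP before
    regression (2 − coded count when the ALT allele is the major one).
    Pairs excluded for zero variance or insufficient data do not enter
    the multiplicity count unless ``m`` overrides it.
    """
    from . import genotype_ld as gl

    sample_ids = [s for s in panel.sample_ids if s in set(expression.sample_ids)]
    if len(sample_ids) < 3:
        raise ValueError("fewer than 3 samples shared between panel and expression")
    sample_idx = [panel.sample_ids.index(s) for s in sample_ids]
    records = []
    for row in pairs.itertuples(index=False):
        snp_id, probe_id = row.snp_id, row.probe_id
        gene_id = getattr(row, "gene_id", expression.probe_to_gene.get(probe_id, ""))
        ma = gl.minor_allele(panel, snp_id)
        if ma.monomorphic:
            logger.warning("pair (%s, %s) excluded: monomorphic", snp_id, probe_id)
            continue
        g = panel.genotype_vector(snp_id)[sample_idx]
        locus = panel.locus(snp_id)
        if ma.allele == str(locus["ref"]):  # minor is REF: flip coding
            g = 2.0 - g
        y = expression.values_for(probe_id, sample_ids)
        try:
            fit = additive_regression(g, y)
        except UntestablePair as exc:
            logger.warning("pair (%s, %s) excluded: %s", snp_id, probe_id, exc)
            continue
        records.append(
            {
                "snp_id": snp_id,
                "probe_id": probe_id,
                "gene_id": gene_id,
                "chrom": str(locus["chrom"]),
                "pos": int(locus["pos"]),
                "minor_allele": ma.allele,
                "maf": ma.frequency,
                "n_used": fit.n_used,
                "slope": fit.slope,
                "standard_error": fit.standard_error,
                "t_statistic": fit.t_statistic,
                "raw_p": fit.raw_p,
                "direction": effect_direction(fit.slope),
            }
        )
    results = pd.DataFrame(records)
    if results.empty:
        results["adjusted_p"] = []
        results["significant"] = []
        return results
    results["adjusted_p"] = bh_adjust(results["raw_p"].to_numpy(), m=m)
    results["significant"] = results["adjusted_p"] < fdr_threshold
    return results


def call_significant(
    results: pd.DataFrame, fdr_threshold: float = 0.20
) -> tuple[pd.DataFrame, dict]:
    """Rows below the FDR threshold plus unique-SNP summary counts.

    A SNP significant for several genes counts once in the overall
    unique tally but appears in each per-gene count.
    """
    if results.empty:
        return results.copy(), {"unique_snps": 0, "per_gene": {}}
    sig = results[results["adjusted_p"] < fdr_threshold].copy()
    per_gene = {
        gene: int(sub["snp_id"].nunique())
        for gene, sub in sig.groupby("gene_id", sort=True)
    }
    summary = {"unique_snps": int(sig["snp_id"].nunique()), "per_gene": per_gene}
    return sig, summary
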