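"""Genotype panels and pairwise linkage disequilibrium.

A :class:`GenotypePanel` holds biallelic loci for a sample of diploid
individuals, optionally with phased haplotypes.  Genotype codes count
copies of the *coded* allele (the ALT allele of each locus); the sample
minor allele is recomputed from the data by :func:`minor_allele`.

LD between two loci is summarised by the two-locus haplotype frequencies
(p_AB, p_Ab, p_aB, p_ab), the disequilibrium coefficient
D = p_AB - p_A * p_B and r² = D² / (p_A(1-p_A) p_B(1-p_B)).  Haplotype
frequencies come either from direct counting of phased haplotypes or,
for unphased genotypes, from an EM maximum-likelihood estimate that
iterates over the phase of double heterozygotes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1  # genotype sentinel

LOCUS_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt"]


class PanelError(ValueError):
    """Raised for malformed or inconsistent panel data."""


@dataclass
class GenotypePanel:
    """Samples × biallelic loci with 0/1/2 coded-allele counts.

    Parameters
    ----------
    sample_ids :
        Identifiers of the diploid individuals (length n).
    loci :
        DataFrame with columns ``snp_id, chrom, pos, ref, alt`` (1-based
        positions).  Row order defines locus order.
    genotypes :
        (n × L) int8 matrix counting copies of the ALT allele;
        ``MISSING`` (-1) marks a missing call.
    haplotypes :
        Optional (2n × L) phased 0/1 matrix; haplotypes ``2i`` and
        ``2i+1`` belong to individual ``i``.
    """

    sample_ids: list[str]
    loci: pd.DataFrame
    genotypes: np.ndarray
    haplotypes: np.ndarray | None = None
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.loci = self.loci.reset_index(drop=True)
        missing_cols = set(LOCUS_COLUMNS) - set(self.loci.columns)
        if missing_cols:
            raise PanelError(f"loci table lacks columns: {sorted(missing_cols)}")
        n, L = len(self.sample_ids), len(self.loci)
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (n, L):
            raise PanelError(
                f"genotypes shape {self.genotypes.shape} != ({n}, {L})"
            )
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            raise PanelError("genotype codes must be 0/1/2 or missing")
        if (self.loci["ref"] == self.loci["alt"]).any():
            raise PanelError("ref and alt alleles must differ at every locus")
        if self.haplotypes is not None:
            self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
            if self.haplotypes.shape != (2 * n, L):
                raise PanelError("haplotypes must be 2n × L")
            summed = self.haplotypes[0::2] + self.haplotypes[1::2]
            obs = self.genotypes != MISSING
            if not np.array_equal(summed[obs], self.genotypes[obs]):
                raise PanelError("genotypes do not equal haplotype sums")
        self._index = {s: i for i, s in enumerate(self.loci["snp_id"])}
        if len(self._index) != L:
            raise PanelError("duplicate snp_id in loci table")

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.loci["snp_id"])

    def locus_index(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise KeyError(f"unknown SNP id: {snp_id}") from None

    def locus(self, snp_id: str) -> pd.Series:
        return self.loci.iloc[self.locus_index(snp_id)]

    def genotype_vector(self, snp_id: str) -> np.ndarray:
        """Coded-allele counts as float with NaN for missing calls."""
        g = self.genotypes[:, self.locus_index(snp_id)].astype(float)
        g[g == MISSING] = np.nan
        return g

    def subset_samples(self, order: Sequence[int]) -> "GenotypePanel":
        order = list(order)
        hap = None
        if self.haplotypes is not None:
            hap_order = np.ravel([[2 * i, 2 * i + 1] for i in order])
            hap = self.haplotypes[hap_order]
        return GenotypePanel(
            sample_ids=[self.sample_ids[i] for i in order],
            loci=self.loci.copy(),
            genotypes=self.genotypes[order],
            haplotypes=hap,
        )


class MinorAllele(NamedTuple):
    allele: str
    frequency: float

    @property
    def monomorphic(self) -> bool:
        return self.frequency == 0.0


class LdResult(NamedTuple):
    """Pairwise LD summary between two loci (coded-allele orientation)."""

    snp_a: str
    snp_b: str
    r2: float
    d: float
    hap_freqs: tuple[float, float, float, float]  # (AB, Ab, aB, ab)
    method: str


@dataclass(frozen=True)
class RiskMatch:
    """Risk-allele assignment for a proxy SNP.

    ``ambiguous`` is True when the two loci carry no phase information
    (D = 0), in which case ``proxy_allele`` is None.
    """

    proxy_snp: str
    proxy_allele: str | None
    d_oriented: float
    ambiguous: bool = False


def minor_allele(panel: GenotypePanel, snp_id: str) -> MinorAllele:
    """Sample minor allele and its frequency in [0, 0.5].

    Ties at 0.5 go to the lexicographically smaller allele.  A locus
    monomorphic in the sample returns the absent allele with frequency
    0.0 (callers exclude such loci); an all-missing locus is an error.
    """
    locus = panel.locus(snp_id)
    g = panel.genotype_vector(snp_id)
    g = g[~np.isnan(g)]
    if g.size == 0:
        raise PanelError(f"{snp_id}: all genotypes missing")
    alt_freq = float(g.sum()) / (2 * g.size)
    ref, alt = str(locus["ref"]), str(locus["alt"])
    if alt_freq < 0.5:
        return MinorAllele(alt, alt_freq)
    if alt_freq > 0.5:
        return MinorAllele(ref, 1.0 - alt_freq)
    return MinorAllele(min(ref, alt), 0.5)


def _phased_hap_freqs(panel: GenotypePanel, ia: int, ib: int) -> np.ndarray:
    ha = panel.haplotypes[:, ia]
    hb = panel.haplotypes[:, ib]
    counts = np.array(
        [
            np.sum((ha == 1) & (hb == 1)),
            np.sum((ha == 1) & (hb == 0)),
            np.sum((ha == 0) & (hb == 1)),
            np.sum((ha == 0) & (hb == 0)),
        ],
        dtype=float,
    )
    return counts / counts.sum()


def _em_hap_freqs(
    ga: np.ndarray,
    gb: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> np.ndarray:
    """EM estimate of (p_AB, p_Ab, p_aB, p_ab) from unphased genotypes.

    Only the double heterozygotes are phase-ambiguous; the E-step splits
    their haplotype pairs between AB/ab and Ab/aB in proportion to the
    current product frequencies.
    """
    keep = ~(np.isnan(ga) | np.isnan(gb))
    ga = ga[keep].astype(int)
    gb = gb[keep].astype(int)
    if ga.size == 0:
        raise PanelError("no individuals with both genotypes observed")
    # 3x3 table of genotype combinations
    table = np.zeros((3, 3))
    for a, b in zip(ga, gb):
        table[a, b] += 1
    n_hap = 2 * ga.size
    # unambiguous haplotype counts contributed by each cell (AB, Ab, aB, ab)
    base = np.zeros(4)
    contrib = {
        (0, 0): (0, 0, 0, 2), (0, 1): (0, 0, 1, 1), (0, 2): (0, 0, 2, 0),
        (1, 0): (0, 1, 0, 1), (1, 2): (1, 0, 1, 0),
        (2, 0): (0, 2, 0, 0), (2, 1): (1, 1, 0, 0), (2, 2): (2, 0, 0, 0),
    }
    for (a, b), (cab, cAb, caB, cabab) in contrib.items():
        base += table[a, b] * np.array([cab, cAb, caB, cabab], dtype=float)
    # fix naming: base is (AB, Ab, aB, ab) with "A"/"B" = coded alleles
    n_dh = table[1, 1]  # double heterozygotes: AB/ab or Ab/aB
    p = np.full(4, 0.25)
    for _ in range(max_iter):
        cis = p[0] * p[3]
        trans = p[1] * p[2]
        x = 0.5 if cis + trans == 0 else cis / (cis + trans)
        counts = base + n_dh * np.array([x, 1 - x, 1 - x, x])
        p_new = counts / n_hap
        if np.max(np.abs(p_new - p)) <= tol * max(1.0, np.max(np.abs(p))):
            p = p_new
            break
        p = p_new
    return p


def haplotype_freqs(
    panel: GenotypePanel,
    snp_a: str,
    snp_b: str,
    method: str = "auto",
) -> LdResult:
    """Two-locus haplotype frequencies for the coded (ALT) alleles.

    ``method`` is ``"phased"`` (requires panel haplotypes), ``"em"``
    (unphased maximum likelihood), or ``"auto"`` which prefers phased
    counting when haplotypes are available.
    """
    ia, ib = panel.locus_index(snp_a), panel.locus_index(snp_b)
    if method == "auto":
        method = "phased" if panel.haplotypes is not None else "em"
    if method == "phased":
        if panel.haplotypes is None:
            raise PanelError("phased method requires haplotypes")
        freqs = _phased_hap_freqs(panel, ia, ib)
    elif method == "em":
        freqs = _em_hap_freqs(panel.genotype_vector(snp_a), panel.genotype_vector(snp_b))
    else:
        raise ValueError(f"unknown method: {method!r}")
    r2_val, d = r2(freqs)
    return LdResult(snp_a, snp_b, r2_val, d, tuple(freqs), method)


def r2(hap_freqs: Iterable[float]) -> tuple[float, float]:
    """(r², D) from (p_AB, p_Ab, p_aB, p_ab).

    D = p_AB − p_A p_B; r² = D² / (p_A(1−p_A) p_B(1−p_B)).  Returns
    (nan, D) when either locus is monomorphic (undefined r²).
    """
    f = np.asarray(list(hap_freqs), dtype=float)
    if f.shape != (4,):
        raise ValueError("hap_freqs must have 4 entries")
    p_a = f[0] + f[1]
    p_b = f[0] + f[2]
    d = f[0] - p_a * p_b
    denom = p_a * (1 - p_a) * p_b * (1 - p_b)
    if denom <= 0:
        return float("nan"), float(d)
    return float(d * d / denom), float(d)


def find_proxies(
    panel: GenotypePanel,
    index_snp: str,
    r2_min: float = 0.8,
    max_distance_bp: int = 500_000,
    method: str = "auto",
) -> list[LdResult]:
    """All same-chromosome SNPs within ``max_distance_bp`` of the index
    whose r² with it is defined and ≥ ``r2_min``, sorted by position.

    The index SNP itself is always returned with r² = 1.  SNPs with
    undefined r² (monomorphic in sample) are excluded with a warning,
    matching how precomputed LD tables omit such pairs.
    """
    idx = panel.locus(index_snp)
    out: list[tuple[int, LdResult]] = []
    for _, cand in panel.loci.iterrows():
        if cand["chrom"] != idx["chrom"]:
            continue
        if abs(int(cand["pos"]) - int(idx["pos"])) > max_distance_bp:
            continue
        sid = cand["snp_id"]
        if sid == index_snp:
            ld = haplotype_freqs(panel, index_snp, index_snp, method)
            out.append((int(cand["pos"]), ld._replace(r2=1.0)))
            continue
        ld = haplotype_freqs(panel, index_snp, sid, method)
        if np.isnan(ld.r2):
            logger.warning("excluding %s: r² with %s undefined (monomorphic)", sid, index_snp)
            continue
        if ld.r2 >= r2_min:
            out.append((int(cand["pos"]), ld))
    out.sort(key=lambda t: t[0])
    return [ld for _, ld in out]


def match_risk_allele(
    panel: GenotypePanel,
    index_snp: str,
    index_risk_allele: str,
    proxy_snp: str,
    method: str = "auto",
    d_tol: float = 1e-12,
) -> RiskMatch:
    """Assign the proxy allele carried on risk haplotypes.

    The 2×2 haplotype table is oriented to (risk allele, proxy coded
    allele); the proxy risk allele is the coded allele when the oriented
    D is positive and the other allele when it is negative.  D = 0 means
    the loci carry no phase information and the call is ambiguous.
    """
    idx_locus = panel.locus(index_snp)
    if index_risk_allele not in (str(idx_locus["ref"]), str(idx_locus["alt"])):
        raise ValueError(
            f"risk allele {index_risk_allele!r} is not an allele of {index_snp}"
        )
    if proxy_snp == index_snp:
        return RiskMatch(proxy_snp, index_risk_allele, d_oriented=float("inf"))
    ld = haplotype_freqs(panel, index_snp, proxy_snp, method)
    d = ld.d
    # ld.d is oriented to the coded (ALT) alleles of both loci
    if index_risk_allele == str(idx_locus["ref"]):
        d = -d
    prox_locus = panel.locus(proxy_snp)
    if abs(d) <= d_tol:
        return RiskMatch(proxy_snp, None, d_oriented=0.0, ambiguous=True)
    allele = str(prox_locus["alt"]) if d > 0 else str(prox_locus["ref"])
    return RiskMatch(proxy_snp, allele, d_oriented=float(d))
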