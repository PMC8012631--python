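"""Individual heterozygosity and pairwise relatedness from SNP genotypes.

Implements the four per-individual / per-pair summaries used to detect
parthenogenesis in a mother-offspring trio:

* **OH** — observed heterozygosity: the proportion of an individual's
  genotyped loci that are heterozygous.
* **HL** — homozygosity by loci: homozygosity weighted by each locus's
  expected heterozygosity ``E = 1 - sum(p_i^2)`` computed from sample allele
  frequencies, ``HL = sum(E_hom) / (sum(E_hom) + sum(E_het))``.
* **B_xy** — shared-alleles index: per-locus allele-sharing score averaged
  over loci (1 identical, 0.75 both-het sharing one allele, 0.5 one shared
  allele, 0 none).
* **M_xy** — genotype-sharing index: shared alleles (with multiplicity)
  divided by 2, averaged over loci.

All metrics exclude missing calls locus-wise, and each comes with a locus
bootstrap (resampling loci with replacement) for its sampling variability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeState, TrioDataset

logger = logging.getLogger(__name__)

__all__ = [
    "MetricBootstrap",
    "allele_frequencies",
    "expected_heterozygosity",
    "observed_heterozygosity",
    "homozygosity_by_loci",
    "pairwise_bxy",
    "pairwise_mxy",
    "bootstrap_metric",
    "summarize_trio",
]

MISSING = int(GenotypeState.MISSING)
HET = int(GenotypeState.HET)


@dataclass
class MetricBootstrap:
    """Point estimate plus locus-bootstrap replicates of one metric."""

    metric: str
    point_estimate: float
    replicates: np.ndarray
    seed: int

    @property
    def sd(self) -> float:
        return float(np.std(self.replicates, ddof=1))


def _as_codes(calls) -> np.ndarray:
    """Accept GenotypeCall sequences, GenotypeState sequences or int arrays."""
    if isinstance(calls, np.ndarray):
        return calls.astype(np.int8)
    first = next(iter(calls), None)
    if hasattr(first, "state"):
        return np.array([c.state for c in calls], dtype=np.int8)
    return np.array([int(c) for c in calls], dtype=np.int8)


def allele_frequencies(gt: np.ndarray) -> np.ndarray:
    """Reference-allele frequency per locus from a (loci x samples) code matrix.

    Missing calls are excluded; loci genotyped in no sample get frequency NaN.
    """
    gt = np.asarray(gt)
    called = gt != MISSING
    n_alleles = 2 * called.sum(axis=1)
    ref_count = np.where(called, 2 - np.where(gt == MISSING, 0, gt), 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_alleles > 0, ref_count / np.maximum(n_alleles, 1), np.nan)


def expected_heterozygosity(p: np.ndarray) -> np.ndarray:
    """Biallelic expected heterozygosity ``E = 1 - p^2 - q^2 = 2pq``."""
    p = np.asarray(p, dtype=float)
    return 1.0 - p**2 - (1.0 - p) ** 2


def observed_heterozygosity(calls) -> float:
    """Proportion of non-missing calls that are heterozygous.

    0 is complete homozygosity and 1 complete heterozygosity; missing calls
    are excluded from numerator and denominator.
    """
    codes = _as_codes(calls)
    called = codes != MISSING
    n = int(called.sum())
    if n == 0:
        raise ValueError("observed_heterozygosity undefined: all calls missing")
    return float((codes[called] == HET).sum() / n)


def homozygosity_by_loci(calls, expected_het: np.ndarray) -> float:
    """Homozygosity by loci for one sample.

    ``expected_het`` supplies the per-locus weight E (from sample allele
    frequencies over the same locus set). Missing loci are excluded from
    both sums; monomorphic loci (E = 0) contribute nothing.
    """
    codes = _as_codes(calls)
    e = np.asarray(expected_het, dtype=float)
    if codes.shape != e.shape:
        raise ValueError("calls and expected_het must align locus-wise")
    called = (codes != MISSING) & ~np.isnan(e)
    hom = called & (codes != HET)
    het = called & (codes == HET)
    denom = float(e[hom].sum() + e[het].sum())
    if denom == 0.0:
        raise ValueError("homozygosity_by_loci undefined: no informative loci")
    return float(e[hom].sum() / denom)


# Unordered genotype pairs for the two indices. B_xy scores allele sharing by
# case analysis (identical 1; both het sharing one allele 0.75; hom-het with a
# shared allele 0.5; none 0). M_xy counts shared alleles of the matched
# pairing over 2. On biallelic codes the both-het-one-shared case cannot
# occur, so the two tables coincide -- kept as separate derivations.

_ALLELES = {0: (0, 0), 1: (0, 1), 2: (1, 1)}


def _bxy_locus(sx: int, sy: int) -> float:
    ax, ay = _ALLELES[sx], _ALLELES[sy]
    if ax == ay:
        return 1.0
    sx_het, sy_het = ax[0] != ax[1], ay[0] != ay[1]
    shared = len(set(ax) & set(ay))
    if sx_het and sy_het and shared == 1:
        return 0.75
    if shared >= 1:
        return 0.5
    return 0.0


def _mxy_locus(sx: int, sy: int) -> float:
    ax, ay = sorted(_ALLELES[sx]), sorted(_ALLELES[sy])
    # count shared alleles with multiplicity under the best matching
    from collections import Counter

    cx, cy = Counter(ax), Counter(ay)
    shared = sum(min(cx[a], cy[a]) for a in cx)
    return shared / 2.0


_BXY_TABLE = np.array([[_bxy_locus(i, j) for j in range(3)] for i in range(3)])
_MXY_TABLE = np.array([[_mxy_locus(i, j) for j in range(3)] for i in range(3)])


def _pairwise(calls_x, calls_y, table: np.ndarray, name: str) -> float:
    x, y = _as_codes(calls_x), _as_codes(calls_y)
    if x.shape != y.shape:
        raise ValueError("genotype vectors must have equal length")
    ok = (x != MISSING) & (y != MISSING)
    if not ok.any():
        raise ValueError(f"{name} undefined: no pairwise-complete loci")
    return float(table[x[ok], y[ok]].mean())


def pairwise_bxy(calls_x, calls_y) -> float:
    """Shared-alleles relatedness index averaged over pairwise-complete loci."""
    return _pairwise(calls_x, calls_y, _BXY_TABLE, "B_xy")


def pairwise_mxy(calls_x, calls_y) -> float:
    """Genotype-sharing relatedness index averaged over pairwise-complete loci."""
    return _pairwise(calls_x, calls_y, _MXY_TABLE, "M_xy")


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

def _metric_on_index(metric: str, gt: np.ndarray, idx: np.ndarray,
                     sample: int, other: int | None) -> float:
    sub = gt[idx]
    if metric == "OH":
        return observed_heterozygosity(sub[:, sample])
    if metric == "HL":
        e = expected_heterozygosity(allele_frequencies(sub))
        return homozygosity_by_loci(sub[:, sample], e)
    if metric == "BXY":
        return pairwise_bxy(sub[:, sample], sub[:, other])
    if metric == "MXY":
        return pairwise_mxy(sub[:, sample], sub[:, other])
    raise ValueError(f"unknown metric {metric!r}")


def bootstrap_metric(data: TrioDataset, metric: str, sample: str | int,
                     other: str | int | None = None, n_boot: int = 100,
                     seed: int = 0) -> MetricBootstrap:
    """Locus bootstrap of OH/HL/B_xy/M_xy.

    Each replicate resamples loci with replacement to the original locus
    count and recomputes the metric. Replicates on which the metric is
    undefined (e.g. an all-missing draw) are redrawn and logged. For HL,
    allele frequencies are recomputed within each replicate.
    """
    metric = metric.upper()
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    j = sample if isinstance(sample, int) else data.sample_index(sample)
    k = None
    if metric in ("BXY", "MXY"):
        if other is None:
            raise ValueError(f"{metric} needs a second sample")
        k = other if isinstance(other, int) else data.sample_index(other)
    gt = data.gt
    n = data.n_sites
    point = _metric_on_index(metric, gt, np.arange(n), j, k)
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            try:
                reps[b] = _metric_on_index(metric, gt, idx, j, k)
                break
            except ValueError:
                logger.info("bootstrap replicate redrawn: metric undefined on draw")
    return MetricBootstrap(metric=metric, point_estimate=point, replicates=reps, seed=seed)


def summarize_trio(data: TrioDataset, n_boot: int = 100, seed: int = 0
                   ) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, MetricBootstrap]]:
    """Per-sample OH/HL and the pairwise relatedness matrix with bootstraps.

    Returns a per-sample metric table, a relatedness matrix with B_xy above
    the diagonal and M_xy below it, and the raw bootstrap objects keyed by
    ``"METRIC:sample"`` or ``"METRIC:sample1:sample2"``.
    """
    boots: dict[str, MetricBootstrap] = {}
    rows = []
    for i, s in enumerate(data.samples):
        oh = bootstrap_metric(data, "OH", i, n_boot=n_boot, seed=seed + i)
        hl = bootstrap_metric(data, "HL", i, n_boot=n_boot, seed=seed + 100 + i)
        boots[f"OH:{s}"] = oh
        boots[f"HL:{s}"] = hl
        rows.append({"sample": s, "OH": oh.point_estimate, "OH_sd": oh.sd,
                     "HL": hl.point_estimate, "HL_sd": hl.sd})
    metrics = pd.DataFrame(rows)

    ns = len(data.samples)
    mat = pd.DataFrame(np.full((ns, ns), np.nan), index=data.samples, columns=data.samples)
    for i in range(ns):
        for j in range(i + 1, ns):
            b = bootstrap_metric(data, "BXY", i, j, n_boot=n_boot, seed=seed + 200 + 10 * i + j)
            m = bootstrap_metric(data, "MXY", i, j, n_boot=n_boot, seed=seed + 300 + 10 * i + j)
            boots[f"BXY:{data.samples[i]}:{data.samples[j]}"] = b
            boots[f"MXY:{data.samples[i]}:{data.samples[j]}"] = m
            mat.iloc[i, j] = b.point_estimate  # B_xy above the diagonal
            mat.iloc[j, i] = m.point_estimate  # M_xy below
    return metrics, mat, boots
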