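"""Inference on patterns of inheritance in parthenogenetic offspring.

Given a filtered mother-offspring trio this module answers the questions a
parthenogenesis study asks of its genotypes:

* the *fate* of each maternally heterozygous locus in an offspring
  (0/0, 0/1 retained, or 1/1), with the retained-heterozygosity fraction;
* whether loss resolves evenly to the two parental homozygotes (exact
  two-sided binomial test of 0/0 vs 1/1 at expectation 0.5);
* whether the two offspring retain heterozygosity at the *same* loci more
  than chance predicts (Jaccard index with a permutation null);
* whether GC content around retained-heterozygosity loci differs from that
  around lost or background loci (rank test plus label permutation);
* a rule-based verdict on the automictic mechanism (terminal fusion,
  gametic duplication, central-fusion-like, sexual) from relatedness and
  retained heterozygosity, with the evidence and thresholds echoed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from .genotype_io import GenotypeState, TrioDataset

logger = logging.getLogger(__name__)

__all__ = [
    "HetFateTable",
    "JaccardResult",
    "GCFlankStats",
    "MechanismThresholds",
    "MechanismCall",
    "classify_fates",
    "retained_fraction",
    "binomial_bias_test",
    "jaccard_index",
    "jaccard_permutation_test",
    "gc_flank_comparison",
    "diagnose_mechanism",
]

Locus = tuple[str, int]


@dataclass
class HetFateTable:
    """Fate counts of maternal-heterozygous loci in one offspring.

    ``n00``/``n01``/``n11`` count loci where the offspring is homozygous
    reference, heterozygous (retained), and homozygous alternate.
    """

    offspring: str
    n00: int
    n01: int
    n11: int
    loci_00: list[Locus] = field(default_factory=list)
    loci_01: list[Locus] = field(default_factory=list)
    loci_11: list[Locus] = field(default_factory=list)

    @property
    def total(self) -> int:
        return self.n00 + self.n01 + self.n11


@dataclass
class JaccardResult:
    observed_j: float
    null_j: np.ndarray
    p_emp: float
    seed: int
    #: |A∩B| / min(|A|, |B|), an alternative sharing proportion
    share_of_smaller: float = float("nan")

    def summary(self) -> dict:
        return {
            "observed_jaccard": self.observed_j,
            "share_of_smaller": self.share_of_smaller,
            "null_mean": float(np.mean(self.null_j)),
            "null_sd": float(np.std(self.null_j, ddof=1)) if len(self.null_j) > 1 else 0.0,
            "n_perm": int(len(self.null_j)),
            "p_emp": self.p_emp,
            "seed": self.seed,
        }


@dataclass
class GCFlankStats:
    """Flank GC fractions per locus class and the between-class comparison."""

    window_bp: int
    gc_by_class: dict[str, np.ndarray]
    mannwhitney_p: float
    permutation_p: float
    observed_diff: float
    compared: tuple[str, str]

    def summary(self) -> dict:
        return {
            "window_bp": self.window_bp,
            "compared": list(self.compared),
            "class_means": {k: float(np.mean(v)) for k, v in self.gc_by_class.items() if len(v)},
            "class_sizes": {k: int(len(v)) for k, v in self.gc_by_class.items()},
            "mannwhitney_p": self.mannwhitney_p,
            "permutation_p": self.permutation_p,
            "observed_diff": self.observed_diff,
        }


@dataclass
class MechanismThresholds:
    """Decision bands for the rule-based mechanism call.

    ``sexual_band`` brackets parent-offspring relatedness compatible with
    biparental inheritance (0.5 at fully polymorphic loci, higher when many
    genotyped loci are monomorphic). ``near_one`` is the minimum relatedness
    for a parthenogenetic interpretation. ``gd_max_fraction`` /
    ``gd_max_count`` bound the retained-heterozygosity signal consistent
    with gametic duplication (a handful of loci tolerated as genotyping
    error); ``cf_min_fraction`` is the retained fraction above which
    heterozygosity is "comparable to the mother", i.e. central-fusion-like.
    """

    sexual_band: tuple[float, float] = (0.25, 0.90)
    near_one: float = 0.95
    gd_max_fraction: float = 0.005
    gd_max_count: int = 2
    cf_min_fraction: float = 0.80


@dataclass
class MechanismCall:
    verdict: str
    evidence: dict
    clone_flag: bool = False


# ---------------------------------------------------------------------------


def classify_fates(trio: TrioDataset, offspring: str | int) -> HetFateTable:
    """Tally the fate of maternal-heterozygous loci in one offspring.

    Restricts to loci where the mother (sample 0) is heterozygous and the
    offspring call is non-missing, and records the locus identities per
    fate class.
    """
    j = offspring if isinstance(offspring, int) else trio.sample_index(offspring)
    if j == 0:
        raise ValueError("offspring must differ from the mother (sample 0)")
    mom = trio.gt[:, 0]
    kid = trio.gt[:, j]
    het = mom == GenotypeState.HET
    if not het.any():
        raise ValueError("mother has no heterozygous loci")
    usable = het & (kid != GenotypeState.MISSING)
    ids = trio.locus_ids()
    loci = {s: [] for s in (GenotypeState.HOM_REF, GenotypeState.HET, GenotypeState.HOM_ALT)}
    for i in np.flatnonzero(usable):
        loci[GenotypeState(int(kid[i]))].append(ids[i])
    name = trio.samples[j]
    return HetFateTable(
        offspring=name,
        n00=len(loci[GenotypeState.HOM_REF]),
        n01=len(loci[GenotypeState.HET]),
        n11=len(loci[GenotypeState.HOM_ALT]),
        loci_00=loci[GenotypeState.HOM_REF],
        loci_01=loci[GenotypeState.HET],
        loci_11=loci[GenotypeState.HOM_ALT],
    )


def retained_fraction(table: HetFateTable) -> float:
    """Fraction of maternal-heterozygous loci still heterozygous in the offspring."""
    if table.total == 0:
        raise ValueError("empty fate table")
    return table.n01 / table.total


def binomial_bias_test(table: HetFateTable) -> float:
    """Exact two-sided binomial test of 0/0 vs 1/1 loss at expectation 0.5.

    Under unbiased inheritance of unlinked loci, loci losing heterozygosity
    resolve to either parental homozygote with equal probability; the
    two-sided p-value sums all outcomes whose point probability does not
    exceed that of the observed count.
    """
    n = table.n00 + table.n11
    if n == 0:
        raise ValueError("no loci lost heterozygosity; bias test undefined")
    return float(stats.binomtest(table.n00, n, 0.5, alternative="two-sided").pvalue)


def jaccard_index(a: set, b: set) -> float:
    """|A ∩ B| / |A ∪ B|; defined as 0 (logged) when both sets are empty."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        logger.warning("jaccard_index of two empty sets: defined as 0")
        return 0.0
    return len(a & b) / len(union)


def jaccard_permutation_test(
    table_a: HetFateTable,
    table_b: HetFateTable,
    maternal_het_loci: set,
    n_perm: int = 100,
    seed: int = 0,
) -> JaccardResult:
    """Test whether retained-heterozygosity loci overlap more than chance.

    The observed statistic is the Jaccard index of the two offsprings'
    retained-HET locus sets. Each permutation draws, for each offspring
    independently, a uniform random subset of the maternal heterozygous
    loci of the same size as its observed retained set; the empirical
    p-value uses the add-one estimator ``(1 + #{null >= obs}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    set_a, set_b = set(table_a.loci_01), set(table_b.loci_01)
    universe = sorted(set(maternal_het_loci))
    if not set_a <= set(universe) or not set_b <= set(universe):
        raise ValueError("retained sets must be subsets of the maternal heterozygous loci")
    observed = jaccard_index(set_a, set_b)
    denom = min(len(set_a), len(set_b))
    share_small = len(set_a & set_b) / denom if denom else float("nan")
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    n_univ = len(universe)
    for p in range(n_perm):
        ia = rng.choice(n_univ, size=len(set_a), replace=False)
        ib = rng.choice(n_univ, size=len(set_b), replace=False)
        ra = {universe[i] for i in ia}
        rb = {universe[i] for i in ib}
        null[p] = jaccard_index(ra, rb)
    p_emp = (1 + int((null >= observed).sum())) / (1 + n_perm)
    return JaccardResult(observed_j=observed, null_j=null, p_emp=p_emp, seed=seed,
                         share_of_smaller=share_small)


# ---------------------------------------------------------------------------
# GC flank comparison
# ---------------------------------------------------------------------------


def _flank_gc(ref: dict[str, str], locus: Locus, window_bp: int) -> float:
    chrom, pos = locus
    if chrom not in ref:
        raise KeyError(f"contig {chrom!r} absent from reference FASTA")
    seq = ref[chrom]
    lo = max(0, pos - 1 - window_bp)
    hi = min(len(seq), pos + window_bp)
    flank = seq[lo:hi].upper()
    counted = [b for b in flank if b != "N"]
    if not counted:
        return float("nan")
    gc = sum(b in "GC" for b in counted)
    return gc / len(counted)


def gc_flank_comparison(
    ref: dict[str, str],
    retained: set,
    lost: set,
    background: set | None = None,
    window_bp: int = 5_000,
    n_perm: int = 100,
    seed: int = 0,
) -> GCFlankStats:
    """Compare flank GC around retained- vs lost-heterozygosity loci.

    Computes the GC fraction of the ±``window_bp`` flank around each locus
    (N bases excluded), then compares retained vs lost by a two-sided
    Mann-Whitney rank test and by a label-permutation test on the
    difference of class means (add-one empirical p, two-sided).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    classes = {"retained": sorted(retained), "lost": sorted(lost)}
    if background:
        classes["background"] = sorted(background)
    gc = {name: np.array([_flank_gc(ref, loc, window_bp) for loc in loci])
          for name, loci in classes.items()}
    gc = {name: v[~np.isnan(v)] for name, v in gc.items()}
    x, y = gc["retained"], gc["lost"]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("need at least one retained and one lost locus with sequence")
    mwu_p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    observed = float(np.mean(x) - np.mean(y))
    pooled = np.concatenate([x, y])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(pooled))
        d = np.mean(pooled[perm[: len(x)]]) - np.mean(pooled[perm[len(x):]])
        if abs(d) >= abs(observed):
            hits += 1
    perm_p = (1 + hits) / (1 + n_perm)
    return GCFlankStats(window_bp=window_bp, gc_by_class=gc, mannwhitney_p=mwu_p,
                        permutation_p=perm_p, observed_diff=observed,
                        compared=("retained", "lost"))


# ---------------------------------------------------------------------------
# Mechanism diagnosis
# ---------------------------------------------------------------------------


def diagnose_mechanism(
    mother_oh: float,
    offspring_oh: float,
    relatedness: float,
    fate_table: HetFateTable,
    thresholds: MechanismThresholds | None = None,
) -> MechanismCall:
    """Rule-based call of the reproductive mechanism for one offspring.

    Relatedness in the sexual band suggests biparental reproduction;
    relatedness near 1 with essentially no retained heterozygosity suggests
    gametic duplication; near-1 relatedness with partial retention suggests
    terminal fusion; retention comparable to maternal heterozygosity with
    near-1 relatedness is central-fusion-like (or a clone, flagged when the
    genotypes match the mother exactly). The evidence payload always
    accompanies the verdict so the call is reproducible from it.
    """
    t = thresholds or MechanismThresholds()
    r = retained_fraction(fate_table)
    clone = relatedness >= 1.0 and fate_table.n00 + fate_table.n11 == 0
    evidence = {
        "mother_oh": mother_oh,
        "offspring_oh": offspring_oh,
        "relatedness": relatedness,
        "retained_fraction": r,
        "retained_count": fate_table.n01,
        "lost_counts": {"hom_ref": fate_table.n00, "hom_alt": fate_table.n11},
        "thresholds": asdict(t),
    }
    if relatedness >= t.near_one:
        if r <= t.gd_max_fraction or fate_table.n01 <= t.gd_max_count:
            verdict = "GAMETIC_DUPLICATION"
        elif r >= t.cf_min_fraction:
            verdict = "CENTRAL_FUSION_LIKE"
        else:
            verdict = "TERMINAL_FUSION"
    elif t.sexual_band[0] <= relatedness <= t.sexual_band[1]:
        verdict = "SEXUAL"
    else:
        verdict = "INCONCLUSIVE"
    return MechanismCall(verdict=verdict, evidence=evidence, clone_flag=clone)
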