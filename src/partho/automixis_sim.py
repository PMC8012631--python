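"""Chromatid-level simulator of automictic parthenogenesis.

Simulates a diploid mother with heterozygous SNP markers spread over several
chromosomes, runs an explicit four-chromatid meiosis (replication into sister
chromatids, crossovers between non-sister chromatids, then the two meiotic
divisions), and forms offspring under each candidate mechanism:

* ``TF`` — terminal fusion: egg nucleus fuses with its second polar body
  (the egg's sister chromatid). Heterozygosity survives only distal to
  crossovers, i.e. toward the telomeres of telocentric chromosomes.
* ``CF`` — central fusion: egg fuses with a first-polar-body product
  (a non-sister chromatid); heterozygosity is retained proximal to
  crossovers and approaches maternal levels overall.
* ``GD`` — gametic duplication: one egg chromatid doubled; the offspring is
  homozygous genome-wide.
* ``APOMIXIS`` — no meiotic reduction; the offspring is a maternal clone.
* ``SEXUAL`` — egg chromatid plus an independent paternal haplotype drawn at
  configurable allele frequencies.

Every offspring carries ground truth (retained-heterozygosity tracts and
crossover positions), so downstream statistics have known-answer tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .genotype_io import GenotypeState, TrioDataset, write_fasta, write_vcf

__all__ = [
    "Mechanism",
    "SimConfig",
    "ChromosomeMap",
    "MarkerMap",
    "MaternalGenome",
    "Chromatid",
    "MeiosisOutcome",
    "Offspring",
    "SimulatedTrio",
    "simulate_mother",
    "simulate_meiosis",
    "form_offspring",
    "simulate_trio",
]

_BASES = np.array(list("ATGC"))


class Mechanism(str, Enum):
    TF = "TF"
    CF = "CF"
    GD = "GD"
    APOMIXIS = "APOMIXIS"
    SEXUAL = "SEXUAL"


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic trio generator.

    Defaults emulate the genotyped marker set of a RADseq snake trio:
    20,562 unlinked loci over 18 chromosomes, a maternal heterozygous
    fraction of 278/20,562, per-sample read depth averaging ~17 (a trio
    total of ~50), and one obligate crossover per chromosome. Chromosome
    lengths are scaled to 2 Mb; all pipeline statistics are invariant to
    physical length since markers and crossovers are placed uniformly.
    """

    n_chrom: int = 18
    chrom_length: int = 2_000_000
    n_markers: int = 20_562
    maternal_het_fraction: float = 278 / 20_562
    obligate_crossover: bool = True
    mean_extra_crossovers: float = 0.0
    missingness: float = 0.01
    depth_mean: float = 17.0
    depth_dispersion: float = 5.0
    centromere_fraction: float = 0.0  # 0 -> telocentric
    paternal_alt_freq: float = 0.5
    gc_content: float = 0.41
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("maternal_het_fraction", "missingness", "centromere_fraction",
                     "paternal_alt_freq", "gc_content"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if self.n_chrom < 1 or self.chrom_length < 2:
            raise ValueError("need at least one chromosome of length >= 2")
        if self.mean_extra_crossovers < 0:
            raise ValueError("mean_extra_crossovers must be >= 0")


@dataclass(frozen=True)
class ChromosomeMap:
    """Marker coordinates on one chromosome (positions 1-based, sorted)."""

    name: str
    length: int
    centromere: float
    positions: np.ndarray

    def __post_init__(self) -> None:
        if not 0 <= self.centromere <= self.length:
            raise ValueError("centromere must lie within the chromosome")
        p = np.asarray(self.positions)
        if p.size and (np.any(np.diff(p) <= 0) or p[0] < 1 or p[-1] > self.length):
            raise ValueError("marker positions must be strictly increasing within [1, length]")


@dataclass(frozen=True)
class MarkerMap:
    chromosomes: dict[str, ChromosomeMap]

    @property
    def n_markers(self) -> int:
        return sum(len(c.positions) for c in self.chromosomes.values())


@dataclass
class MaternalGenome:
    """Two maternal haplotypes per chromosome, as REF(0)/ALT(1) allele codes.

    ``haplotypes[chrom]`` has shape (2, n_markers); a marker is heterozygous
    exactly where the two rows differ. ``ref_base``/``alt_base`` give the
    nucleotide identities used when emitting VCF/FASTA.
    """

    haplotypes: dict[str, np.ndarray]
    ref_base: dict[str, np.ndarray]
    alt_base: dict[str, np.ndarray]

    def het_mask(self, chrom: str) -> np.ndarray:
        h = self.haplotypes[chrom]
        return h[0] != h[1]

    def genotype_states(self, chrom: str) -> np.ndarray:
        h = self.haplotypes[chrom]
        return (h[0] + h[1]).astype(np.int8)  # 0/1/2 == HOM_REF/HET/HOM_ALT


@dataclass
class Chromatid:
    """A chromatid as contiguous segments of maternal-haplotype ancestry.

    ``segments`` is an ordered list of ``(start, end, source_haplotype)``
    with float breakpoints covering ``[0, length)``.
    """

    segments: list[tuple[float, float, int]]

    @property
    def breakpoints(self) -> list[float]:
        return [s for s, _, _ in self.segments[1:]]

    def hap_at(self, positions: np.ndarray) -> np.ndarray:
        """Source haplotype (0/1) at each query position."""
        ends = np.array([e for _, e, _ in self.segments])
        haps = np.array([h for _, _, h in self.segments])
        idx = np.searchsorted(ends, positions, side="right")
        idx = np.clip(idx, 0, len(haps) - 1)
        return haps[idx]


def _pure_chromatid(length: float, hap: int) -> Chromatid:
    return Chromatid([(0.0, float(length), hap)])


def _slice_segments(segs, a, b):
    out = []
    for s, e, h in segs:
        s2, e2 = max(s, a), min(e, b)
        if s2 < e2:
            out.append((s2, e2, h))
    return out


def _exchange(c1: Chromatid, c2: Chromatid, a: float, b: float) -> None:
    """Physically swap the interval [a, b) between two chromatids."""
    c1_in, c2_in = _slice_segments(c1.segments, a, b), _slice_segments(c2.segments, a, b)
    c1_out = [(s, e, h) for s, e, h in
              (_slice_segments(c1.segments, 0, a) + _slice_segments(c1.segments, b, np.inf))]
    c2_out = [(s, e, h) for s, e, h in
              (_slice_segments(c2.segments, 0, a) + _slice_segments(c2.segments, b, np.inf))]

    def rebuild(outside, inside):
        segs = sorted(outside + inside)
        merged: list[tuple[float, float, int]] = []
        for s, e, h in segs:
            if merged and merged[-1][2] == h and merged[-1][1] == s:
                merged[-1] = (merged[-1][0], e, h)
            else:
                merged.append((s, e, h))
        return merged

    c1.segments = rebuild(c1_out, c2_in)
    c2.segments = rebuild(c2_out, c1_in)


@dataclass
class ChromosomeMeiosis:
    """Meiotic products for one chromosome.

    Chromatids 0,1 are sisters with the haplotype-0 centromere; 2,3 carry
    the haplotype-1 centromere. ``egg_pair`` names the sister pair that
    entered the egg lineage at meiosis I; the other pair forms the first
    polar body.
    """

    chromatids: list[Chromatid]
    crossovers: list[tuple[float, int, int]]  # (position, chromatid_i, chromatid_j)
    egg_pair: tuple[int, int]
    polar_pair: tuple[int, int]


@dataclass
class MeiosisOutcome:
    per_chrom: dict[str, ChromosomeMeiosis]


@dataclass
class Offspring:
    """Genotypes plus ground truth for one simulated offspring."""

    mechanism: Mechanism
    states: dict[str, np.ndarray]  # genotype codes per chromosome
    het_tracts: dict[str, list[tuple[float, float]]] | None
    crossovers: dict[str, list[float]]
    retained_mask: dict[str, np.ndarray]  # maternal-HET markers heterozygous in offspring


@dataclass
class SimulatedTrio:
    config: SimConfig
    mechanisms: list[Mechanism]
    marker_map: MarkerMap
    genome: MaternalGenome
    trio: TrioDataset
    offspring: list[Offspring]
    reference: dict[str, str] | None


# ---------------------------------------------------------------------------


def simulate_mother(cfg: SimConfig, rng: np.random.Generator | None = None
                    ) -> tuple[MaternalGenome, MarkerMap]:
    """Draw the maternal genome: marker positions and phased haplotypes.

    Each marker is independently heterozygous with probability
    ``maternal_het_fraction``; which haplotype carries the reference allele
    is uniform, and homozygous markers are REF/REF or ALT/ALT equally.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    per_chrom = np.full(cfg.n_chrom, cfg.n_markers // cfg.n_chrom)
    per_chrom[: cfg.n_markers % cfg.n_chrom] += 1

    chroms: dict[str, ChromosomeMap] = {}
    haplotypes: dict[str, np.ndarray] = {}
    ref_base: dict[str, np.ndarray] = {}
    alt_base: dict[str, np.ndarray] = {}
    for k in range(cfg.n_chrom):
        name = f"chr{k + 1:02d}"
        n = int(per_chrom[k])
        pos = np.sort(rng.choice(cfg.chrom_length, size=n, replace=False)) + 1
        chroms[name] = ChromosomeMap(
            name=name,
            length=cfg.chrom_length,
            centromere=cfg.centromere_fraction * cfg.chrom_length,
            positions=pos,
        )
        het = rng.random(n) < cfg.maternal_het_fraction
        hap = np.zeros((2, n), dtype=np.int8)
        # heterozygous: one haplotype gets ALT, chosen uniformly
        which = rng.integers(0, 2, size=n)
        hap[0, het & (which == 0)] = 1
        hap[1, het & (which == 1)] = 1
        # homozygous: REF/REF or ALT/ALT equally
        hom_alt = (~het) & (rng.random(n) < 0.5)
        hap[:, hom_alt] = 1
        haplotypes[name] = hap
        rb_idx = rng.integers(0, 4, size=n)
        shift = rng.integers(1, 4, size=n)
        ref_base[name] = _BASES[rb_idx]
        alt_base[name] = _BASES[(rb_idx + shift) % 4]
    genome = MaternalGenome(haplotypes=haplotypes, ref_base=ref_base, alt_base=alt_base)
    return genome, MarkerMap(chromosomes=chroms)


def simulate_meiosis(genome: MaternalGenome, marker_map: MarkerMap, cfg: SimConfig,
                     rng: np.random.Generator) -> MeiosisOutcome:
    """Run one four-chromatid meiosis over every chromosome.

    Per chromosome: both haplotypes replicate into sister pairs; the
    crossover count is (1 if obligate) + Poisson(mean extra); each crossover
    picks a uniform position and one chromatid from each homolog, and the
    region distal to the position (relative to the centromere side) is
    physically exchanged. At segregation, one homolog's centromere pair
    becomes the egg-lineage sister pair, chosen uniformly.
    """
    out: dict[str, ChromosomeMeiosis] = {}
    for name, cmap in marker_map.chromosomes.items():
        L = float(cmap.length)
        chromatids = [_pure_chromatid(L, 0), _pure_chromatid(L, 0),
                      _pure_chromatid(L, 1), _pure_chromatid(L, 1)]
        n_co = int(cfg.obligate_crossover) + int(rng.poisson(cfg.mean_extra_crossovers))
        crossovers: list[tuple[float, int, int]] = []
        for _ in range(n_co):
            x = float(rng.uniform(0.0, L))
            i = int(rng.integers(0, 2))       # chromatid from homolog 0
            j = int(rng.integers(2, 4))       # chromatid from homolog 1
            if x >= cmap.centromere:
                _exchange(chromatids[i], chromatids[j], x, L)
            else:
                _exchange(chromatids[i], chromatids[j], 0.0, x)
            crossovers.append((x, i, j))
        if rng.integers(0, 2) == 0:
            egg_pair, polar_pair = (0, 1), (2, 3)
        else:
            egg_pair, polar_pair = (2, 3), (0, 1)
        out[name] = ChromosomeMeiosis(chromatids, crossovers, egg_pair, polar_pair)
    return MeiosisOutcome(per_chrom=out)


def _diff_tracts(c1: Chromatid, c2: Chromatid) -> list[tuple[float, float]]:
    """Intervals where two chromatids descend from different haplotypes."""
    bounds = sorted({0.0} | {e for _, e, _ in c1.segments} | {e for _, e, _ in c2.segments})
    tracts: list[tuple[float, float]] = []
    for a, b in zip(bounds, bounds[1:]):
        mid = np.array([(a + b) / 2.0])
        if c1.hap_at(mid)[0] != c2.hap_at(mid)[0]:
            if tracts and tracts[-1][1] == a:
                tracts[-1] = (tracts[-1][0], b)
            else:
                tracts.append((a, b))
    return tracts


def form_offspring(outcome: MeiosisOutcome, mechanism: Mechanism | str,
                   genome: MaternalGenome, marker_map: MarkerMap,
                   rng: np.random.Generator,
                   paternal_alt_freq: float = 0.5) -> Offspring:
    """Restore diploidy from meiotic products under the given mechanism."""
    mechanism = Mechanism(mechanism)
    states: dict[str, np.ndarray] = {}
    tracts: dict[str, list[tuple[float, float]]] | None = {}
    crossovers: dict[str, list[float]] = {}
    retained: dict[str, np.ndarray] = {}

    for name, cmap in marker_map.chromosomes.items():
        cm = outcome.per_chrom[name]
        pos = cmap.positions.astype(float)
        hap = genome.haplotypes[name]
        het = genome.het_mask(name)
        crossovers[name] = [x for x, _, _ in cm.crossovers]

        if mechanism is Mechanism.APOMIXIS:
            st = genome.genotype_states(name)
            states[name] = st
            tracts[name] = [(0.0, float(cmap.length))]
            retained[name] = het.copy()
            continue

        egg_idx = int(rng.choice(cm.egg_pair))
        egg = cm.chromatids[egg_idx]
        if mechanism is Mechanism.TF:
            partner = cm.chromatids[cm.egg_pair[0] if egg_idx == cm.egg_pair[1] else cm.egg_pair[1]]
        elif mechanism is Mechanism.CF:
            partner = cm.chromatids[int(rng.choice(cm.polar_pair))]
        elif mechanism is Mechanism.GD:
            partner = egg
        elif mechanism is Mechanism.SEXUAL:
            partner = None
        else:  # pragma: no cover - enum is exhaustive
            raise ValueError(f"unknown mechanism {mechanism}")

        idx = np.arange(len(pos))
        a1 = hap[egg.hap_at(pos), idx]
        if mechanism is Mechanism.SEXUAL:
            a2 = (rng.random(len(pos)) < paternal_alt_freq).astype(np.int8)
            st = (a1 + a2).astype(np.int8)
            states[name] = st
            retained[name] = het & (st == GenotypeState.HET)
            continue
        a2 = hap[partner.hap_at(pos), idx]
        st = (a1 + a2).astype(np.int8)
        states[name] = st
        tracts[name] = _diff_tracts(egg, partner)
        retained[name] = het & (st == GenotypeState.HET)

    if mechanism is Mechanism.SEXUAL:
        tracts = None
    return Offspring(mechanism=mechanism, states=states, het_tracts=tracts,
                     crossovers=crossovers, retained_mask=retained)


def _simulate_reference(marker_map: MarkerMap, genome: MaternalGenome,
                        gc_content: float, rng: np.random.Generator) -> dict[str, str]:
    """Random background sequence at the configured GC fraction, with the
    reference allele planted at each marker position."""
    p = np.array([(1 - gc_content) / 2, (1 - gc_content) / 2,
                  gc_content / 2, gc_content / 2])
    seqs: dict[str, str] = {}
    for name, cmap in marker_map.chromosomes.items():
        arr = rng.choice(_BASES, size=cmap.length, p=p)
        arr[cmap.positions - 1] = genome.ref_base[name]
        seqs[name] = "".join(arr.tolist())
    return seqs


def simulate_trio(cfg: SimConfig, mechanisms: Sequence[Mechanism | str],
                  out_dir: str | Path | None = None,
                  generate_reference: bool = True) -> SimulatedTrio:
    """Simulate a mother plus one offspring per requested mechanism.

    Emits (optionally to ``out_dir``) a multi-sample VCF, a reference FASTA
    consistent with the planted reference alleles, and TSV truth tables
    (per-marker fates, retained-heterozygosity tracts, crossover positions).
    Fully reproducible: a fixed config seed yields byte-identical outputs.
    """
    if not mechanisms:
        raise ValueError("need at least one mechanism")
    mechanisms = [Mechanism(m) for m in mechanisms]
    master = np.random.SeedSequence(cfg.seed)
    s_mother, s_meiosis, s_ref, s_noise = master.spawn(4)
    rng_mother = np.random.default_rng(s_mother)
    genome, marker_map = simulate_mother(cfg, rng_mother)

    rng_meiosis = np.random.default_rng(s_meiosis)
    offspring: list[Offspring] = []
    for mech in mechanisms:
        outcome = simulate_meiosis(genome, marker_map, cfg, rng_meiosis)
        offspring.append(form_offspring(outcome, mech, genome, marker_map,
                                        rng_meiosis, cfg.paternal_alt_freq))

    reference = None
    if generate_reference:
        reference = _simulate_reference(marker_map, genome, cfg.gc_content,
                                        np.random.default_rng(s_ref))

    # assemble the TrioDataset
    chrom_names = list(marker_map.chromosomes)
    chrom_col, pos_col, ref_col, alt_col = [], [], [], []
    gt_cols = []
    for name in chrom_names:
        cmap = marker_map.chromosomes[name]
        n = len(cmap.positions)
        chrom_col.extend([name] * n)
        pos_col.extend(int(p) for p in cmap.positions)
        ref_col.extend(genome.ref_base[name].tolist())
        alt_col.extend((b,) for b in genome.alt_base[name].tolist())
        mother_states = genome.genotype_states(name)
        gt_cols.append(np.column_stack([mother_states] + [o.states[name] for o in offspring]))
    gt = np.vstack(gt_cols).astype(np.int8)
    n_sites, n_samples = gt.shape

    rng_noise = np.random.default_rng(s_noise)
    p_nb = cfg.depth_dispersion / (cfg.depth_dispersion + cfg.depth_mean)
    depth = rng_noise.negative_binomial(cfg.depth_dispersion, p_nb, size=(n_sites, n_samples))
    miss = rng_noise.random((n_sites, n_samples)) < cfg.missingness
    gt = gt.copy()
    gt[miss] = GenotypeState.MISSING
    qual = np.round(rng_noise.gamma(4.0, 250.0, size=n_sites), 1)

    samples = ["mother"] + [f"offspring_{i + 1}" for i in range(len(offspring))]
    trio = TrioDataset(
        samples=samples,
        chrom=chrom_col, pos=pos_col, ref=ref_col, alt=alt_col,
        qual=qual, info=[{} for _ in range(n_sites)],
        gt=gt, depth=depth.astype(np.int32),
        provenance=[f"simulate_trio: seed={cfg.seed} mechanisms={[m.value for m in mechanisms]}"],
    )
    sim = SimulatedTrio(config=cfg, mechanisms=mechanisms, marker_map=marker_map,
                        genome=genome, trio=trio, offspring=offspring,
                        reference=reference)
    if out_dir is not None:
        _write_outputs(sim, Path(out_dir))
    return sim


def _write_outputs(sim: SimulatedTrio, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    contigs = {c.name: c.length for c in sim.marker_map.chromosomes.values()}
    write_vcf(sim.trio, out_dir / "trio.vcf", contigs=contigs)
    if sim.reference is not None:
        write_fasta(sim.reference, out_dir / "reference.fa")
    with open(out_dir / "truth_fates.tsv", "w") as fh:
        fh.write("offspring\tmechanism\tchrom\tpos\tmother_het\tretained\n")
        for i, off in enumerate(sim.offspring, 1):
            for name, cmap in sim.marker_map.chromosomes.items():
                het = sim.genome.het_mask(name)
                for p, h, r in zip(cmap.positions, het, off.retained_mask[name]):
                    fh.write(f"offspring_{i}\t{off.mechanism.value}\t{name}\t{p}\t{int(h)}\t{int(r)}\n")
    with open(out_dir / "truth_tracts.tsv", "w") as fh:
        fh.write("offspring\tmechanism\tchrom\tstart\tend\n")
        for i, off in enumerate(sim.offspring, 1):
            if off.het_tracts is None:
                continue
            for name, tr in off.het_tracts.items():
                for s, e in tr:
                    fh.write(f"offspring_{i}\t{off.mechanism.value}\t{name}\t{s:.1f}\t{e:.1f}\n")
    with open(out_dir / "truth_crossovers.tsv", "w") as fh:
        fh.write("offspring\tchrom\tpos\n")
        for i, off in enumerate(sim.offspring, 1):
            for name, xs in off.crossovers.items():
                for x in xs:
                    fh.write(f"offspring_{i}\t{name}\t{x:.1f}\n")
    cfg_echo = {k: (v if not isinstance(v, np.generic) else v.item())
                for k, v in vars(sim.config).items()}
    cfg_echo["mechanisms"] = [m.value for m in sim.mechanisms]
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg_echo, fh, sort_keys=True)
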