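"""Genotype input/output and site-level filtering for trio datasets.

This module reads multi-sample VCFs into a columnar :class:`TrioDataset`,
applies the seven-rule site filter cascade used for RADseq trio analyses
(indel removal, per-sample depth masking, indel-adjacency exclusion, site
quality, INFO hard filters, total-depth outliers, biallelic-only, and a final
complete-case requirement), thins variants to one per fixed genomic window,
and derives RAD-locus footprints from per-base depth tracks.

Coordinates follow the usual conventions: VCF positions are 1-based,
BED/RAD-locus intervals are 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeState",
    "GenotypeCall",
    "VariantSite",
    "TrioDataset",
    "DepthTrack",
    "RadLocus",
    "FilterConfig",
    "read_vcf",
    "write_vcf",
    "apply_site_filters",
    "thin_by_window",
    "derive_rad_loci",
    "read_fasta",
    "write_fasta",
    "write_bed",
]


class GenotypeState(IntEnum):
    """Diploid genotype state at a biallelic site (VCF 0/0, 0/1, 1/1, ./.)."""

    MISSING = -1
    HOM_REF = 0
    HET = 1
    HOM_ALT = 2


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one site: genotype state plus read depth."""

    state: GenotypeState
    depth: int

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError(f"depth must be >= 0, got {self.depth}")


@dataclass(frozen=True)
class VariantSite:
    """A single variant record with per-sample calls.

    ``alt_alleles`` may hold more than one allele on input; the filter
    cascade removes non-biallelic sites, after which :attr:`alt_allele`
    is well defined.
    """

    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_alleles: tuple[str, ...]
    qual: float
    info: Mapping[str, float]
    calls: tuple[GenotypeCall, ...]

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt_alleles) == 1

    @property
    def alt_allele(self) -> str:
        if not self.alt_alleles:
            return "."
        return self.alt_alleles[0]

    @property
    def is_indel(self) -> bool:
        if len(self.ref_allele) != 1:
            return True
        return any(len(a) != 1 for a in self.alt_alleles if a != ".")

    @property
    def indel_span(self) -> tuple[int, int]:
        """1-based inclusive interval of reference bases touched by the record."""
        longest = max([len(self.ref_allele)] + [len(a) for a in self.alt_alleles if a != "."])
        return self.pos, self.pos + longest - 1


class TrioDataset:
    """Per-site genotypes and depths for a mother and one or more offspring.

    Storage is columnar (NumPy arrays over sites x samples) for speed;
    :meth:`site` materialises a :class:`VariantSite` view on demand. The
    mother is always sample index 0.
    """

    def __init__(
        self,
        samples: Sequence[str],
        chrom: Sequence[str],
        pos: Sequence[int],
        ref: Sequence[str],
        alt: Sequence[tuple[str, ...]],
        qual: Sequence[float],
        info: Sequence[Mapping[str, float]],
        gt: np.ndarray,
        depth: np.ndarray,
        provenance: Sequence[str] = (),
    ) -> None:
        if len(samples) < 2:
            raise ValueError("a trio dataset needs a mother and at least one offspring")
        n = len(pos)
        gt = np.asarray(gt, dtype=np.int8)
        depth = np.asarray(depth, dtype=np.int32)
        if gt.shape != (n, len(samples)) or depth.shape != (n, len(samples)):
            raise ValueError("gt/depth must be (n_sites, n_samples) arrays")
        if np.any(depth < 0):
            raise ValueError("depths must be >= 0")
        self.samples = list(samples)
        self.chrom = np.asarray(chrom, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.ref = np.asarray(ref, dtype=object)
        self.alt = list(alt)
        self.qual = np.asarray(qual, dtype=float)
        self.info = list(info)
        self.gt = gt
        self.depth = depth
        self.provenance = list(provenance)

    # -- basic container protocol ------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def __len__(self) -> int:
        return self.n_sites

    def __iter__(self) -> Iterator[VariantSite]:
        return (self.site(i) for i in range(self.n_sites))

    def site(self, i: int) -> VariantSite:
        calls = tuple(
            GenotypeCall(GenotypeState(int(self.gt[i, j])), int(self.depth[i, j]))
            for j in range(len(self.samples))
        )
        return VariantSite(
            chrom=str(self.chrom[i]),
            pos=int(self.pos[i]),
            ref_allele=str(self.ref[i]),
            alt_alleles=tuple(self.alt[i]),
            qual=float(self.qual[i]),
            info=dict(self.info[i]),
            calls=calls,
        )

    def sample_index(self, name: str) -> int:
        try:
            return self.samples.index(name)
        except ValueError:
            raise KeyError(f"sample {name!r} not in dataset (have {self.samples})") from None

    def genotypes(self, sample: str | int) -> np.ndarray:
        """Genotype-state codes for one sample across all sites."""
        j = sample if isinstance(sample, int) else self.sample_index(sample)
        return self.gt[:, j]

    def locus_ids(self) -> list[tuple[str, int]]:
        return list(zip((str(c) for c in self.chrom), (int(p) for p in self.pos)))

    def subset(self, index: np.ndarray, note: str | None = None) -> "TrioDataset":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        prov = self.provenance + ([note] if note else [])
        return TrioDataset(
            samples=self.samples,
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=[self.alt[i] for i in index],
            qual=self.qual[index],
            info=[self.info[i] for i in index],
            gt=self.gt[index],
            depth=self.depth[index],
            provenance=prov,
        )

    def with_provenance(self, note: str) -> "TrioDataset":
        self.provenance.append(note)
        return self


@dataclass
class DepthTrack:
    """Per-base coverage for one sample over one chromosome interval.

    ``quality`` is an optional per-base Phred track (or pass mask); when
    omitted every base is treated as passing the quality requirement.
    """

    sample: str
    chrom: str
    start: int  # 0-based
    depth: np.ndarray
    quality: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth)
        if np.any(self.depth < 0):
            raise ValueError("depths must be >= 0")
        if self.quality is not None:
            self.quality = np.asarray(self.quality)
            if len(self.quality) != len(self.depth):
                raise ValueError("quality track length must match depth track")


@dataclass(frozen=True, order=True)
class RadLocus:
    """A RAD-locus footprint interval, 0-based half-open."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("locus end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

_CYVCF2_STATE = {0: GenotypeState.HOM_REF, 1: GenotypeState.HET,
                 2: GenotypeState.MISSING, 3: GenotypeState.HOM_ALT}


def read_vcf(path: str | Path, sample_order: Sequence[str] | None = None) -> TrioDataset:
    """Read a VCF 4.x file into a :class:`TrioDataset`.

    Parameters
    ----------
    path:
        VCF file with GT (and ideally DP) per-sample fields.
    sample_order:
        Desired sample ordering, mother first. Every name must occur in the
        VCF header. Defaults to header order.
    """
    path = str(path)
    vcf = VCF(path)
    if "##FORMAT=<ID=GT" not in vcf.raw_header:
        raise ValueError(f"{path}: VCF has no GT FORMAT field")
    header_samples = list(vcf.samples)
    if sample_order is None:
        sample_order = header_samples
    else:
        missing = [s for s in sample_order if s not in header_samples]
        if missing:
            raise KeyError(
                f"sample(s) {missing} requested but absent from VCF header "
                f"(header has {header_samples})"
            )
    order = [header_samples.index(s) for s in sample_order]

    chrom, pos, ref, alt, qual, info = [], [], [], [], [], []
    gt_rows, dp_rows = [], []
    for var in vcf:
        chrom.append(var.CHROM)
        pos.append(var.POS)
        ref.append(var.REF)
        alt.append(tuple(var.ALT))
        qual.append(var.QUAL if var.QUAL is not None else 0.0)
        rec_info = {}
        for key, value in var.INFO:
            if isinstance(value, (int, float)):
                rec_info[key] = float(value)
        info.append(rec_info)
        states = np.array([_CYVCF2_STATE[t] for t in var.gt_types], dtype=np.int8)
        dp = var.format("DP")
        if dp is None:
            depths = np.zeros(len(header_samples), dtype=np.int32)
        else:
            depths = dp.reshape(-1).astype(np.int64)
            depths = np.where(depths < 0, 0, depths)
        gt_rows.append(states[order])
        dp_rows.append(depths[order])
    vcf.close()

    n = len(pos)
    gt = np.array(gt_rows, dtype=np.int8) if n else np.empty((0, len(sample_order)), np.int8)
    dp = np.array(dp_rows, dtype=np.int32) if n else np.empty((0, len(sample_order)), np.int32)
    return TrioDataset(
        samples=list(sample_order),
        chrom=chrom, pos=pos, ref=ref, alt=alt, qual=qual, info=info,
        gt=gt, depth=dp,
        provenance=[f"read_vcf: {n} records from {path}"],
    )


_GT_STRING = {
    GenotypeState.HOM_REF: "0/0",
    GenotypeState.HET: "0/1",
    GenotypeState.HOM_ALT: "1/1",
    GenotypeState.MISSING: "./.",
}


def _fmt_num(x: float) -> str:
    return f"{x:g}"


def write_vcf(data: TrioDataset, path: str | Path, contigs: Mapping[str, int] | None = None) -> None:
    """Write a :class:`TrioDataset` as a VCF 4.2 text file.

    Output is deterministic (no timestamps), so identical datasets produce
    byte-identical files. Genotypes are emitted in biallelic-state encoding
    (0/0, 0/1, 1/1, ./.).
    """
    info_keys: list[str] = []
    for rec in data.info:
        for k in rec:
            if k not in info_keys:
                info_keys.append(k)
    lines = ["##fileformat=VCFv4.2", "##source=partho"]
    if contigs is None:
        contigs = {}
        for c in data.chrom:
            contigs.setdefault(str(c), 0)
    for name, length in contigs.items():
        if length:
            lines.append(f"##contig=<ID={name},length={length}>")
        else:
            lines.append(f"##contig=<ID={name}>")
    for k in info_keys:
        lines.append(f'##INFO=<ID={k},Number=1,Type=Float,Description="{k}">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(data.samples))
    for i in range(data.n_sites):
        alt = ",".join(data.alt[i]) if data.alt[i] else "."
        if data.info[i]:
            info_s = ";".join(f"{k}={_fmt_num(v)}" for k, v in data.info[i].items())
        else:
            info_s = "."
        calls = "\t".join(
            f"{_GT_STRING[GenotypeState(int(data.gt[i, j]))]}:{int(data.depth[i, j])}"
            for j in range(len(data.samples))
        )
        lines.append(
            f"{data.chrom[i]}\t{data.pos[i]}\t.\t{data.ref[i]}\t{alt}\t"
            f"{_fmt_num(float(data.qual[i]))}\t.\t{info_s}\tGT:DP\t{calls}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

#: GATK-style hard filter: a site is dropped when the condition is TRUE.
DEFAULT_INFO_FILTERS: tuple[tuple[str, str, float], ...] = (
    ("QD", "<", 2.0),
    ("FS", ">", 60.0),
    ("MQ", "<", 40.0),
    ("MQRankSum", "<", -12.5),
    ("ReadPosRankSum", "<", -8.0),
)

_COMPARATORS = {
    "<": np.less,
    ">": np.greater,
    "<=": np.less_equal,
    ">=": np.greater_equal,
}


@dataclass
class FilterConfig:
    """Parameters of the site filter cascade.

    ``depth_sum_bounds`` (absolute) overrides ``depth_sum_multipliers``
    (fractions of the dataset's mean total depth) when given.
    """

    min_depth: int = 5
    min_qual: float = 30.0
    info_filters: tuple[tuple[str, str, float], ...] = DEFAULT_INFO_FILTERS
    depth_sum_multipliers: tuple[float, float] = (0.5, 2.0)
    depth_sum_bounds: tuple[float, float] | None = None
    biallelic_only: bool = True
    snp_indel_gap: int = 3
    indel_cluster_gap: int = 10
    require_complete: bool = True
    exclude_chroms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        for name, op, _ in self.info_filters:
            if op not in _COMPARATORS:
                raise ValueError(f"unknown comparator {op!r} in filter on {name}")


def _is_indel_mask(data: TrioDataset) -> np.ndarray:
    """Vectorised indel detection from REF/ALT allele lengths."""
    mask = np.fromiter(
        (len(r) != 1 or any(len(a) != 1 for a in alts if a != ".")
         for r, alts in zip(data.ref, data.alt)),
        dtype=bool, count=data.n_sites)
    return mask


def _indel_exclusion_mask(data: TrioDataset, cfg: FilterConfig,
                          is_indel: np.ndarray) -> np.ndarray:
    """True for SNP sites lying within ``snp_indel_gap`` bp of any input indel."""
    indel_spans: dict[str, list[tuple[int, int]]] = {}
    for i in np.flatnonzero(is_indel):
        site = data.site(int(i))
        indel_spans.setdefault(site.chrom, []).append(site.indel_span)
    # flag clusters of indels separated by <= indel_cluster_gap
    for c, spans in indel_spans.items():
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 - e1 <= cfg.indel_cluster_gap:
                logger.warning("indel cluster on %s between %d and %d", c, s1, e2)
    drop = np.zeros(data.n_sites, dtype=bool)
    if not indel_spans:
        return drop
    affected = {c for c in indel_spans}
    for i in range(data.n_sites):
        c = str(data.chrom[i])
        if c not in affected:
            continue
        p = int(data.pos[i])
        for s, e in indel_spans[c]:
            if s - cfg.snp_indel_gap <= p <= e + cfg.snp_indel_gap:
                drop[i] = True
                break
    return drop


def apply_site_filters(data: TrioDataset, cfg: FilterConfig | None = None) -> TrioDataset:
    """Apply the seven-rule site filter cascade plus the complete-case rule.

    In order: (1) indels dropped; (2) per-sample calls with depth below
    ``min_depth`` set MISSING; (3) SNPs within ``snp_indel_gap`` bp of an
    input indel dropped; (4) site quality below ``min_qual`` dropped;
    (5) INFO hard-filter violations dropped (absent annotations skipped with
    a logged warning); (6) total-depth outliers dropped; (7) non-biallelic
    sites dropped; finally sites with any MISSING call are dropped so that
    downstream statistics see genotypes called in every trio member.

    Rule 6's multiplier bounds are resolved against the mean total depth of
    the sites reaching that rule, and the whole cascade is iterated until no
    further site is removed, so the operation is idempotent even though the
    mean shifts as sites drop out. Per-rule attrition is recorded in the
    output's provenance log.
    """
    if cfg is None:
        cfg = FilterConfig()
    out = _apply_site_filters_once(data, cfg)
    while out.n_sites < data.n_sites:
        data = out
        out = _apply_site_filters_once(data, cfg)
    return out


def _apply_site_filters_once(data: TrioDataset, cfg: FilterConfig) -> TrioDataset:
    log: list[str] = []
    n_samples = len(data.samples)

    keep = np.ones(data.n_sites, dtype=bool)

    if cfg.exclude_chroms:
        excl = np.isin(data.chrom.astype(str), list(cfg.exclude_chroms))
        keep &= ~excl
        log.append(f"exclude_chroms: removed {int(excl.sum())} sites")

    # rule 3 needs indels from the *unfiltered* input, collect before rule 1
    is_indel = _is_indel_mask(data)
    indel_adjacent = _indel_exclusion_mask(data, cfg, is_indel)

    # (1) indels
    removed = int((keep & is_indel).sum())
    keep &= ~is_indel
    log.append(f"rule1_indels: removed {removed} sites")

    # (2) low-depth calls -> MISSING (applied to the genotype matrix copy)
    gt = data.gt.copy()
    low = data.depth < cfg.min_depth
    n_masked = int((low & (gt != GenotypeState.MISSING)).sum())
    gt[low] = GenotypeState.MISSING
    log.append(f"rule2_low_depth_calls: set {n_masked} calls missing (depth < {cfg.min_depth})")

    # (3) SNPs near indels
    removed = int((keep & indel_adjacent).sum())
    keep &= ~indel_adjacent
    log.append(f"rule3_near_indel: removed {removed} sites")

    # (4) site quality
    low_qual = data.qual < cfg.min_qual
    removed = int((keep & low_qual).sum())
    keep &= ~low_qual
    log.append(f"rule4_qual: removed {removed} sites (QUAL < {cfg.min_qual})")

    # (5) INFO hard filters
    warned: set[str] = set()
    info_drop = np.zeros(data.n_sites, dtype=bool)
    has_info = any(data.info)
    for name, op, threshold in cfg.info_filters if has_info else ():
        fn = _COMPARATORS[op]
        for i in range(data.n_sites):
            if not keep[i]:
                continue
            value = data.info[i].get(name)
            if value is None:
                if name not in warned:
                    logger.warning("INFO key %s absent at some sites; hard filter skipped there", name)
                    warned.add(name)
                continue
            if fn(value, threshold):
                info_drop[i] = True
    removed = int((keep & info_drop).sum())
    keep &= ~info_drop
    log.append(f"rule5_info_hard_filter: removed {removed} sites")

    # (6) total-depth outliers, iterated to a fixed point
    total_depth = data.depth.sum(axis=1)
    removed = 0
    if cfg.depth_sum_bounds is not None:
        lo, hi = cfg.depth_sum_bounds
        bad = keep & ((total_depth < lo) | (total_depth > hi))
        removed = int(bad.sum())
        keep &= ~bad
        log.append(f"rule6_depth_sum: removed {removed} sites (bounds [{lo:g}, {hi:g}])")
    else:
        m_lo, m_hi = cfg.depth_sum_multipliers
        while True:
            if not keep.any():
                break
            mean = float(total_depth[keep].mean())
            lo, hi = m_lo * mean, m_hi * mean
            bad = keep & ((total_depth < lo) | (total_depth > hi))
            if not bad.any():
                break
            removed += int(bad.sum())
            keep &= ~bad
        log.append(
            f"rule6_depth_sum: removed {removed} sites "
            f"(multipliers {m_lo}x/{m_hi}x of mean total depth, fixed point)"
        )

    # (7) non-biallelic
    if cfg.biallelic_only:
        multi = np.array([len(a) != 1 or a[0] in (".", "") for a in data.alt])
        removed = int((keep & multi).sum())
        keep &= ~multi
        log.append(f"rule7_non_biallelic: removed {removed} sites")

    # complete case across the trio
    if cfg.require_complete:
        any_missing = (gt == GenotypeState.MISSING).any(axis=1)
        removed = int((keep & any_missing).sum())
        keep &= ~any_missing
        log.append(f"complete_case: removed {removed} sites with missing calls")

    out = TrioDataset(
        samples=data.samples,
        chrom=data.chrom[keep],
        pos=data.pos[keep],
        ref=data.ref[keep],
        alt=[data.alt[i] for i in np.flatnonzero(keep)],
        qual=data.qual[keep],
        info=[data.info[i] for i in np.flatnonzero(keep)],
        gt=gt[keep],
        depth=data.depth[keep],
        provenance=data.provenance + log + [f"apply_site_filters: {int(keep.sum())}/{data.n_sites} sites kept"],
    )
    return out


def thin_by_window(data: TrioDataset, window_bp: int = 50_000, seed: int = 0) -> TrioDataset:
    """Keep at most one site per fixed, zero-anchored genomic window.

    Each occupied window ``[k*w, (k+1)*w)`` on each chromosome contributes
    one site chosen uniformly at random; the result is deterministic for a
    fixed seed and sorted by (chrom, pos).
    """
    if window_bp <= 0:
        raise ValueError(f"window_bp must be positive, got {window_bp}")
    rng = np.random.default_rng(seed)
    windows: dict[tuple[str, int], list[int]] = {}
    for i in range(data.n_sites):
        key = (str(data.chrom[i]), int(data.pos[i]) // window_bp)
        windows.setdefault(key, []).append(i)
    chosen = [int(rng.choice(members)) for key, members in sorted(windows.items())]
    order = sorted(chosen, key=lambda i: (str(data.chrom[i]), int(data.pos[i])))
    return data.subset(
        np.array(order, dtype=int),
        note=f"thin_by_window: kept {len(order)}/{data.n_sites} sites (window {window_bp} bp, seed {seed})",
    )


def derive_rad_loci(
    tracks: Iterable[DepthTrack],
    min_depth: int = 5,
    min_qual: float = 30.0,
    max_gap: int = 10,
    min_len: int = 100,
) -> list[RadLocus]:
    """Derive RAD-locus footprints from per-base depth tracks.

    A base passes when depth >= ``min_depth`` in every sample and its quality
    (where a quality track is supplied) is >= ``min_qual``. Passing runs
    separated by at most ``max_gap`` failing bases are merged, gap included;
    merged intervals shorter than ``min_len`` are dropped. Output is 0-based
    half-open, sorted, non-overlapping.
    """
    by_chrom: dict[str, list[DepthTrack]] = {}
    for t in tracks:
        by_chrom.setdefault(t.chrom, []).append(t)
    loci: list[RadLocus] = []
    for chrom in sorted(by_chrom):
        group = by_chrom[chrom]
        starts = {t.start for t in group}
        lengths = {len(t.depth) for t in group}
        if len(starts) != 1 or len(lengths) != 1:
            raise ValueError(f"depth tracks for {chrom} cover mismatched intervals")
        start0 = group[0].start
        passing = np.ones(lengths.pop(), dtype=bool)
        for t in group:
            passing &= t.depth >= min_depth
            if t.quality is not None:
                passing &= t.quality >= min_qual
        # run-length scan with gap merging
        idx = np.flatnonzero(passing)
        if idx.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(idx) > max_gap + 1)
        run_starts = np.concatenate(([0], breaks + 1))
        run_ends = np.concatenate((breaks, [idx.size - 1]))
        for a, b in zip(run_starts, run_ends):
            s, e = int(idx[a]), int(idx[b]) + 1
            if e - s >= min_len:
                loci.append(RadLocus(chrom, start0 + s, start0 + e))
    return loci


# ---------------------------------------------------------------------------
# FASTA / BED plumbing
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{name: sequence}``; sequences are upper-cased."""
    seqs: dict[str, str] = {}
    lowered = False
    for rec in SeqIO.parse(str(path), "fasta"):
        s = str(rec.seq)
        if not s.isupper():
            lowered = True
        seqs[rec.id] = s.upper()
    if lowered:
        logger.info("read_fasta: lowercase bases upper-cased in %s", path)
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def write_bed(loci: Iterable[RadLocus], path: str | Path) -> None:
    """Write RAD loci as BED3 (0-based half-open)."""
    with open(path, "w") as fh:
        for loc in loci:
            fh.write(f"{loc.chrom}\t{loc.start}\t{loc.end}\n")


def read_bed(path: str | Path) -> list[RadLocus]:
    """Read a BED3 file into :class:`RadLocus` records."""
    loci = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: malformed BED line: {line!r}")
            try:
                loci.append(RadLocus(parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: {exc}") from None
    return loci
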