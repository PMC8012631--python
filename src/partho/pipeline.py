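"""End-to-end orchestration: simulate/load -> filter -> thin -> stats -> inherit.

A :class:`RunConfig` (usually from YAML) either names an input VCF or embeds
a simulator block. :func:`run_pipeline` executes the stages in order, writes
per-stage tables under the output directory and returns a consolidated,
JSON-serialisable report. One global seed fans out to the stochastic stages
by fixed offsets so each stage is independently reproducible.
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

from . import __version__
from .automixis_sim import Mechanism, SimConfig, simulate_trio
from .diversity_stats import summarize_trio
from .genotype_io import FilterConfig, apply_site_filters, read_fasta, read_vcf, thin_by_window
from .inheritance import (
    MechanismThresholds,
    binomial_bias_test,
    classify_fates,
    diagnose_mechanism,
    gc_flank_comparison,
    jaccard_permutation_test,
    retained_fraction,
)
from .genotype_io import GenotypeState

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1

# fixed per-stage seed offsets from the global seed
SEED_OFFSETS = {"simulate": 0, "thin": 1, "stats": 2, "jaccard": 3, "gc": 4}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_vcf`` or ``simulate`` must be provided.
    """

    seed: int = 0
    out_dir: str = "partho_run"
    input_vcf: str | None = None
    sample_order: list[str] | None = None
    reference_fasta: str | None = None
    simulate: dict | None = None
    filter: dict = field(default_factory=dict)
    thin_window_bp: int | None = 50_000
    n_boot: int = 100
    n_perm: int = 100
    gc_window_bp: int = 5_000
    thresholds: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.input_vcf is None) == (self.simulate is None):
            raise ValueError("exactly one of input_vcf or simulate must be configured")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def echo(self) -> dict:
        return dataclasses.asdict(self)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapper
    return deco


@_stage("load")
def _load(cfg: RunConfig):
    if cfg.simulate is not None:
        sim_kwargs = dict(cfg.simulate)
        mechanisms = [Mechanism(m) for m in sim_kwargs.pop("mechanisms", ["TF", "TF"])]
        sim_cfg = SimConfig(seed=cfg.seed + SEED_OFFSETS["simulate"],
                            **sim_kwargs)
        sim = simulate_trio(sim_cfg, mechanisms, out_dir=Path(cfg.out_dir) / "sim")
        return sim.trio, sim.reference, sim
    data = read_vcf(cfg.input_vcf, cfg.sample_order)
    ref = read_fasta(cfg.reference_fasta) if cfg.reference_fasta else None
    return data, ref, None


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline and return the consolidated report.

    Writes ``report.json``, a Table-1-style metrics TSV, a Table-2-style
    fate TSV, bootstrap replicates, and (when two offspring and a reference
    are available) the Jaccard and GC comparison summaries to ``out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "partho_version": __version__,
        "seed": cfg.seed,
        "config": cfg.echo(),
        "stages": {},
    }

    data, reference, sim = _load(cfg)
    report["stages"]["load"] = {"n_sites": data.n_sites, "samples": data.samples}
    if sim is not None:
        report["stages"]["load"]["mechanism_truth"] = [m.value for m in sim.mechanisms]

    # filter
    try:
        fcfg = FilterConfig(**cfg.filter)
        filtered = apply_site_filters(data, fcfg)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("filter", exc) from exc
    report["stages"]["filter"] = {
        "n_sites_in": data.n_sites,
        "n_sites_out": filtered.n_sites,
        "log": [line for line in filtered.provenance if line not in data.provenance],
    }

    # thin
    if cfg.thin_window_bp:
        try:
            thinned = thin_by_window(filtered, cfg.thin_window_bp,
                                     seed=cfg.seed + SEED_OFFSETS["thin"])
        except Exception as exc:
            raise PipelineError("thin", exc) from exc
    else:
        thinned = filtered
    report["stages"]["thin"] = {"n_sites_out": thinned.n_sites,
                                "window_bp": cfg.thin_window_bp}

    # stats
    try:
        metrics, rel_matrix, boots = summarize_trio(
            thinned, n_boot=cfg.n_boot, seed=cfg.seed + SEED_OFFSETS["stats"])
    except Exception as exc:
        raise PipelineError("stats", exc) from exc
    metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)
    rel_matrix.to_csv(out / "relatedness_matrix.tsv", sep="\t")
    pd.DataFrame({k: b.replicates for k, b in boots.items()}).to_csv(
        out / "bootstrap_replicates.tsv", sep="\t", index=False)
    report["stages"]["stats"] = {
        "n_boot": cfg.n_boot,
        "metrics": metrics.to_dict(orient="records"),
        "relatedness_matrix": rel_matrix.to_dict(),
    }

    # inheritance
    try:
        thresholds = MechanismThresholds(**cfg.thresholds)
        mom_het = thinned.gt[:, 0] == GenotypeState.HET
        maternal_het_loci = {loc for loc, h in zip(thinned.locus_ids(), mom_het) if h}
        fate_rows = []
        tables = []
        calls = []
        mother_oh = float(metrics.loc[metrics["sample"] == thinned.samples[0], "OH"].iloc[0])
        for j, name in enumerate(thinned.samples[1:], start=1):
            table = classify_fates(thinned, j)
            tables.append(table)
            p = binomial_bias_test(table) if table.n00 + table.n11 > 0 else float("nan")
            frac = retained_fraction(table)
            fate_rows.append({"offspring": name, "n00": table.n00, "n01": table.n01,
                              "n11": table.n11, "retained_fraction": frac,
                              "binomial_p": p})
            oh = float(metrics.loc[metrics["sample"] == name, "OH"].iloc[0])
            rel = float(rel_matrix.iloc[j, 0])  # M_xy below the diagonal
            call = diagnose_mechanism(mother_oh, oh, rel, table, thresholds)
            calls.append({"offspring": name, "verdict": call.verdict,
                          "clone_flag": call.clone_flag, "evidence": call.evidence})
        fates = pd.DataFrame(fate_rows)
        fates.to_csv(out / "fates.tsv", sep="\t", index=False)
        report["stages"]["inherit"] = {"fates": fate_rows, "mechanism_calls": calls}

        if len(tables) >= 2:
            jac = jaccard_permutation_test(tables[0], tables[1], maternal_het_loci,
                                           n_perm=cfg.n_perm,
                                           seed=cfg.seed + SEED_OFFSETS["jaccard"])
            report["stages"]["inherit"]["jaccard"] = jac.summary()
            with open(out / "jaccard.json", "w") as fh:
                json.dump(jac.summary(), fh, indent=2)

        if reference is not None and len(tables) >= 1:
            retained = set().union(*(t.loci_01 for t in tables))
            lost = set().union(*(t.loci_00 + t.loci_11 for t in tables)) - retained
            if retained and lost:
                gc = gc_flank_comparison(reference, retained, lost,
                                         window_bp=cfg.gc_window_bp,
                                         n_perm=cfg.n_perm,
                                         seed=cfg.seed + SEED_OFFSETS["gc"])
                report["stages"]["inherit"]["gc_flanks"] = gc.summary()
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("inherit", exc) from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=_json_default)
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
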