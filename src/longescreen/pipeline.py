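"""End-to-end synthetic pipeline and its configuration.

``run_pipeline`` simulates each input type, runs every analysis stage,
and writes all result tables plus a run manifest recording the seed,
thresholds and package version, so any result is reproducible from the
manifest and inputs alone.  Outputs are deterministic given the seed:
two runs with the same config produce byte-identical files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .degs import (
    assign_abundance_bins,
    call_degs,
    fisher_enrichment,
    promoter_state_enrichment,
    updown_ratio_by_bin,
)
from .screen import LongevityScreen, WeightScheme
from .simulate import (
    simulate_expression_experiment,
    simulate_lifespan_cohort,
    simulate_screen_dataset,
)
from .survival import log_rank_test, kaplan_meier, percent_extension, summarize_group

log = logging.getLogger("longescreen")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Thresholds, simulation sizes and paths for one pipeline run."""

    seed: int = 0
    out_dir: str = "longescreen_run"
    # analysis thresholds
    lfc_cut: float = 1.0
    alpha: float = 0.05
    extreme_fpkm: float = 5000.0
    weight_offset: float = 50.0
    loess_span: float = 0.75
    min_strains: int = 10
    # simulation sizes
    screen_strains: int = 200
    screen_genes: int = 500
    screen_drivers: int = 5
    cohort_means: dict = field(default_factory=lambda: {"control": 23.92, "treatment": 26.78})
    cohort_n: int = 150
    cohort_dispersion: float = 0.25
    cohort_censor_frac: float = 0.0
    experiment_genes: int = 2000
    experiment_reps: int = 4
    experiment_degs: int = 100
    log_level: str = "INFO"

    def validate(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        for name in ("lfc_cut", "extreme_fpkm", "weight_offset", "loess_span"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.loess_span <= 1):
            raise ValueError("loess_span must lie in (0, 1]")
        if self.min_strains < 3:
            raise ValueError("min_strains must be >= 3")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _seeds(seed: int) -> dict[str, int]:
    """Independent per-stage substreams derived from the run seed."""
    ss = np.random.SeedSequence(seed)
    names = ("screen", "cohort", "experiment")
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Run simulate -> screen, survival, and degs -> stratify -> enrich.

    Writes every result TSV plus ``manifest.json`` under
    ``config.out_dir`` and returns the manifest dict.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _seeds(config.seed)
    manifest: dict = {
        "package": "longescreen",
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "thresholds": {
            "lfc_cut": config.lfc_cut,
            "alpha": config.alpha,
            "extreme_fpkm": config.extreme_fpkm,
            "weight_offset": config.weight_offset,
            "loess_span": config.loess_span,
            "min_strains": config.min_strains,
        },
        "stages": {},
        "files": [],
    }

    def _write(df: pd.DataFrame, name: str):
        io.write_tsv(df, out / name)
        manifest["files"].append(name)

    # --- screen stage -----------------------------------------------------
    t0 = time.perf_counter()
    compendium, phenotypes, truth = simulate_screen_dataset(
        M=config.screen_strains,
        G=config.screen_genes,
        n_drivers=config.screen_drivers,
        seed=seeds["screen"],
    )
    io.write_phenotypes(phenotypes, out / "phenotypes.tsv")
    io.write_compendium(compendium, out / "compendium.tsv")
    manifest["files"] += ["phenotypes.tsv", "compendium.tsv"]
    _write(truth.frame(), "screen_truth.tsv")
    screen = LongevityScreen(
        compendium,
        phenotypes,
        WeightScheme(config.weight_offset),
        min_strains=config.min_strains,
    ).fit()
    _write(screen.frame, "screen_results.tsv")
    manifest["stages"]["screen"] = {
        "n_strains": len(screen.model.strains),
        "n_genes_fitted": len(screen.results),
        "n_skipped": len(screen.skipped),
        "seconds": round(time.perf_counter() - t0, 3),
    }
    log.info("screen: %d genes fitted", len(screen.results))

    # --- survival stage ---------------------------------------------------
    t0 = time.perf_counter()
    records = simulate_lifespan_cohort(
        config.cohort_means,
        ns=config.cohort_n,
        dispersion=config.cohort_dispersion,
        censor_frac=config.cohort_censor_frac,
        seed=seeds["cohort"],
    )
    io.write_lifespans(records, out / "lifespans.tsv")
    manifest["files"].append("lifespans.tsv")
    groups = list(config.cohort_means)
    summaries = [summarize_group(records, g) for g in groups]
    _write(
        pd.DataFrame(
            {
                "group": [s.group for s in summaries],
                "n": [s.n for s in summaries],
                "mean": [s.mean for s in summaries],
                "median": [s.median for s in summaries],
            }
        ),
        "survival_summary.tsv",
    )
    for g in groups:
        _write(kaplan_meier([r for r in records if r.group == g]), f"km_{g}.tsv")
    lr = log_rank_test(
        [r for r in records if r.group == groups[0]],
        [r for r in records if r.group == groups[1]],
    )
    ext_rounded, ext_exact = percent_extension(summaries[1].mean, summaries[0].mean)
    _write(
        pd.DataFrame(
            [
                {
                    "comparison": f"{groups[1]}_vs_{groups[0]}",
                    "percent_extension": ext_rounded,
                    "percent_extension_exact": ext_exact,
                    "logrank_chi_square": lr.chi_square,
                    "logrank_p": lr.p_value,
                }
            ]
        ),
        "survival_tests.tsv",
    )
    manifest["stages"]["survival"] = {
        "groups": groups,
        "n_records": len(records),
        "seconds": round(time.perf_counter() - t0, 3),
    }

    # --- expression stage -------------------------------------------------
    t0 = time.perf_counter()
    records_x, annotations, gene_terms, xtruth = simulate_expression_experiment(
        G=config.experiment_genes,
        n_reps=config.experiment_reps,
        n_deg=config.experiment_degs,
        seed=seeds["experiment"],
    )
    io.write_expression_long(records_x, out / "expression.tsv")
    io.write_promoter_states(annotations, out / "promoter_states.tsv")
    io.write_gene_terms(gene_terms, out / "gene_terms.tsv")
    manifest["files"] += ["expression.tsv", "promoter_states.tsv", "gene_terms.tsv"]
    _write(xtruth.frame(), "experiment_truth.tsv")

    degset = call_degs(records_x, tissue="synthetic", lfc_cut=config.lfc_cut, alpha=config.alpha)
    _write(
        pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in records_x],
                "log2fc": [r.log2fc for r in records_x],
                "p_value": [r.p_value for r in records_x],
                "q_value": [r.q_value for r in records_x],
            }
        ),
        "deg_stats.tsv",
    )
    _write(
        pd.DataFrame(
            [{"gene_id": g, "direction": d} for d, s in (("up", degset.up), ("down", degset.down)) for g in sorted(s)]
        ),
        "deg_sets.tsv",
    )

    enr = promoter_state_enrichment(degset, annotations)
    _write(
        pd.DataFrame(
            [
                {
                    "prop_active_up": enr.prop_active_up,
                    "prop_active_down": enr.prop_active_down,
                    "chi_square": enr.chi_square,
                    "p_value": enr.p_value,
                    "n_unannotated": enr.n_unannotated,
                }
            ]
        ),
        "promoter_enrichment.tsv",
    )

    bins, binning = assign_abundance_bins(records_x, extreme=config.extreme_fpkm)
    ratios = updown_ratio_by_bin(degset, bins)
    _write(ratios, "abundance_ratios.tsv")

    background = {r.gene_id for r in records_x}
    results = fisher_enrichment(degset.down, gene_terms, background)
    _write(
        pd.DataFrame(
            [
                {
                    "term_id": r.term_id,
                    "overlap": r.overlap,
                    "term_size": r.term_size,
                    "set_size": r.set_size,
                    "background_size": r.background_size,
                    "odds_ratio": r.odds_ratio,
                    "p_value": r.p_value,
                    "q_value": r.q_value,
                }
                for r in results
            ]
        ),
        "enrichment_down.tsv",
    )
    manifest["stages"]["expression"] = {
        "n_genes": len(records_x),
        "n_up": degset.n_up,
        "n_down": degset.n_down,
        "bin_edges": list(binning.edges),
        "seconds": round(time.perf_counter() - t0, 3),
    }

    manifest["status"] = "complete"
    # timing is reported in the manifest "stages" for logging but must not
    # break byte-identity across runs; zero it out in the written file
    frozen = json.loads(json.dumps(manifest))
    for st in frozen["stages"].values():
        st.pop("seconds", None)
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(frozen, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
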