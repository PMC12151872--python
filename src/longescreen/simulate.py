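"""Synthetic data generators with full ground truth.

Every analysis stage has a generator that emulates the statistical
structure it assumes, so the whole pipeline is testable without any
external download:

* :func:`simulate_screen_dataset` — a knockout expression compendium and
  lifespan phenotype table where a few planted "driver" genes linearly
  drive the lifespan change, with heteroscedastic noise whose variance is
  ``sigma^2 * (n + 50) / n`` for a strain measured on ``n`` cells — which
  makes ``w = n / (n + 50)`` exactly the inverse-variance weight.
* :func:`simulate_lifespan_cohort` — per-individual lifespans from a
  Gompertz distribution parameterised to a target mean, with optional
  independent right-censoring.
* :func:`simulate_expression_experiment` — replicate FPKM tables with a
  heavy-tailed abundance spectrum (reaching the >5000 total-FPKM class),
  planted DEGs, promoter states whose activity rises with abundance and
  is boosted for planted-down genes, and a term annotation with one term
  planted enriched in the down set.

All randomness flows through ``numpy.random.default_rng(seed)`` (PCG64),
so identical seeds give identical outputs across runs and platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .degs import GeneExpressionRecord, PromoterAnnotation
from .screen import ExpressionCompendium, StrainPhenotype
from .survival import LifespanRecord

__all__ = [
    "ScreenTruth",
    "ExperimentTruth",
    "simulate_screen_dataset",
    "simulate_lifespan_cohort",
    "simulate_expression_experiment",
]


@dataclass
class ScreenTruth:
    """Ground truth for a simulated screen dataset."""

    drivers: dict[str, float]  # gene id -> true slope
    sigma: float
    cellcount_range: tuple[int, int]
    seed: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": list(self.drivers), "true_slope": list(self.drivers.values())}
        )


@dataclass
class ExperimentTruth:
    """Ground truth for a simulated expression experiment."""

    planted_lfc: dict[str, float]  # gene id -> true log2 fold change (DEGs only)
    baseline_fpkm: dict[str, float]
    active_probability: dict[str, float]
    enriched_term: str
    seed: int

    def frame(self) -> pd.DataFrame:
        genes = sorted(self.baseline_fpkm)
        return pd.DataFrame(
            {
                "gene_id": genes,
                "baseline_fpkm": [self.baseline_fpkm[g] for g in genes],
                "true_log2fc": [self.planted_lfc.get(g, 0.0) for g in genes],
                "p_active": [self.active_probability[g] for g in genes],
            }
        )


def simulate_screen_dataset(
    M: int = 200,
    G: int = 500,
    n_drivers: int = 5,
    slope_range: tuple[float, float] = (4.0, 10.0),
    sigma: float = 10.0,
    cellcount_range: tuple[int, int] = (5, 120),
    seed: int = 0,
) -> tuple[ExpressionCompendium, list[StrainPhenotype], ScreenTruth]:
    """Simulate a strain x gene compendium plus lifespan phenotypes.

    Expression log2FC entries are standard normal.  Lifespan change is
    ``y_i = sum_d beta_d x_id + eps_i`` with ``eps_i ~ N(0, sigma^2 *
    (n_i + 50) / n_i)`` and cell counts ``n_i`` uniform over
    ``cellcount_range``.  Driver slopes are uniform over ``slope_range``
    in magnitude with random sign.  ``n_drivers=0`` gives a pure null
    dataset.
    """
    if M < 20:
        raise ValueError("need at least 20 strains (M >= 20)")
    if not (0 <= n_drivers <= G):
        raise ValueError("n_drivers must lie in [0, G]")
    lo, hi = cellcount_range
    if not (1 <= lo <= hi):
        raise ValueError("cellcount_range must satisfy 1 <= lo <= hi")
    if slope_range[0] > slope_range[1] or slope_range[0] < 0:
        raise ValueError("slope_range must be 0 <= lo <= hi (magnitudes)")
    if sigma < 0:
        raise ValueError("sigma must be non-negative")

    rng = np.random.default_rng(seed)
    strains = [f"strain{i:04d}" for i in range(M)]
    genes = [f"gene{j:04d}" for j in range(G)]
    X = rng.standard_normal((M, G))
    driver_idx = rng.choice(G, size=n_drivers, replace=False)
    mags = rng.uniform(slope_range[0], slope_range[1], size=n_drivers)
    signs = rng.choice([-1.0, 1.0], size=n_drivers)
    betas = mags * signs

    n_cells = rng.integers(lo, hi + 1, size=M)
    noise_sd = sigma * np.sqrt((n_cells + 50.0) / n_cells)
    y = X[:, driver_idx] @ betas + rng.standard_normal(M) * noise_sd

    compendium = ExpressionCompendium.from_arrays(strains, genes, X)
    phenotypes = [
        StrainPhenotype(s, float(yv), int(nv)) for s, yv, nv in zip(strains, y, n_cells)
    ]
    truth = ScreenTruth(
        drivers={genes[j]: float(b) for j, b in zip(driver_idx, betas)},
        sigma=float(sigma),
        cellcount_range=(int(lo), int(hi)),
        seed=int(seed),
    )
    return compendium, phenotypes, truth


from functools import lru_cache


@lru_cache(maxsize=64)
def _gompertz_shape_for_cv(cv: float) -> float:
    """Gompertz shape parameter whose coefficient of variation equals cv.

    The Gompertz CV (scale-free) increases monotonically with the shape
    parameter from near 0 toward 1 (the exponential limit); a target
    outside the attainable range raises.
    """
    if not (0 < cv < 1):
        raise ValueError(f"dispersion (CV) must lie in (0, 1), got {cv}")

    def f(log_c: float) -> float:
        m, v = stats.gompertz.stats(np.exp(log_c), moments="mv")
        return float(np.sqrt(v) / m) - cv

    lo, hi = np.log(1e-8), np.log(1e4)
    flo, fhi = f(lo), f(hi)
    if not (flo < 0 < fhi):
        raise ValueError(f"dispersion {cv} not attainable by a Gompertz distribution")
    return float(np.exp(optimize.brentq(f, lo, hi, xtol=1e-12)))


def simulate_lifespan_cohort(
    group_means: Mapping[str, float],
    ns: Mapping[str, int] | int,
    dispersion: float = 0.25,
    censor_frac: float = 0.0,
    seed: int = 0,
) -> list[LifespanRecord]:
    """Simulate lifespan cohorts with given group means.

    Lifespans are Gompertz with the shape fixed by ``dispersion`` (the
    coefficient of variation) and the scale solved so the distribution
    mean equals each group's target.  With probability ``censor_frac`` an
    individual is right-censored at a uniform time before its death.
    """
    if not (0 <= censor_frac < 1):
        raise ValueError("censor_frac must lie in [0, 1)")
    c = _gompertz_shape_for_cv(dispersion)
    unit_mean = float(stats.gompertz.mean(c))
    rng = np.random.default_rng(seed)
    records: list[LifespanRecord] = []
    for group, mean in group_means.items():
        if not mean > 0:
            raise ValueError(f"group {group!r}: target mean must be positive")
        n = ns if isinstance(ns, int) else ns[group]
        if n < 1:
            raise ValueError(f"group {group!r}: n must be >= 1")
        t = stats.gompertz.rvs(c, scale=mean / unit_mean, size=n, random_state=rng)
        censored = rng.random(n) < censor_frac
        u = rng.random(n)
        for ti, ci, ui in zip(t, censored, u):
            if ci:
                records.append(LifespanRecord(group, float(ti * ui) or float(ti) * 0.5, observed=False))
            else:
                records.append(LifespanRecord(group, float(ti), observed=True))
    return records


def simulate_expression_experiment(
    G: int = 2000,
    n_reps: int = 4,
    baseline_lognormal_params: tuple[float, float] = (2.0, 2.2),
    n_deg: int = 100,
    deg_lfc: float = 2.0,
    down_frac: float = 0.6,
    rep_noise_sd: float = 0.2,
    promoter_model: Mapping[str, float] | None = None,
    term_model: Mapping[str, float] | None = None,
    abundance_down_bias: float = 0.0,
    seed: int = 0,
) -> tuple[list[GeneExpressionRecord], list[PromoterAnnotation], dict[str, list[str]], ExperimentTruth]:
    """Simulate a two-group replicate FPKM experiment with planted structure.

    Baseline FPKM is log-normal (natural-log parameters
    ``baseline_lognormal_params``), heavy-tailed so the top of the
    spectrum exceeds 5000 total FPKM across replicates.  ``n_deg`` genes
    with baseline >= 10 FPKM are planted as DEGs with |log2fc| =
    ``deg_lfc``; a fraction ``down_frac`` are down-regulated (with
    ``abundance_down_bias`` > 0 the probability of being down rises with
    log10 baseline abundance).  Replicate noise is multiplicative
    log-normal with natural-log sd ``rep_noise_sd``.

    Promoter states are Bernoulli-active with probability
    ``sigmoid(slope * (log10(baseline + 1) - center))`` plus
    ``down_boost`` for planted-down genes.  Terms: ``n_terms`` random
    background terms of size ``term_size`` plus one planted term holding
    ``planted_down`` planted-down genes (the enriched term).
    """
    if n_reps < 2:
        raise ValueError("need at least 2 replicates per group")
    if not (0 <= down_frac <= 1):
        raise ValueError("down_frac must lie in [0, 1]")
    if deg_lfc == 0 and n_deg > 0:
        raise ValueError("planted DEGs need a nonzero log2 fold change")
    pm = {"slope": 1.5, "center": 1.0, "down_boost": 0.35}
    pm.update(promoter_model or {})
    tm = {"n_terms": 50, "term_size": 30, "planted_down": 20}
    tm.update(term_model or {})

    rng = np.random.default_rng(seed)
    genes = [f"g{j:05d}" for j in range(G)]
    mu, sg = baseline_lognormal_params
    baseline = rng.lognormal(mean=mu, sigma=sg, size=G)

    eligible = np.flatnonzero(baseline >= 10.0)
    if n_deg > eligible.size:
        raise ValueError(
            f"cannot plant {n_deg} DEGs: only {eligible.size} genes with baseline >= 10 FPKM"
        )
    deg_idx = rng.choice(eligible, size=n_deg, replace=False)
    if abundance_down_bias > 0:
        z = abundance_down_bias * (np.log10(baseline[deg_idx] + 1) - 1.5)
        p_down = 1.0 / (1.0 + np.exp(-(np.log(down_frac / (1 - down_frac)) + z)))
        down = rng.random(n_deg) < p_down
    else:
        down = rng.random(n_deg) < down_frac
    lfc = np.zeros(G)
    lfc[deg_idx] = np.where(down, -deg_lfc, deg_lfc)

    treat_mean = baseline * np.power(2.0, lfc)
    noise_c = rng.lognormal(mean=0.0, sigma=rep_noise_sd, size=(G, n_reps))
    noise_t = rng.lognormal(mean=0.0, sigma=rep_noise_sd, size=(G, n_reps))
    fpkm_c = baseline[:, None] * noise_c
    fpkm_t = treat_mean[:, None] * noise_t

    records = [
        GeneExpressionRecord(g, fpkm_control=fpkm_c[j], fpkm_treatment=fpkm_t[j])
        for j, g in enumerate(genes)
    ]

    # promoter states: activity rises with abundance, boosted for planted-down
    logit = pm["slope"] * (np.log10(baseline + 1.0) - pm["center"])
    p_active = 1.0 / (1.0 + np.exp(-logit))
    down_set = {genes[j] for j, d in zip(deg_idx, down) if d}
    for j, g in enumerate(genes):
        if g in down_set:
            p_active[j] = min(1.0, p_active[j] + pm["down_boost"])
    active = rng.random(G) < p_active
    annotations = [
        PromoterAnnotation(g, "active" if a else "inactive") for g, a in zip(genes, active)
    ]

    # term annotation: random background terms + one planted enriched term
    gene_terms: dict[str, list[str]] = {g: [] for g in genes}
    n_terms, term_size = int(tm["n_terms"]), int(tm["term_size"])
    for t in range(n_terms):
        members = rng.choice(G, size=min(term_size, G), replace=False)
        for j in members:
            gene_terms[genes[j]].append(f"term{t:03d}")
    enriched_term = "term_planted"
    down_list = sorted(down_set)
    k_down = min(int(tm["planted_down"]), len(down_list))
    planted_members = list(rng.choice(len(down_list), size=k_down, replace=False))
    members = {down_list[i] for i in planted_members}
    others = [g for g in genes if g not in members]
    extra = rng.choice(len(others), size=max(0, term_size - len(members)), replace=False)
    members |= {others[i] for i in extra}
    for g in members:
        gene_terms[g].append(enriched_term)

    truth = ExperimentTruth(
        planted_lfc={genes[j]: float(lfc[j]) for j in deg_idx},
        baseline_fpkm={g: float(b) for g, b in zip(genes, baseline)},
        active_probability={g: float(p) for g, p in zip(genes, p_active)},
        enriched_term=enriched_term,
        seed=int(seed),
    )
    return records, annotations, gene_terms, truth
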