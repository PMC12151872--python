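"""Differential-expression calling and stratification analyses.

DEGs are genes with |log2FC| > 1 and Benjamini-Hochberg adjusted p < 0.05
(both thresholds configurable).  On top of the called sets this module
implements the stratification analyses used to characterise a knockdown
transcriptome:

* promoter transcriptional-state enrichment — do down-regulated DEGs have
  active promoters more often than up-regulated ones? (2x2 chi-square)
* abundance binning — genes grouped by total control FPKM into low /
  middle / high / extremely-high (total FPKM > 5000) classes, with the
  up/down DEG ratio per class;
* shared DEGs across tissues (Venn regions and subset intersections);
* Fisher-exact gene-set enrichment with BH correction.

Per-gene differential tests may be supplied precomputed (preferred, e.g.
from a dedicated DE caller); the built-in fallback is a Welch two-sample
t test on log2(FPKM + 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneExpressionRecord",
    "DEGSet",
    "PromoterAnnotation",
    "AbundanceBinning",
    "EnrichmentResult",
    "PromoterEnrichment",
    "two_group_gene_test",
    "bh_adjust",
    "call_degs",
    "promoter_state_enrichment",
    "chi_square_2x2",
    "assign_abundance_bins",
    "updown_ratio_by_bin",
    "shared_degs",
    "fisher_enrichment",
]

ABUNDANCE_BINS = ("low", "middle", "high", "extremely_high")


@dataclass
class GeneExpressionRecord:
    """Per-gene FPKM replicates for control and treatment groups.

    ``log2fc``, ``p_value`` and ``q_value`` may be supplied precomputed;
    otherwise :func:`two_group_gene_test` fills log2fc and p.
    """

    gene_id: str
    fpkm_control: np.ndarray | None = None
    fpkm_treatment: np.ndarray | None = None
    log2fc: float = np.nan
    p_value: float = np.nan
    q_value: float = np.nan

    def __post_init__(self):
        for attr in ("fpkm_control", "fpkm_treatment"):
            v = getattr(self, attr)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if np.any(v < 0):
                    raise ValueError(f"{self.gene_id}: FPKM must be non-negative")
                setattr(self, attr, v)

    @property
    def total_control_fpkm(self) -> float:
        if self.fpkm_control is None:
            raise ValueError(f"{self.gene_id}: no control FPKM replicates")
        return float(self.fpkm_control.sum())


@dataclass
class DEGSet:
    """Up- and down-regulated gene sets for one tissue/contrast."""

    tissue: str
    up: set
    down: set
    thresholds: tuple = (1.0, 0.05)

    def __post_init__(self):
        if self.up & self.down:
            raise ValueError("up and down DEG sets must be disjoint")

    @property
    def n_up(self) -> int:
        return len(self.up)

    @property
    def n_down(self) -> int:
        return len(self.down)


@dataclass(frozen=True)
class PromoterAnnotation:
    """Active/inactive transcriptional state of a gene's promoter."""

    gene_id: str
    state: str

    def __post_init__(self):
        if self.state not in ("active", "inactive"):
            raise ValueError(f"{self.gene_id}: state must be 'active' or 'inactive'")


@dataclass(frozen=True)
class AbundanceBinning:
    """Bin edges on total control FPKM.

    ``edges = (e1, e2, extreme)``: low <= e1 < middle <= e2 < high <= extreme
    < extremely_high.  The extremely-high class is *strictly* above its
    edge (default 5000).
    """

    edges: tuple

    def __post_init__(self):
        e = tuple(float(v) for v in self.edges)
        if len(e) != 3 or not (e[0] < e[1] < e[2]):
            raise ValueError(f"bin edges must be 3 strictly increasing values, got {self.edges}")
        object.__setattr__(self, "edges", e)

    @classmethod
    def from_totals(cls, totals: Iterable[float], extreme: float = 5000.0) -> "AbundanceBinning":
        """Default edges: tertiles of the totals not exceeding ``extreme``."""
        t = np.asarray(list(totals), dtype=float)
        body = t[t <= extreme]
        if body.size == 0:
            raise ValueError("no totals at or below the extreme edge")
        e1, e2 = np.quantile(body, [1 / 3, 2 / 3])
        if not (e1 < e2 < extreme):
            raise ValueError("degenerate totals: tertile edges are not strictly increasing")
        return cls((float(e1), float(e2), float(extreme)))

    def assign(self, total: float) -> str:
        e1, e2, ex = self.edges
        if total > ex:
            return "extremely_high"
        if total > e2:
            return "high"
        if total > e1:
            return "middle"
        return "low"


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    overlap: int
    term_size: int
    set_size: int
    background_size: int
    odds_ratio: float
    p_value: float
    q_value: float


def two_group_gene_test(record: GeneExpressionRecord) -> GeneExpressionRecord:
    """Welch two-sample t test on log2(FPKM + 1); fills log2fc and p in place.

    log2fc = mean(log2(treatment + 1)) - mean(log2(control + 1)).
    Requires >= 2 replicates per group.
    """
    if record.fpkm_control is None or record.fpkm_treatment is None:
        raise ValueError(
            f"{record.gene_id}: replicate FPKM absent; supply precomputed p-values instead"
        )
    if record.fpkm_control.size < 2 or record.fpkm_treatment.size < 2:
        raise ValueError(
            f"{record.gene_id}: need >= 2 replicates per group for the built-in test; "
            "supply precomputed p-values otherwise"
        )
    lc = np.log2(record.fpkm_control + 1.0)
    lt = np.log2(record.fpkm_treatment + 1.0)
    record.log2fc = float(lt.mean() - lc.mean())
    if np.ptp(lc) == 0 and np.ptp(lt) == 0:
        record.p_value = 1.0 if lc.mean() == lt.mean() else 0.0
    else:
        record.p_value = float(stats.ttest_ind(lt, lc, equal_var=False).pvalue)
    return record


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    records: Sequence[GeneExpressionRecord],
    tissue: str = "",
    lfc_cut: float = 1.0,
    alpha: float = 0.05,
) -> DEGSet:
    """Call DEGs at |log2fc| > lfc_cut and BH-adjusted p < alpha.

    Records missing log2fc/p are first run through the built-in Welch
    test; q-values are computed across the supplied records when absent.
    """
    records = list(records)
    for r in records:
        if not np.isfinite(r.p_value) or not np.isfinite(r.log2fc):
            two_group_gene_test(r)
    if any(not np.isfinite(r.q_value) for r in records):
        if records:
            q = bh_adjust([r.p_value for r in records])
            for r, qv in zip(records, q):
                r.q_value = float(qv)
    up = {r.gene_id for r in records if r.log2fc > lfc_cut and r.q_value < alpha}
    down = {r.gene_id for r in records if r.log2fc < -lfc_cut and r.q_value < alpha}
    return DEGSet(tissue=tissue, up=up, down=down, thresholds=(lfc_cut, alpha))


def chi_square_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 table, 1 df."""
    counts = np.array([[a, b], [c, d]], dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("chi-square undefined: zero row or column margin")
    stat, p, _, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), float(p)


@dataclass
class PromoterEnrichment:
    """Promoter-state composition of up vs down DEGs.

    ``chi_square``/``p_value`` are NaN when a margin of the 2x2 table is
    zero (test undefined); the proportions are still reported.
    """

    prop_active_up: float
    prop_active_down: float
    counts: pd.DataFrame  # direction x state
    chi_square: float
    p_value: float
    n_unannotated: int


def promoter_state_enrichment(
    degset: DEGSet, annotation: Sequence[PromoterAnnotation] | Mapping[str, str]
) -> PromoterEnrichment:
    """Active-promoter proportions among up and down DEGs plus a 2x2 test.

    Unannotated DEGs are excluded from the table and counted separately.
    """
    if isinstance(annotation, Mapping):
        states = dict(annotation)
    else:
        states = {a.gene_id: a.state for a in annotation}
    table = np.zeros((2, 2), dtype=int)  # rows: up, down; cols: active, inactive
    unannotated = 0
    for i, genes in enumerate((degset.up, degset.down)):
        for g in genes:
            s = states.get(g)
            if s is None:
                unannotated += 1
            else:
                table[i, 0 if s == "active" else 1] += 1
    n_up, n_down = table.sum(axis=1)
    prop_up = table[0, 0] / n_up if n_up else np.nan
    prop_down = table[1, 0] / n_down if n_down else np.nan
    try:
        chi2, p = chi_square_2x2(*table.ravel())
    except ValueError:
        chi2, p = np.nan, np.nan
    counts = pd.DataFrame(table, index=["up", "down"], columns=["active", "inactive"])
    return PromoterEnrichment(
        prop_active_up=float(prop_up),
        prop_active_down=float(prop_down),
        counts=counts,
        chi_square=chi2,
        p_value=p,
        n_unannotated=unannotated,
    )


def assign_abundance_bins(
    records: Sequence[GeneExpressionRecord] | Mapping[str, float],
    binning: AbundanceBinning | None = None,
    extreme: float = 5000.0,
) -> tuple[dict, AbundanceBinning]:
    """Map each gene to an abundance bin from its total control FPKM.

    ``extremely_high`` iff total > the extreme edge (strict; 5000 by
    default).  When no binning is given, the low/middle/high edges default
    to tertiles of totals at or below the extreme edge.
    """
    if isinstance(records, Mapping):
        totals = {g: float(t) for g, t in records.items()}
    else:
        totals = {r.gene_id: r.total_control_fpkm for r in records}
    if binning is None:
        binning = AbundanceBinning.from_totals(totals.values(), extreme=extreme)
    return {g: binning.assign(t) for g, t in totals.items()}, binning


def updown_ratio_by_bin(degset: DEGSet, bins: Mapping[str, str]) -> pd.DataFrame:
    """Per-bin counts of up/down DEGs and their ratio (NaN when n_down=0)."""
    rows = []
    for b in ABUNDANCE_BINS:
        n_up = sum(1 for g in degset.up if bins.get(g) == b)
        n_down = sum(1 for g in degset.down if bins.get(g) == b)
        ratio = n_up / n_down if n_down else np.nan
        rows.append({"bin": b, "n_up": n_up, "n_down": n_down, "ratio": ratio})
    return pd.DataFrame(rows)


def shared_degs(degsets: Sequence[DEGSet]) -> pd.DataFrame:
    """Venn table of DEG overlaps across tissues, separately for up and down.

    For every non-empty subset of tissues, reports the intersection size
    over the subset and the exclusive Venn-region size (genes in exactly
    that subset).  Region sizes over one direction sum to the union size.
    """
    tissues = [d.tissue for d in degsets]
    if len(set(tissues)) != len(tissues):
        raise ValueError("duplicate tissue labels")
    if len(degsets) < 2:
        raise ValueError("need at least two tissues to intersect")
    rows = []
    for direction in ("up", "down"):
        sets = {d.tissue: getattr(d, direction) for d in degsets}
        for k in range(1, len(tissues) + 1):
            for combo in itertools.combinations(tissues, k):
                inter = set.intersection(*(sets[t] for t in combo))
                exclusive = inter - set().union(*(sets[t] for t in tissues if t not in combo))
                rows.append(
                    {
                        "direction": direction,
                        "tissues": "&".join(combo),
                        "n_tissues": k,
                        "intersection": len(inter),
                        "exclusive": len(exclusive),
                    }
                )
    return pd.DataFrame(rows)


def fisher_enrichment(
    query: set,
    annotation: Mapping[str, Iterable[str]],
    background: set,
) -> list[EnrichmentResult]:
    """One-sided Fisher-exact (hypergeometric tail) term enrichment with BH.

    ``annotation`` maps gene -> iterable of term ids; terms are tested
    against the background universe; results are sorted by p.
    """
    query = set(query)
    background = set(background)
    stray = query - background
    if stray:
        raise ValueError(f"query genes outside background: {sorted(stray)[:5]}")
    term_genes: dict[str, set] = {}
    for gene, terms in annotation.items():
        if gene not in background:
            continue
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)

    N, n = len(background), len(query)
    raw = []
    for term, genes in sorted(term_genes.items()):
        K = len(genes)
        k = len(genes & query)
        # hypergeometric upper tail: P(X >= k)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        a, b_, c, d = k, n - k, K - k, N - n - K + k
        if b_ * c == 0:
            odds = np.inf if a * d > 0 else 0.0
        else:
            odds = a * d / (b_ * c)
        raw.append((term, k, K, p, odds))
    q = bh_adjust([r[3] for r in raw]) if raw else np.array([])
    out = [
        EnrichmentResult(
            term_id=term,
            overlap=k,
            term_size=K,
            set_size=n,
            background_size=N,
            odds_ratio=float(odds),
            p_value=p,
            q_value=float(qv),
        )
        for (term, k, K, p, odds), qv in zip(raw, q)
    ]
    out.sort(key=lambda r: (r.p_value, r.term_id))
    return out
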