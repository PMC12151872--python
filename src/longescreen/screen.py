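"""Weighted-regression screen for longevity genes.

The screen asks, for each gene *j* in a knockout expression compendium,
whether its expression change across mutant strains predicts the strains'
replicative-lifespan change.  For strain *i* with lifespan change ``y_i``
(percent relative to wild type) and expression log2 fold-change ``x_ij``,
the per-gene fit minimises the weighted cost

    sum_i  w_i * (y_i - (b0 + b1_j * x_ij))**2

with precision weights ``w_i = n_i / (n_i + offset)`` derived from the
number of cells ``n_i`` dissected in strain *i*'s lifespan assay (more
cells -> more reliable lifespan estimate -> larger weight; ``offset``
defaults to 50).  Genes are ranked by the p-value of the slope ``b1_j``.

Inference on the slope uses standard weighted-least-squares theory:
``Var(b1) = sigma2 / S_xx_w`` with ``sigma2 = RSS_w / (m - 2)``, a
two-sided t test on ``m - 2`` degrees of freedom, where ``m`` is the
number of strains entering that gene's fit.  This makes every statistic
invariant to rescaling all weights by a positive constant.

The model/results pair :class:`LongevityScreen` / :class:`ScreenResults`
is the main entry point; the module-level functions expose the individual
steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .degs import bh_adjust

__all__ = [
    "WeightScheme",
    "StrainPhenotype",
    "ExpressionCompendium",
    "RegressionFit",
    "GeneScreenResult",
    "SkippedGene",
    "LongevityScreen",
    "ScreenResults",
    "lifespan_weight",
    "fit_weighted_line",
    "screen_genes",
    "rank_by_p",
]


@dataclass(frozen=True)
class WeightScheme:
    """Cell-count weighting ``w = n / (n + offset)``; ``offset`` > 0."""

    offset: float = 50.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.offset) or self.offset <= 0:
            raise ValueError(f"weight offset must be positive, got {self.offset}")


@dataclass(frozen=True)
class StrainPhenotype:
    """One strain's lifespan phenotype.

    ``lifespan_change`` is the percent change of replicative lifespan
    relative to the wild-type strain; ``n_cells`` is the number of mother
    cells dissected in the assay.
    """

    strain_id: str
    lifespan_change: float
    n_cells: int

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValueError(f"{self.strain_id}: n_cells must be >= 0")
        if not np.isfinite(self.lifespan_change):
            raise ValueError(f"{self.strain_id}: lifespan_change must be finite")


class ExpressionCompendium:
    """Strain x gene matrix of expression log2 fold-changes vs wild type.

    Backed by a pandas DataFrame with strains as rows and genes as
    columns; NaN marks missing measurements.
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            raise ValueError("duplicate strain ids in compendium")
        if values.columns.has_duplicates:
            raise ValueError("duplicate gene ids in compendium")
        self.values = values.astype(float)

    @property
    def strains(self) -> list[str]:
        return list(self.values.index)

    @property
    def genes(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def from_arrays(
        cls,
        strains: Sequence[str],
        genes: Sequence[str],
        matrix: np.ndarray,
    ) -> "ExpressionCompendium":
        return cls(pd.DataFrame(np.asarray(matrix, dtype=float), index=list(strains), columns=list(genes)))


@dataclass(frozen=True)
class RegressionFit:
    intercept: float
    slope: float
    slope_se: float
    t_stat: float
    p_value: float
    df: int
    weighted_rss: float


@dataclass
class GeneScreenResult:
    gene_id: str
    intercept: float
    slope: float
    slope_se: float
    t_stat: float
    p_value: float
    n_strains_used: int
    q_value: float = np.nan
    rank: int = 0


@dataclass(frozen=True)
class SkippedGene:
    gene_id: str
    reason: str


def lifespan_weight(n_cells, scheme: WeightScheme = WeightScheme()) -> np.ndarray | float:
    """Reliability weight for a lifespan measurement: ``n / (n + offset)``.

    0 for n=0, strictly increasing in n, approaches 1 as n grows.
    Accepts scalars or arrays.
    """
    n = np.asarray(n_cells, dtype=float)
    if np.any(n < 0):
        raise ValueError("n_cells must be non-negative")
    w = n / (n + scheme.offset)
    return float(w) if np.isscalar(n_cells) or w.ndim == 0 else w


def fit_weighted_line(x, y, w) -> RegressionFit:
    """Weighted least-squares line minimising ``sum w_i (y_i - b0 - b1 x_i)^2``.

    Closed-form solution of the weighted normal equations, with x centred
    at its weighted mean for numerical stability.  Returns slope/intercept,
    the slope's standard error, t statistic and two-sided p on m-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (x.shape == y.shape == w.shape) or x.ndim != 1:
        raise ValueError("x, y, w must be 1-D arrays of equal length")
    m = x.size
    if m < 3:
        raise ValueError(f"need at least 3 points for a weighted line fit, got {m}")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("all weights must be positive and finite")
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all x values identical")

    sw = w.sum()
    xw = (w * x).sum() / sw
    yw = (w * y).sum() / sw
    xc = x - xw
    sxx = (w * xc * xc).sum()
    slope = (w * xc * y).sum() / sxx
    intercept = yw - slope * xw

    resid = y - intercept - slope * x
    rss_w = float((w * resid * resid).sum())
    df = m - 2
    sigma2 = rss_w / df
    slope_se = float(np.sqrt(sigma2 / sxx))

    if slope_se == 0.0:
        # perfect fit: a zero slope carries no association (t=0, p=1); a
        # nonzero slope on a zero-residual line is infinitely significant
        t_stat = 0.0 if slope == 0.0 else np.inf * np.sign(slope)
        p_value = 1.0 if slope == 0.0 else 0.0
    else:
        t_stat = float(slope / slope_se)
        p_value = float(2.0 * stats.t.sf(abs(t_stat), df))

    return RegressionFit(
        intercept=float(intercept),
        slope=float(slope),
        slope_se=slope_se,
        t_stat=float(t_stat),
        p_value=p_value,
        df=df,
        weighted_rss=rss_w,
    )


def rank_by_p(results: Sequence[GeneScreenResult]) -> list[GeneScreenResult]:
    """Order results by ascending p, ties by larger |slope| then gene id.

    Returns a new list with ``rank`` populated 1..K.
    """
    ordered = sorted(results, key=lambda r: (r.p_value, -abs(r.slope), r.gene_id))
    for i, r in enumerate(ordered, start=1):
        r.rank = i
    return ordered


class LongevityScreen:
    """Model object joining a knockout expression compendium to per-strain
    lifespan phenotypes for the gene-by-gene weighted regression screen.

    Parameters
    ----------
    compendium :
        Strain x gene log2 fold-change matrix (NaN = missing).
    phenotypes :
        Per-strain lifespan change (percent vs WT) and assay cell counts.
    weight_scheme :
        Cell-count weighting; default offset 50.
    min_strains :
        Minimum number of strains with non-missing expression for a gene
        to be fitted (default 10); genes below it are reported as skipped.

    Only strains present in both inputs are used.
    """

    def __init__(
        self,
        compendium: ExpressionCompendium,
        phenotypes: Sequence[StrainPhenotype],
        weight_scheme: WeightScheme = WeightScheme(),
        min_strains: int = 10,
    ):
        self.compendium = compendium
        self.weight_scheme = weight_scheme
        self.min_strains = int(min_strains)

        pheno = {p.strain_id: p for p in phenotypes}
        if len(pheno) != len(phenotypes):
            raise ValueError("duplicate strain ids in phenotypes")
        common = [s for s in compendium.strains if s in pheno]
        if not common:
            raise ValueError("no strains shared between compendium and phenotypes")
        self.strains = common
        self.y = np.array([pheno[s].lifespan_change for s in common])
        self.n_cells = np.array([pheno[s].n_cells for s in common])
        self.weights = lifespan_weight(self.n_cells.astype(float), weight_scheme)
        self.X = compendium.values.loc[common]

    @classmethod
    def from_dataframes(
        cls,
        compendium: pd.DataFrame,
        phenotypes: pd.DataFrame,
        weight_scheme: WeightScheme = WeightScheme(),
        min_strains: int = 10,
    ) -> "LongevityScreen":
        """Build from a strain x gene DataFrame and a phenotype table with
        columns ``strain_id``, ``lifespan_change_pct``, ``n_cells``."""
        phen = [
            StrainPhenotype(str(r.strain_id), float(r.lifespan_change_pct), int(r.n_cells))
            for r in phenotypes.itertuples(index=False)
        ]
        return cls(ExpressionCompendium(compendium), phen, weight_scheme, min_strains)

    def fit(self) -> "ScreenResults":
        results: list[GeneScreenResult] = []
        skipped: list[SkippedGene] = []
        Xv = self.X.to_numpy()
        for k, gene in enumerate(self.X.columns):
            col = Xv[:, k]
            mask = np.isfinite(col)
            m = int(mask.sum())
            if m == 0:
                skipped.append(SkippedGene(gene, "all expression values missing"))
                continue
            if m < max(self.min_strains, 3):
                skipped.append(SkippedGene(gene, f"only {m} strains with data (< {max(self.min_strains, 3)})"))
                continue
            xs = col[mask]
            if np.ptp(xs) == 0:
                skipped.append(SkippedGene(gene, "constant expression across strains"))
                continue
            fit = fit_weighted_line(xs, self.y[mask], self.weights[mask])
            results.append(
                GeneScreenResult(
                    gene_id=gene,
                    intercept=fit.intercept,
                    slope=fit.slope,
                    slope_se=fit.slope_se,
                    t_stat=fit.t_stat,
                    p_value=fit.p_value,
                    n_strains_used=m,
                )
            )
        if results:
            q = bh_adjust(np.array([r.p_value for r in results]))
            for r, qv in zip(results, q):
                r.q_value = float(qv)
        results = rank_by_p(results)
        return ScreenResults(self, results, skipped)


@dataclass
class ScreenResults:
    """Fitted screen: ranked per-gene regressions plus skipped genes."""

    model: LongevityScreen
    results: list[GeneScreenResult] = field(default_factory=list)
    skipped: list[SkippedGene] = field(default_factory=list)

    @property
    def frame(self) -> pd.DataFrame:
        """Ranked results as a DataFrame (one row per fitted gene)."""
        return pd.DataFrame(
            [
                {
                    "rank": r.rank,
                    "gene_id": r.gene_id,
                    "slope": r.slope,
                    "intercept": r.intercept,
                    "slope_se": r.slope_se,
                    "t_stat": r.t_stat,
                    "p_value": r.p_value,
                    "q_value": r.q_value,
                    "n_strains_used": r.n_strains_used,
                }
            for r in self.results
            ]
        )

    def top(self, k: int = 10) -> pd.DataFrame:
        return self.frame.head(k)

    def summary(self, k: int = 10) -> str:
        lines = [
            "Longevity gene screen (weighted least squares)",
            f"  strains used: {len(self.model.strains)}"
            f"   genes fitted: {len(self.results)}   skipped: {len(self.skipped)}",
            f"  weight offset: {self.model.weight_scheme.offset:g}"
            f"   min strains/gene: {self.model.min_strains}",
            "",
            self.top(k).to_string(index=False),
        ]
        return "\n".join(lines)

    def plot_pvalues(self, ax=None):
        """Rank vs -log10 p scatter of the screened genes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        f = self.frame
        ax.scatter(f["rank"], -np.log10(np.clip(f["p_value"], 1e-300, None)), s=8)
        ax.set_xlabel("gene rank")
        ax.set_ylabel("-log10 p")
        return ax


def screen_genes(
    compendium: ExpressionCompendium,
    phenotypes: Sequence[StrainPhenotype],
    scheme: WeightScheme = WeightScheme(),
    min_strains: int = 10,
) -> ScreenResults:
    """Functional wrapper: build a :class:`LongevityScreen` and fit it."""
    return LongevityScreen(compendium, phenotypes, scheme, min_strains).fit()
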