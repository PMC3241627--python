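"""Per-tissue two-group differential expression.

Expression values are assumed log2-scale. Fold change is geometric:
``log2FC = mean(tumor) - mean(normal)`` and ``FC = 2**log2FC``. P-values
come from the unequal-variance (Welch) two-sample t statistic and are
adjusted across all genes of one table by Benjamini–Hochberg step-up;
the filter keeps up-regulated genes with ``q < fdr_max`` (strict) and
``FC >= fc_min``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionTable

__all__ = ["DEResult", "DEFilterConfig", "fold_change", "de_test", "filter_de",
           "merge_dataset_lists", "results_to_frame"]


@dataclass(frozen=True)
class DEResult:
    gene: str
    log2fc: float
    fold_change: float
    t_stat: float
    p_value: float
    q_value: float


@dataclass(frozen=True)
class DEFilterConfig:
    """Cut-offs for the up-regulated gene filter.

    fdr_max : keep genes with BH q strictly below this (default 0.05)
    fc_min  : minimum linear fold change, inclusive (default 2.0)
    direction : which tail to keep; ``up`` keeps FC >= fc_min, ``down``
        keeps FC <= 1/fc_min, ``both`` keeps either
    """

    fdr_max: float = 0.05
    fc_min: float = 2.0
    direction: str = "up"

    def __post_init__(self) -> None:
        if not 0 < self.fdr_max <= 1:
            raise ValueError(f"fdr_max must be in (0, 1], got {self.fdr_max}")
        if self.fc_min < 1:
            raise ValueError(f"fc_min must be >= 1, got {self.fc_min}")
        if self.direction not in ("up", "down", "both"):
            raise ValueError(f"direction must be up/down/both, got {self.direction!r}")


def fold_change(tumor_values, normal_values) -> tuple[float, float]:
    """Geometric fold change on log2 data: (log2fc, linear fold change)."""
    tumor = np.asarray(tumor_values, dtype=float)
    normal = np.asarray(normal_values, dtype=float)
    if tumor.size == 0 or normal.size == 0:
        raise ValueError("both groups must be non-empty")
    log2fc = float(tumor.mean() - normal.mean())
    return log2fc, float(2.0 ** log2fc)


def de_test(table: ExpressionTable) -> list[DEResult]:
    """Welch t-test per gene with BH adjustment across the whole table.

    Degenerate genes (zero variance in both groups and equal means) get
    t = 0, p = 1 by convention. P-values are clamped into (0, 1].
    """
    tumor = table.group_values("tumor")
    normal = table.group_values("normal")
    log2fc = tumor.mean(axis=1) - normal.mean(axis=1)
    import warnings

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # near-constant rows trigger a harmless precision warning; their
        # p-values are overridden by the degenerate-row convention below
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, p = stats.ttest_ind(tumor, normal, axis=1, equal_var=False)
    t_stat = np.asarray(t_stat, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(p)
    t_stat[~np.isfinite(t_stat)] = 0.0
    p[degenerate] = 1.0
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    q = multipletests(p, method="fdr_bh")[1]
    q = np.clip(q, p, 1.0)  # step-up guarantees q >= p; clip guards rounding
    return [
        DEResult(gene=g, log2fc=float(l), fold_change=float(2.0 ** l),
                 t_stat=float(t), p_value=float(pv), q_value=float(qv))
        for g, l, t, pv, qv in zip(table.genes, log2fc, t_stat, p, q)
    ]


def filter_de(results: list[DEResult], config: DEFilterConfig | None = None) -> set[str]:
    """Genes passing the FDR and fold-change cut-offs, deduplicated."""
    if not results:
        raise ValueError("results must be non-empty")
    config = config or DEFilterConfig()
    kept: set[str] = set()
    for r in results:
        if not r.q_value < config.fdr_max:
            continue
        up = r.fold_change >= config.fc_min
        down = r.fold_change <= 1.0 / config.fc_min
        if (config.direction == "up" and up) or (config.direction == "down" and down) \
                or (config.direction == "both" and (up or down)):
            kept.add(r.gene)
    return kept


def merge_dataset_lists(lists: list[set[str]]) -> set[str]:
    """Pool per-dataset filtered gene lists for one tissue (set union)."""
    if not lists:
        raise ValueError("need at least one gene list")
    return set().union(*lists)


def results_to_frame(results: list[DEResult]) -> pd.DataFrame:
    """DE results as a DataFrame (gene, log2fc, fold_change, t, p, q)."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "log2fc": [r.log2fc for r in results],
            "fold_change": [r.fold_change for r in results],
            "t_stat": [r.t_stat for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
        }
    )
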