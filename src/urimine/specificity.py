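"""N-way tissue-exclusivity comparison of up-regulated gene sets.

Candidate fluid markers must be specific to the tissue of interest:
a gene up-regulated in several tumor types of the same organ system
(here prostate, bladder, kidney — the tissues shedding into urine)
cannot discriminate between them. :func:`partition` computes the full
Venn decomposition of the per-tissue sets; :func:`unique_to` returns the
exclusive region of one tissue.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .io import normalize_symbol

__all__ = ["TissueGeneSets", "ExclusivityPartition", "partition", "unique_to",
           "summary_counts"]


@dataclass
class TissueGeneSets:
    """Ordered tissue names with one up-regulated gene set each."""

    tissues: list[str]
    sets: dict[str, set[str]]

    def __post_init__(self) -> None:
        if len(set(self.tissues)) != len(self.tissues):
            raise ValueError("tissue names must be unique")
        if len(self.tissues) < 2:
            raise ValueError("need at least two tissues to compare")
        missing = [t for t in self.tissues if t not in self.sets]
        if missing:
            raise ValueError(f"no gene set for tissues {missing}")
        self.sets = {t: {normalize_symbol(g) for g in self.sets[t]} for t in self.tissues}


@dataclass
class ExclusivityPartition:
    """Disjoint Venn regions keyed by the tissue subset sharing the genes."""

    tissues: list[str]
    regions: dict[frozenset[str], set[str]] = field(default_factory=dict)

    def region(self, *tissues: str) -> set[str]:
        return self.regions.get(frozenset(tissues), set())


def partition(sets: TissueGeneSets) -> ExclusivityPartition:
    """Full Venn partition: each gene lands in the region keyed by the exact
    subset of tissues whose sets contain it."""
    regions: dict[frozenset[str], set[str]] = {}
    universe = set().union(*sets.sets.values()) if sets.sets else set()
    for gene in universe:
        key = frozenset(t for t in sets.tissues if gene in sets.sets[t])
        regions.setdefault(key, set()).add(gene)
    # singleton regions always exist, possibly empty, for reporting
    for t in sets.tissues:
        regions.setdefault(frozenset([t]), set())
    return ExclusivityPartition(tissues=list(sets.tissues), regions=regions)


def unique_to(sets: TissueGeneSets, tissue: str) -> set[str]:
    """Genes in ``tissue``'s set and in no other tissue's set."""
    if tissue not in sets.tissues:
        raise KeyError(f"unknown tissue {tissue!r}; available: {sets.tissues}")
    others = set().union(*(sets.sets[t] for t in sets.tissues if t != tissue))
    return sets.sets[tissue] - others


def summary_counts(part: ExclusivityPartition) -> pd.DataFrame:
    """Per-region gene counts (the numbers behind a comparison pie chart).

    One row per non-empty region plus zero rows for empty singleton
    regions; counts sum to the size of the input union.
    """
    rows = []
    order = {t: i for i, t in enumerate(part.tissues)}
    for key, genes in part.regions.items():
        if genes or len(key) == 1:
            label = "&".join(sorted(key, key=order.get))
            rows.append({"region": label, "n_tissues": len(key), "count": len(genes)})
    df = pd.DataFrame(rows, columns=["region", "n_tissues", "count"])
    return df.sort_values(["n_tissues", "region"]).reset_index(drop=True)
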