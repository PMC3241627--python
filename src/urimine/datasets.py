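"""Packaged worked-example data.

Two small fixtures ship with the package:

* ``prostate_urine_markers.tsv`` — the 19-entity candidate urinary-marker
  table for prostate tumor (symbol, name, subcellular location, family,
  urine/blood presence flags, fold change, p-value). The table is
  transcribed verbatim, including the "hypothetical LOC151162" name on the
  MGAT5 row.
* ``subnetwork_centrality_scores.tsv`` — the published betweenness (BC)
  and closeness (CC) scores for the ten growth-pathway entities of the
  focused interaction subnetwork. The underlying edge set is not public,
  so these scores serve as *inputs* to the ranking rule, not as values the
  package recomputes.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

from .io import MarkerRecord, read_marker_table

__all__ = ["marker_table_path", "load_marker_table", "load_subnetwork_scores"]


def _data_path(name: str) -> Path:
    return Path(resources.files("urimine.data").joinpath(name))  # type: ignore[arg-type]


def marker_table_path() -> Path:
    """Path of the packaged 19-marker table fixture."""
    return _data_path("prostate_urine_markers.tsv")


def load_marker_table() -> list[MarkerRecord]:
    """The 19 candidate prostate-tumor urinary markers."""
    return read_marker_table(marker_table_path())


def load_subnetwork_scores() -> pd.DataFrame:
    """Published (betweenness, closeness) scores for the 10 subnetwork hubs.

    Returns a DataFrame with columns ``gene``, ``betweenness``,
    ``closeness``; use with :func:`urimine.network.prioritize_scores`.
    """
    return pd.read_csv(_data_path("subnetwork_centrality_scores.tsv"), sep="\t")
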