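"""Packaged study-summary fixtures.

The field genotypes themselves are not distributed, but the per-site count
table and the cross-landscape gene-flow records are, as plain CSVs. Site
centroids in ``sites.csv`` are synthetic placements on a 5 km line (the
source reports only inter-landscape distances in whole km), provided so the
site table parses into full records.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_site_counts", "load_geneflow_records", "packaged_sites_path"]


def _data_path(name: str):
    return resources.files("palmflow.data").joinpath(name)


def load_site_counts() -> pd.DataFrame:
    """Per-site adults/seedlings/assignment counts (nine sites)."""
    with resources.as_file(_data_path("site_counts.csv")) as p:
        return pd.read_csv(p, dtype={"site_id": str})


def load_geneflow_records() -> pd.DataFrame:
    """Cross-landscape assignments: covers, paternity probability, km."""
    with resources.as_file(_data_path("geneflow_records.csv")) as p:
        return pd.read_csv(p, dtype={"progeny_id": str, "parent_id": str})


def packaged_sites_path():
    """Path-like handle on the packaged site table CSV."""
    return _data_path("sites.csv")
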