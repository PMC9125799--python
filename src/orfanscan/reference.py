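"""Shipped reference measurements for the ormycovirus dataset.

Two small tables accompany the package so that the worked examples and the
acceptance computations run without any download:

* per-library stranded read-mapping tallies for every ormycovirus genome
  segment (plus- and minus-orientation read counts), and
* the qPCR Ct screen of the *Starmerella bacillaris* isolate collection
  (blank cells mean no amplification; decimal commas as exported).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import read_ct_table


def _data_path(name: str):
    return resources.files("orfanscan.data") / name


def load_strand_counts() -> pd.DataFrame:
    """Tidy per-(segment, library) plus/minus read tallies."""
    with resources.as_file(_data_path("ormycovirus_strand_counts.tsv")) as path:
        return pd.read_csv(path, sep="\t")


def load_counts_wide() -> pd.DataFrame:
    """Total read counts as a segments x libraries matrix."""
    tidy = load_strand_counts()
    tidy["total"] = tidy["plus"] + tidy["minus"]
    return tidy.pivot(index="segment", columns="library",
                      values="total").fillna(0.0)


def load_starmerella_ct() -> pd.DataFrame:
    """Ct table of the yeast isolate screen (NaN where blank)."""
    with resources.as_file(_data_path("starmerella_ct.csv")) as path:
        return read_ct_table(path)
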