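"""Published Barramundi Perch cohort composition and aggregation helpers.

The packaged table ``data/bp_cohort_groups.tsv`` records the sampling
design of the published Barramundi Perch (*Lates calcarifer*) cohort this
pipeline's synthetic generator emulates: per sampling region, the number
of samples, their genetic lineage (IND, SEA, AUS+NG) and data type
(WGS or RAD).  The aggregation helpers reproduce the cohort's headline
composition (total samples, per-lineage and per-data-type counts).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_cohort_groups() -> pd.DataFrame:
    """The packaged cohort design table (region, sample_size, lineage,
    data_type)."""
    with resources.files("invscan.data").joinpath("bp_cohort_groups.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def aggregate_cohort(groups: pd.DataFrame) -> dict[str, int]:
    """Totals over a cohort design table: overall, per lineage, per data
    type (keys like ``total``, ``lineage:SEA``, ``data_type:RAD``)."""
    out = {"total": int(groups["sample_size"].sum())}
    for lineage, n in groups.groupby("lineage")["sample_size"].sum().items():
        out[f"lineage:{lineage}"] = int(n)
    for dt, n in groups.groupby("data_type")["sample_size"].sum().items():
        out[f"data_type:{dt}"] = int(n)
    return out
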