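"""Packaged tabular fixtures: the published region, design-score, ΔRMSF and
hydrogen-bond-count tables for the α-L-rhamnosidase stability screen."""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import (DesignRecord, read_delta_rmsf_table, read_design_table,
                 read_region_table)
from .regions import FlexibleRegion

__all__ = [
    "table1_regions",
    "table1_region_objects",
    "table2_designs",
    "table3_delta_rmsf",
    "table5_hbond_counts",
    "CATALYTIC_RESIDUES",
    "C_TERMINUS_EXCLUSION",
]

#: Catalytic residues of the enzyme (Glu442 and Glu712).
CATALYTIC_RESIDUES = (442, 712)
#: C-terminal interval excluded from flexible-region calls.
C_TERMINUS_EXCLUSION = ((815, 843),)


def _path(name: str):
    return resources.files("flexiscreen").joinpath("data", name)


def table1_regions() -> pd.DataFrame:
    """The twelve highly flexible regions of the wild type (range, size, mean ± sd RMSF)."""
    with resources.as_file(_path("table1_regions.tsv")) as p:
        return read_region_table(p)


def table1_region_objects() -> list[FlexibleRegion]:
    return [
        FlexibleRegion(int(r.region), int(r.start_residue), int(r.end_residue),
                       float(r.mean_rmsf), float(r.sd_rmsf))
        for r in table1_regions().itertuples()
    ]


def table2_designs() -> list[DesignRecord]:
    """Per-position design scores (ΔΔG in REU) for the five selected regions."""
    with resources.as_file(_path("table2_designs.tsv")) as p:
        return read_design_table(p)


def table3_delta_rmsf() -> pd.DataFrame:
    """Replicate-averaged regional ΔRMSF (%) of the 21 simulated mutants."""
    with resources.as_file(_path("table3_delta_rmsf.tsv")) as p:
        return read_delta_rmsf_table(p)


def table5_hbond_counts() -> pd.DataFrame:
    """Published hydrogen-bond counts per strength class; ``-`` read as 0."""
    with resources.as_file(_path("table5_hbond_counts.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    for col in ("strong", "medium", "weak", "very_weak"):
        df[col] = df[col].replace("-", 0).astype(int)
    return df
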