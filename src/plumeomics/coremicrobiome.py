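"""Core plume microbiome: prevalence/abundance filtering and trait profiles.

A genus belongs to the core plume microbiome when it is present in more than
``prevalence_min`` of the plume samples (default > 0.66, strict) AND its mean
relative abundance across plume samples exceeds ``abundance_min`` (default
> 0.01, strict).  "Present" means abundance above ``presence_eps`` (default 0:
any nonzero abundance).  Background samples never enter the filter.

Core genera are joined to metabolic-trait profiles by the union rule: a trait
is present for a genus iff any MAG mapped to that genus encodes it; genera
with no mapped MAGs get an NA row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from ._tsv import read_tsv, write_tsv

DEFAULT_PREVALENCE_MIN = 0.66
DEFAULT_ABUNDANCE_MIN = 0.01


class ParameterError(ValueError):
    pass


@dataclass
class AbundanceTable:
    """Samples x genus relative abundances with per-sample class labels."""

    abundances: pd.DataFrame  # samples x genera, fractions
    labels: pd.Series         # "plume" | "background" per sample

    def __post_init__(self) -> None:
        if not self.abundances.index.equals(self.labels.index):
            raise ParameterError("abundances and labels must share the sample index")
        if (self.abundances < 0).any().any():
            raise ParameterError("negative abundances")
        sums = self.abundances.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=1e-6):
            bad = sums[~np.isclose(sums, 1.0, atol=1e-6)]
            raise ParameterError(f"sample rows must sum to 1: {dict(bad)}")

    @property
    def plume_samples(self) -> pd.DataFrame:
        return self.abundances[self.labels == "plume"]


@dataclass
class CoreMicrobiome:
    """Genera passing both core thresholds, with their plume statistics."""

    table: pd.DataFrame  # genus, prevalence, mean_abundance
    prevalence_min: float
    abundance_min: float

    @property
    def genera(self) -> list[str]:
        return list(self.table["genus"])


def identify_core_taxa(table: AbundanceTable,
                       prevalence_min: float = DEFAULT_PREVALENCE_MIN,
                       abundance_min: float = DEFAULT_ABUNDANCE_MIN,
                       presence_eps: float = 0.0) -> CoreMicrobiome:
    """Filter genera by strict prevalence and mean-abundance thresholds."""
    plume = table.plume_samples
    if plume.empty:
        raise ParameterError("no plume samples in the table")
    prevalence = (plume > presence_eps).mean(axis=0)
    mean_abundance = plume.mean(axis=0)
    keep = (prevalence > prevalence_min) & (mean_abundance > abundance_min)
    out = pd.DataFrame({
        "genus": plume.columns[keep],
        "prevalence": prevalence[keep].values,
        "mean_abundance": mean_abundance[keep].values,
    }).sort_values("mean_abundance", ascending=False).reset_index(drop=True)
    return CoreMicrobiome(table=out, prevalence_min=prevalence_min,
                          abundance_min=abundance_min)


def profile_core_metabolism(core: CoreMicrobiome,
                            mag_taxonomy: Mapping[str, str],
                            function_table) -> pd.DataFrame:
    """Presence/absence of metabolic traits per core genus (union over MAGs).

    ``function_table`` is a :class:`plumeomics.metaconnect.FunctionTable`.
    Genera with no mapped MAGs get an all-NA row.
    """
    functions = function_table.functions
    rows = []
    for genus in core.genera:
        mags = [m for m, g in mag_taxonomy.items()
                if g == genus and m in function_table.incidence.index]
        if not mags:
            rows.append({"genus": genus,
                         **{f: pd.NA for f in functions}})
            continue
        union = function_table.incidence.loc[mags].any(axis=0)
        rows.append({"genus": genus, **{f: bool(union[f]) for f in functions}})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# serialization


def write_abundance_table(table: AbundanceTable, path) -> None:
    df = table.abundances.copy()
    df.insert(0, "label", table.labels)
    df.insert(0, "sample", df.index)
    write_tsv(df, path)


def read_abundance_table(path) -> AbundanceTable:
    df = read_tsv(path).set_index("sample")
    labels = df.pop("label")
    return AbundanceTable(abundances=df.astype(float), labels=labels)


def write_core(core: CoreMicrobiome, path) -> None:
    df = core.table.copy()
    df["prevalence_min"] = core.prevalence_min
    df["abundance_min"] = core.abundance_min
    write_tsv(df, path)
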