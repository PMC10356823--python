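"""Shared TSV conventions: tab-separated, header line, missing values as "NA"."""

from __future__ import annotations

import pandas as pd

NA_REP = "NA"


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=NA_REP)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    # keep_default_na=False so that only the literal "NA" token is missing;
    # gene/taxon names like "None" or "nan" stay strings.
    return pd.read_csv(path, sep="\t", na_values=[NA_REP], keep_default_na=False, **kwargs)
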