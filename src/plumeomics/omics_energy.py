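"""Omics-weighted electron-donor energy attribution and taxon contributions.

Community energy is attributed to electron donors by combining marker-gene
weights (metagenomic coverage or metatranscriptomic TPM) with the free energy
of each catabolic reaction:

    contribution(d) ∝ sum over reactions r of donor d of
                      ( sum of marker-gene weight mapped to r ) * |min(0, dG_r)|

normalized to percent.  Only exergonic reactions contribute (clamped at zero).
The electron-acceptor balance is folded in by weighting O2-coupled reaction
terms by rho = O2 share and nitrate-coupled terms by (1 - rho); the default
rho is [O2] / ([O2] + [NO3-]) from the mixture state.

The module also houses the read-mapping normalization conventions: coverage
scaled to a 100M-read-pair dataset and TPM (transcripts per kilobase million)
per gene within each genome, and the per-function taxon-contribution shares
used to name a function's major microbial contributors (share > 10% flagged).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._tsv import read_tsv, write_tsv
from .geochem import CatabolicReaction, EnergyLandscape

NORMALIZATION_READ_PAIRS = 1e8
DEFAULT_SHARE_THRESHOLD = 0.10


class ParameterError(ValueError):
    pass


@dataclass
class DonorContribution:
    """Percent of community energy per electron donor."""

    percents: pd.Series  # donor -> percent; sums to 100 when any > 0
    basis: str           # "metagenome" (coverage) or "metatranscriptome" (TPM)
    rho: float | None = None
    skipped_functions: list[str] = field(default_factory=list)


def normalize_coverage(raw_coverage: float, dataset_read_pairs: float,
                       target_read_pairs: float = NORMALIZATION_READ_PAIRS) -> float:
    """Scale a coverage value to a fixed dataset size (default 100M read pairs)."""
    if dataset_read_pairs <= 0:
        raise ParameterError("dataset_read_pairs must be positive")
    return raw_coverage * target_read_pairs / dataset_read_pairs


def compute_tpm(counts: Sequence[float], lengths: Sequence[float]) -> np.ndarray:
    """TPM_g = 1e6 (c_g / L_g) / sum_h (c_h / L_h)."""
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if np.any(lengths <= 0):
        raise ParameterError("gene lengths must be positive")
    rate = counts / lengths
    total = rate.sum()
    if total == 0:
        warnings.warn("all read counts are zero; TPM set to zero", stacklevel=2)
        return np.zeros_like(rate)
    return 1e6 * rate / total


#: packaged marker-gene -> reaction map; editable data, not code.  Markers of
#: each oxidation step map to both acceptor variants where one exists.
DEFAULT_MARKER_MAP = pd.DataFrame(
    [("sqr", "sulfide_O2"), ("fccB", "sulfide_O2"),
     ("sqr", "sulfide_NO3"), ("fccB", "sulfide_NO3"),
     ("dsrA", "sulfur_O2"), ("dsrB", "sulfur_O2"), ("sdo", "sulfur_O2"),
     ("dsrA", "sulfur_NO3"), ("dsrB", "sulfur_NO3"), ("sdo", "sulfur_NO3"),
     ("soxB", "thiosulfate_O2"), ("soxB", "thiosulfate_NO3"),
     ("hyaB", "hydrogen_O2"), ("hyaB", "hydrogen_NO3"),
     ("pmoA", "methane_O2"), ("mmoX", "methane_O2"),
     ("amoA", "ammonia_O2"), ("cyc2", "iron_O2"), ("mnxG", "manganese_O2")],
    columns=["function", "reaction"],
)


def _weight_column(basis: str) -> str:
    if basis == "metagenome":
        return "coverage"
    if basis == "metatranscriptome":
        return "tpm"
    raise ParameterError("basis must be 'metagenome' or 'metatranscriptome'")


def _exergonic_magnitude(landscape: EnergyLandscape, reaction_id: str) -> float:
    return abs(min(0.0, landscape.delta_g(reaction_id)))


def donor_energy_contribution(weights: pd.DataFrame,
                              landscape: EnergyLandscape,
                              reactions: Iterable[CatabolicReaction],
                              basis: str = "metagenome",
                              marker_map: pd.DataFrame | None = None,
                              ) -> DonorContribution:
    """Attribute community energy to electron donors from gene weights.

    ``weights`` is a gene-weight table with columns (function, coverage, tpm);
    ``marker_map`` maps function ids to reaction ids (default: the packaged
    marker map, falling back to function id == reaction id).  Function ids
    that map to no reaction in the landscape are reported in
    ``skipped_functions`` rather than failing.
    """
    col = _weight_column(basis)
    reactions = list(reactions)
    by_id = {r.id: r for r in reactions}
    if marker_map is None:
        marker_map = DEFAULT_MARKER_MAP
    mapping: dict[str, list[str]] = {}
    for rec in marker_map.itertuples(index=False):
        mapping.setdefault(str(rec.function), []).append(str(rec.reaction))
    for rid in by_id:  # identity fallback: reaction ids usable as function ids
        mapping.setdefault(rid, [rid])

    known = set(landscape.table["reaction"])
    scores: dict[str, float] = {}
    skipped: list[str] = []
    for function, sub in weights.groupby("function"):
        total_weight = float(sub[col].sum())
        targets = [r for r in mapping.get(str(function), []) if r in known]
        if not targets:
            skipped.append(str(function))
            continue
        for rid in targets:
            donor = by_id[rid].donor
            scores[donor] = scores.get(donor, 0.0) \
                + total_weight * _exergonic_magnitude(landscape, rid)
    percents = _normalize_scores(scores)
    return DonorContribution(percents=percents, basis=basis,
                             skipped_functions=sorted(skipped))


def acceptor_adjusted_contribution(weights: pd.DataFrame,
                                   landscape_o2: EnergyLandscape,
                                   landscape_no3: EnergyLandscape,
                                   reactions: Iterable[CatabolicReaction],
                                   rho: float,
                                   basis: str = "metagenome",
                                   marker_map: pd.DataFrame | None = None,
                                   ) -> DonorContribution:
    """Donor attribution with the O2/NO3- acceptor balance folded in.

    Aerobic reaction terms are weighted by ``rho`` (the O2 share) and
    nitrate-coupled terms by ``1 - rho``; each term uses the Gibbs energy from
    its own landscape.
    """
    if not 0.0 <= rho <= 1.0:
        raise ParameterError("rho outside [0, 1]")
    col = _weight_column(basis)
    reactions = list(reactions)
    by_id = {r.id: r for r in reactions}
    if marker_map is None:
        marker_map = DEFAULT_MARKER_MAP
    mapping: dict[str, list[str]] = {}
    for rec in marker_map.itertuples(index=False):
        mapping.setdefault(str(rec.function), []).append(str(rec.reaction))
    for rid in by_id:
        mapping.setdefault(rid, [rid])

    known_o2 = set(landscape_o2.table["reaction"])
    known_no3 = set(landscape_no3.table["reaction"])
    scores: dict[str, float] = {}
    skipped: list[str] = []
    for function, sub in weights.groupby("function"):
        total_weight = float(sub[col].sum())
        targets = mapping.get(str(function), [])
        used = False
        for rid in targets:
            rxn = by_id.get(rid)
            if rxn is None:
                continue
            if rxn.aerobic and rid in known_o2:
                factor = rho * _exergonic_magnitude(landscape_o2, rid)
            elif not rxn.aerobic and rid in known_no3:
                factor = (1.0 - rho) * _exergonic_magnitude(landscape_no3, rid)
            else:
                continue
            scores[rxn.donor] = scores.get(rxn.donor, 0.0) + total_weight * factor
            used = True
        if not used:
            skipped.append(str(function))
    percents = _normalize_scores(scores)
    return DonorContribution(percents=percents, basis=basis, rho=rho,
                             skipped_functions=sorted(skipped))


def _normalize_scores(scores: Mapping[str, float]) -> pd.Series:
    s = pd.Series(scores, dtype=float).sort_index()
    total = s.sum()
    if total > 0:
        return 100.0 * s / total
    return s * 0.0


def rho_from_state(state) -> float:
    """Default O2 share rho = [O2] / ([O2] + [NO3-]) from a mixture state."""
    o2 = state.concentrations.get("O2", 0.0)
    no3 = state.concentrations.get("NO3-", 0.0)
    if o2 + no3 == 0:
        raise ParameterError("no O2 or NO3- in the mixture state")
    return o2 / (o2 + no3)


def taxon_function_contribution(weights: pd.DataFrame,
                                mag_taxonomy: Mapping[str, str],
                                function_id: str,
                                threshold: float = DEFAULT_SHARE_THRESHOLD,
                                basis: str = "metagenome") -> pd.DataFrame:
    """Share of a function's total gene weight per taxon.

    Returns all taxa ranked by share with taxa above the strict ``threshold``
    flagged (default > 10%).  An absent function yields an empty result with
    a warning.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ParameterError("threshold outside [0, 1]")
    col = _weight_column(basis)
    sub = weights[weights["function"] == function_id]
    if sub.empty:
        warnings.warn(f"function {function_id!r} absent from the weight table",
                      stacklevel=2)
        return pd.DataFrame(columns=["taxon", "share", "flagged"])
    taxa = sub["mag"].map(lambda m: mag_taxonomy.get(m, "unclassified"))
    by_taxon = sub.groupby(taxa.values)[col].sum()
    total = by_taxon.sum()
    share = by_taxon / total if total > 0 else by_taxon * 0.0
    out = pd.DataFrame({"taxon": share.index, "share": share.values})
    out["flagged"] = out["share"] > threshold
    return out.sort_values("share", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# serialization


def write_gene_weights(weights: pd.DataFrame, path) -> None:
    write_tsv(weights, path)


def read_gene_weights(path) -> pd.DataFrame:
    return read_tsv(path)


def write_marker_map(marker_map: pd.DataFrame, path) -> None:
    write_tsv(marker_map, path)


def read_marker_map(path) -> pd.DataFrame:
    return read_tsv(path)


def write_donor_contribution(contribution: DonorContribution, path) -> None:
    df = pd.DataFrame({"donor": contribution.percents.index,
                       "percent": contribution.percents.values})
    df["basis"] = contribution.basis
    df["rho"] = contribution.rho if contribution.rho is not None else np.nan
    write_tsv(df, path)
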