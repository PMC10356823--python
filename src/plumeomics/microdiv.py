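"""Population-level microdiversity, Hudson FST, and gene-specific sweep screens.

Inputs are per-site allele-count matrices for two pooled sample groups
(conventionally ``env1`` = hydrothermal, ``env2`` = open-ocean background)
mapped against one genome, plus gene models and the reference sequence.  The
counts are assumed to come from reads already filtered upstream (read-pair
identity >95%, paired-insert-size rules); those filters are an input contract,
not re-implemented here.

Statistics follow the strain-profiling conventions of the inStrain family:

- a site is *callable* when its coverage >= ``min_cov`` (default 5); a variant
  allele is called when its frequency >= ``min_freq`` (default 0.05) and its
  read count >= ``min_count`` (default 2); consensus ties break alphabetically;
- per-site nucleotide diversity pi = 1 - sum(p_b^2) (read-frequency based, no
  sample-size correction) and consensus frequency = max(p_b), both over
  callable sites;
- SNV effects are classified strand-aware against the reference codon
  (stop<->sense counts as nonsynonymous); genome N/S is the ratio of total
  nonsynonymous to total synonymous SNV counts;
- the per-gene fixation index uses the Hudson estimator as a ratio of sums
  over usable sites,

      num_s = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
      den_s = p1(1-p2) + p2(1-p1)
      FST_gene = sum(num_s) / sum(den_s)

  with p the minor (second-most-common pooled) allele frequency and n the
  read counts of the two retained alleles in each group.

Two screens call putative gene-specific selective sweeps:

- *high-FST screen*: FST > genome mean + 2.5 sd, both gene coverages > 5x,
  gene pi (env1) below the genome average and below the gene's env2 pi, and
  gene N/S (env1) above the genome average and above the gene's env2 N/S; a
  genome is skipped when more than half of its genes have undefined FST;
- *sulfur-gene fixation screen* (sat/aprA/sdo/oxidative dsrAB/soxBCY): FST
  above a positive genome mean, pi lower and N/S higher in env1 than env2,
  both coverages > 5x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from ._tsv import read_tsv, write_tsv

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_TABLE = CodonTable.unambiguous_dna_by_id[1]
#: codon -> amino acid, stop codons mapped to "*".
CODON_TO_AA = {**_TABLE.forward_table, **{c: "*" for c in _TABLE.stop_codons}}

DEFAULT_MIN_COV = 5
DEFAULT_MIN_FREQ = 0.05
DEFAULT_MIN_COUNT = 2
DEFAULT_SIGMA = 2.5
DEFAULT_MIN_GENE_COV = 5.0
DEFAULT_SULFUR_TAGS = frozenset(
    {"sat", "aprA", "sdo", "dsrA", "dsrB", "soxB", "soxC", "soxY"})


class DataError(ValueError):
    pass


@dataclass(frozen=True)
class GeneModel:
    """1-based inclusive gene coordinates with strand and annotation tags."""

    contig: str
    gene_id: str
    start: int
    end: int
    strand: str = "+"
    annotation: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise DataError(f"{self.gene_id}: strand must be + or -")
        if self.end < self.start:
            raise DataError(f"{self.gene_id}: end < start")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeProfile:
    """inStrain-style per-genome microdiversity summary for one sample group."""

    group: str
    coverage: float
    breadth_mincov: float
    snv_count: int
    snv_rate: float
    ns_ratio: float
    pi_mean: float
    con_freq_mean: float
    con_freq_mean_n: float
    con_freq_mean_s: float
    r2_mean: float
    excluded: bool


@dataclass
class FstResult:
    """Per-gene Hudson FST plus the genome-wide gene-level mean and std."""

    per_gene: pd.DataFrame  # gene_id, fst, n_sites
    mean: float
    std: float
    n_genes: int
    n_undefined: int


@dataclass
class SweepCallSet:
    high_fst: pd.DataFrame
    sulfur_fixed: pd.DataFrame
    genome_skipped: bool
    skip_reason: str = ""


# ---------------------------------------------------------------------------
# matrix plumbing


def _group_arrays(matrix: pd.DataFrame, group: str,
                  contig: str | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Sorted positions and (n, 4) count array for one group (single contig)."""
    sub = matrix[matrix["group"] == group]
    if contig is not None:
        sub = sub[sub["contig"] == contig]
    elif sub["contig"].nunique() > 1:
        raise DataError("multiple contigs present; pass contig explicitly")
    sub = sub.sort_values("pos")
    pos = sub["pos"].to_numpy(dtype=np.int64)
    counts = sub[["nA", "nC", "nG", "nT"]].to_numpy(dtype=np.float64)
    return pos, counts


def _site_calls(counts: np.ndarray, min_cov: int, min_freq: float,
                min_count: int) -> dict[str, np.ndarray]:
    """Vectorized per-site calls from an (n, 4) count array."""
    cov = counts.sum(axis=1)
    callable_ = cov >= min_cov
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(cov[:, None] > 0, counts / np.maximum(cov, 1)[:, None], 0.0)
    consensus_idx = counts.argmax(axis=1)  # ties -> lowest index -> alphabetical
    con_freq = freq[np.arange(len(counts)), consensus_idx]
    pi = 1.0 - (freq ** 2).sum(axis=1)
    variant = (freq >= min_freq) & (counts >= min_count)
    variant[np.arange(len(counts)), consensus_idx] = False
    variant &= callable_[:, None]
    return {
        "coverage": cov,
        "callable": callable_,
        "consensus_idx": consensus_idx,
        "con_freq": np.where(callable_, con_freq, np.nan),
        "pi": np.where(callable_, pi, np.nan),
        "variant_mask": variant,
        "n_snv": variant.sum(axis=1),
    }


def call_snvs(matrix: pd.DataFrame, min_cov: int = DEFAULT_MIN_COV,
              min_freq: float = DEFAULT_MIN_FREQ,
              min_count: int = DEFAULT_MIN_COUNT,
              group: str | None = None, contig: str | None = None) -> pd.DataFrame:
    """Per-site SNV calls: consensus base, consensus frequency, variant alleles, pi.

    A site is callable iff coverage >= ``min_cov``; each non-consensus base
    with frequency >= ``min_freq`` and count >= ``min_count`` is reported as a
    variant allele.  Uncallable sites carry NaN statistics and no variants.
    """
    if min_cov < 1:
        raise DataError("min_cov must be >= 1")
    groups = [group] if group is not None else sorted(matrix["group"].unique())
    frames = []
    for g in groups:
        pos, counts = _group_arrays(matrix, g, contig)
        calls = _site_calls(counts, min_cov, min_freq, min_count)
        variants = [
            ",".join(BASES[j] for j in np.flatnonzero(row)) if row.any() else ""
            for row in calls["variant_mask"]
        ]
        frames.append(pd.DataFrame({
            "pos": pos, "group": g,
            "coverage": calls["coverage"].astype(int),
            "callable": calls["callable"],
            "consensus": [BASES[i] for i in calls["consensus_idx"]],
            "con_freq": calls["con_freq"],
            "pi": calls["pi"],
            "n_snv": calls["n_snv"],
            "variants": variants,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# SNV effect classification


def classify_snv_effect(pos: int, variant: str, gene: GeneModel,
                        reference: str) -> str:
    """Classify a substitution as "N", "S", or "noncoding" (outside the gene).

    The codon containing the site is read strand-aware from the reference
    (minus-strand codons on the reverse complement), the variant base is
    substituted, and the amino acids are compared; stop<->sense changes count
    as nonsynonymous.
    """
    if variant not in _BASE_INDEX:
        raise DataError(f"invalid base {variant!r}")
    if not gene.start <= pos <= gene.end:
        return "noncoding"
    if gene.length % 3 != 0:
        raise DataError(f"{gene.gene_id}: length not divisible by 3")
    if gene.strand == "+":
        off = pos - gene.start
        codon_start = gene.start - 1 + 3 * (off // 3)
        codon = reference[codon_start:codon_start + 3]
        within = off % 3
        new_base = variant
    else:
        off = gene.end - pos
        codon_end = gene.end - 3 * (off // 3)
        codon = reference[codon_end - 3:codon_end][::-1].translate(_COMPLEMENT)
        within = off % 3
        new_base = variant.translate(_COMPLEMENT)
    mutated = codon[:within] + new_base + codon[within + 1:]
    if CODON_TO_AA[codon] == CODON_TO_AA[mutated]:
        return "S"
    return "N"


# ---------------------------------------------------------------------------
# diversity statistics


def site_diversity_stats(matrix: pd.DataFrame, group: str,
                         min_cov: int = DEFAULT_MIN_COV,
                         contig: str | None = None) -> pd.DataFrame:
    """Per-site pi and consensus frequency over callable sites for one group."""
    calls = call_snvs(matrix, min_cov=min_cov, group=group, contig=contig)
    return calls[["pos", "coverage", "callable", "pi", "con_freq"]]


def linkage_r2(hap_counts: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """Squared allelic correlation per SNV pair from joint haplotype counts.

    ``hap_counts`` has columns n_AB, n_Ab, n_aB, n_ab (joint observations of
    the two bialleles at two sites).  Pairs with a monomorphic member are
    skipped.  Returns the per-pair table (column ``r2``) and the mean over
    defined pairs.
    """
    c = hap_counts[["n_AB", "n_Ab", "n_aB", "n_ab"]].to_numpy(dtype=float)
    n = c.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_a = (c[:, 0] + c[:, 1]) / n
        p_b = (c[:, 0] + c[:, 2]) / n
        p_ab = c[:, 0] / n
        denom = p_a * (1 - p_a) * p_b * (1 - p_b)
        r2 = np.where(denom > 0, (p_ab - p_a * p_b) ** 2 / denom, np.nan)
    out = hap_counts.copy()
    out["r2"] = r2
    mean = float(np.nanmean(r2)) if np.isfinite(r2).any() else math.nan
    return out, mean


def _ns_ratio(n_n: float, n_s: float) -> float:
    """N/S with the documented conventions: S=0,N>0 -> +inf; S=0,N=0 -> NaN."""
    if n_s > 0:
        return n_n / n_s
    return math.inf if n_n > 0 else math.nan


def _gene_slices(pos: np.ndarray, genes: Sequence[GeneModel]) -> list[tuple[int, int]]:
    return [(int(np.searchsorted(pos, g.start, "left")),
             int(np.searchsorted(pos, g.end, "right"))) for g in genes]


def gene_group_stats(matrix: pd.DataFrame, genes: Sequence[GeneModel],
                     reference: str, group: str,
                     min_cov: int = DEFAULT_MIN_COV,
                     min_freq: float = DEFAULT_MIN_FREQ,
                     min_count: int = DEFAULT_MIN_COUNT,
                     contig: str | None = None) -> pd.DataFrame:
    """Per-gene coverage, pi, SNV and N/S statistics for one sample group.

    Gene coverage is the mean depth over the gene's positions (positions
    absent from the matrix count as zero depth); pi is the mean over the
    gene's callable sites (NaN if none).
    """
    pos, counts = _group_arrays(matrix, group, contig)
    calls = _site_calls(counts, min_cov, min_freq, min_count)
    rows = []
    for gene, (lo, hi) in zip(genes, _gene_slices(pos, genes)):
        cov = calls["coverage"][lo:hi]
        callable_ = calls["callable"][lo:hi]
        pi = calls["pi"][lo:hi]
        n_n = n_s = 0
        vm = calls["variant_mask"][lo:hi]
        for local_idx in np.flatnonzero(vm.any(axis=1)):
            p = int(pos[lo + local_idx])
            for j in np.flatnonzero(vm[local_idx]):
                effect = classify_snv_effect(p, BASES[j], gene, reference)
                if effect == "N":
                    n_n += 1
                elif effect == "S":
                    n_s += 1
        rows.append({
            "gene_id": gene.gene_id,
            "coverage": float(cov.sum()) / gene.length,
            "n_callable": int(callable_.sum()),
            "pi": float(np.nanmean(pi)) if callable_.any() else math.nan,
            "n_snv": int(calls["n_snv"][lo:hi].sum()),
            "n_N": n_n,
            "n_S": n_s,
            "ns_ratio": _ns_ratio(n_n, n_s),
        })
    return pd.DataFrame(rows)


def profile_genome(matrix: pd.DataFrame, genes: Sequence[GeneModel],
                   group: str, reference: str, genome_length: int,
                   min_cov: int = DEFAULT_MIN_COV,
                   min_freq: float = DEFAULT_MIN_FREQ,
                   min_count: int = DEFAULT_MIN_COUNT,
                   haplotype_counts: pd.DataFrame | None = None,
                   contig: str | None = None) -> GenomeProfile:
    """Genome-wide microdiversity profile for one sample group.

    Genomes with breadth_minCov < 0.5 are flagged ``excluded`` (they do not
    enter downstream microdiversity comparisons).
    """
    if genome_length <= 0:
        raise DataError("genome_length must be positive")
    pos, counts = _group_arrays(matrix, group, contig)
    calls = _site_calls(counts, min_cov, min_freq, min_count)
    coverage = float(calls["coverage"].sum()) / genome_length
    breadth = float(calls["callable"].sum()) / genome_length
    snv_count = int(calls["n_snv"].sum())
    snv_rate = snv_count / (breadth * genome_length) if breadth > 0 else math.nan

    # classify every called variant against the gene models
    gene_bounds = _gene_slices(pos, genes)
    n_n = n_s = 0
    con_n: list[float] = []
    con_s: list[float] = []
    vm = calls["variant_mask"]
    for gene, (lo, hi) in zip(genes, gene_bounds):
        for local_idx in np.flatnonzero(vm[lo:hi].any(axis=1)):
            idx = lo + local_idx
            site_effects = set()
            for j in np.flatnonzero(vm[idx]):
                effect = classify_snv_effect(int(pos[idx]), BASES[j], gene, reference)
                site_effects.add(effect)
                if effect == "N":
                    n_n += 1
                elif effect == "S":
                    n_s += 1
            if "N" in site_effects:
                con_n.append(calls["con_freq"][idx])
            if "S" in site_effects:
                con_s.append(calls["con_freq"][idx])

    snv_sites = vm.any(axis=1)
    con_all = calls["con_freq"][snv_sites]
    r2_mean = math.nan
    if haplotype_counts is not None and len(haplotype_counts):
        _, r2_mean = linkage_r2(haplotype_counts)
    return GenomeProfile(
        group=group,
        coverage=coverage,
        breadth_mincov=breadth,
        snv_count=snv_count,
        snv_rate=snv_rate,
        ns_ratio=_ns_ratio(n_n, n_s),
        pi_mean=float(np.nanmean(calls["pi"])) if calls["callable"].any() else math.nan,
        con_freq_mean=float(con_all.mean()) if len(con_all) else math.nan,
        con_freq_mean_n=float(np.mean(con_n)) if con_n else math.nan,
        con_freq_mean_s=float(np.mean(con_s)) if con_s else math.nan,
        r2_mean=r2_mean,
        excluded=breadth < 0.5,
    )


# ---------------------------------------------------------------------------
# Hudson FST


def _hudson_site_components(counts1: np.ndarray, counts2: np.ndarray,
                            min_cov: int = DEFAULT_MIN_COV,
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-site Hudson components for aligned (n, 4) count arrays.

    The two retained alleles at each site are the two most common bases in the
    pooled counts (ties alphabetical).  A site is usable when the pooled minor
    allele is observed, both groups have coverage >= min_cov, and both groups
    retain >= 2 reads across the two alleles.
    Returns (num, den, usable).
    """
    pooled = counts1 + counts2
    ref = pooled.argmax(axis=1)
    masked = pooled.copy()
    masked[np.arange(len(pooled)), ref] = -1.0
    alt = masked.argmax(axis=1)
    rows = np.arange(len(pooled))
    c1r, c1a = counts1[rows, ref], counts1[rows, alt]
    c2r, c2a = counts2[rows, ref], counts2[rows, alt]
    n1, n2 = c1r + c1a, c2r + c2a
    usable = ((pooled[rows, alt] > 0)
              & (counts1.sum(axis=1) >= min_cov) & (counts2.sum(axis=1) >= min_cov)
              & (n1 >= 2) & (n2 >= 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(n1 > 0, c1a / np.maximum(n1, 1), 0.0)
        p2 = np.where(n2 > 0, c2a / np.maximum(n2, 1), 0.0)
        num = ((p1 - p2) ** 2
               - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
               - p2 * (1 - p2) / np.maximum(n2 - 1, 1))
        den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den, usable


def hudson_fst(matrix: pd.DataFrame, gene: GeneModel,
               groups: tuple[str, str] = ("env1", "env2"),
               min_cov: int = DEFAULT_MIN_COV,
               contig: str | None = None) -> tuple[float, int]:
    """Hudson FST for one gene as a ratio of sums over usable sites.

    Returns (fst, n_usable_sites); fst is NaN when no site is usable or the
    summed denominator is zero.
    """
    pos1, counts1 = _group_arrays(matrix, groups[0], contig)
    pos2, counts2 = _group_arrays(matrix, groups[1], contig)
    common, i1, i2 = np.intersect1d(pos1, pos2, return_indices=True)
    sel = (common >= gene.start) & (common <= gene.end)
    num, den, usable = _hudson_site_components(
        counts1[i1][sel], counts2[i2][sel], min_cov=min_cov)
    n_sites = int(usable.sum())
    den_sum = float(den[usable].sum())
    if n_sites == 0 or den_sum == 0.0:
        return math.nan, n_sites
    return float(num[usable].sum()) / den_sum, n_sites


def genome_fst(matrix: pd.DataFrame, genes: Sequence[GeneModel],
               groups: tuple[str, str] = ("env1", "env2"),
               min_cov: int = DEFAULT_MIN_COV,
               mode: str = "gene",
               contig: str | None = None) -> FstResult:
    """Per-gene Hudson FST plus genome-wide mean/std.

    ``mode="gene"`` (default) computes the genome-wide mean and standard
    deviation over defined per-gene FST values; ``mode="site"`` computes them
    over per-site FST ratios across all usable sites in genes.
    """
    if mode not in ("gene", "site"):
        raise DataError("mode must be 'gene' or 'site'")
    pos1, counts1 = _group_arrays(matrix, groups[0], contig)
    pos2, counts2 = _group_arrays(matrix, groups[1], contig)
    common, i1, i2 = np.intersect1d(pos1, pos2, return_indices=True)
    c1, c2 = counts1[i1], counts2[i2]
    num, den, usable = _hudson_site_components(c1, c2, min_cov=min_cov)
    rows = []
    site_values: list[np.ndarray] = []
    for gene, (lo, hi) in zip(genes, _gene_slices(common, genes)):
        u = usable[lo:hi]
        den_sum = float(den[lo:hi][u].sum())
        if u.sum() == 0 or den_sum == 0.0:
            rows.append({"gene_id": gene.gene_id, "fst": math.nan, "n_sites": int(u.sum())})
        else:
            rows.append({"gene_id": gene.gene_id,
                         "fst": float(num[lo:hi][u].sum()) / den_sum,
                         "n_sites": int(u.sum())})
        if mode == "site":
            d = den[lo:hi][u]
            ok = d != 0
            site_values.append(num[lo:hi][u][ok] / d[ok])
    per_gene = pd.DataFrame(rows)
    if mode == "gene":
        defined = per_gene["fst"].dropna()
    else:
        defined = pd.Series(np.concatenate(site_values) if site_values else [])
    mean = float(defined.mean()) if len(defined) else math.nan
    std = float(defined.std(ddof=1)) if len(defined) > 1 else math.nan
    return FstResult(per_gene=per_gene, mean=mean, std=std,
                     n_genes=len(genes),
                     n_undefined=int(per_gene["fst"].isna().sum()))


# ---------------------------------------------------------------------------
# sweep screens


def _merge_screen_inputs(fst: FstResult, stats1: pd.DataFrame,
                         stats2: pd.DataFrame) -> pd.DataFrame:
    df = fst.per_gene.merge(stats1, on="gene_id", suffixes=("", "_env1"))
    df = df.merge(stats2, on="gene_id", suffixes=("_env1", "_env2"))
    return df


def screen_high_fst_genes(fst: FstResult, stats1: pd.DataFrame,
                          stats2: pd.DataFrame,
                          genome_pi1: float, genome_ns1: float,
                          sigma: float = DEFAULT_SIGMA,
                          min_gene_cov: float = DEFAULT_MIN_GENE_COV,
                          ) -> tuple[pd.DataFrame, bool]:
    """High-FST gene-specific sweep screen (part 1).

    A gene is flagged iff ALL of: FST > mean + sigma*std; min coverage in both
    groups > min_gene_cov; env1 gene pi below the genome average; env1 gene
    N/S above the genome average; env1 pi below env2 pi; env1 N/S above env2
    N/S.  The genome is skipped (empty result, skipped=True) when more than
    half of its genes have undefined FST.  Returns (calls, genome_skipped).
    """
    df = _merge_screen_inputs(fst, stats1, stats2)
    if fst.n_undefined > fst.n_genes / 2:
        return df.head(0), True
    threshold = fst.mean + sigma * fst.std
    flagged = (
        (df["fst"] > threshold)
        & (df["coverage_env1"] > min_gene_cov)
        & (df["coverage_env2"] > min_gene_cov)
        & (df["pi_env1"] < genome_pi1)
        & (df["ns_ratio_env1"] > genome_ns1)
        & (df["pi_env1"] < df["pi_env2"])
        & (df["ns_ratio_env1"] > df["ns_ratio_env2"])
    )
    out = df[flagged.fillna(False)].copy()
    out["fst_threshold"] = threshold
    return out, False


def screen_sulfur_gene_fixation(fst: FstResult, stats1: pd.DataFrame,
                                stats2: pd.DataFrame,
                                genes: Sequence[GeneModel],
                                sulfur_tags: Iterable[str] = DEFAULT_SULFUR_TAGS,
                                min_gene_cov: float = DEFAULT_MIN_GENE_COV,
                                ) -> pd.DataFrame:
    """Fixation screen for sulfur-metabolism genes (part 2, less stringent).

    A sulfur-tagged gene is flagged iff: FST > genome FST mean with both
    positive; env1 pi < env2 pi; env1 N/S > env2 N/S; both coverages > 5x.
    """
    tags = set(sulfur_tags)
    sulfur_ids = {g.gene_id for g in genes if tags & set(g.annotation)}
    df = _merge_screen_inputs(fst, stats1, stats2)
    df = df[df["gene_id"].isin(sulfur_ids)]
    if not (fst.mean > 0):  # NaN-safe: a non-positive genome mean flags nothing
        return df.head(0)
    flagged = (
        (df["fst"] > fst.mean) & (df["fst"] > 0)
        & (df["pi_env1"] < df["pi_env2"])
        & (df["ns_ratio_env1"] > df["ns_ratio_env2"])
        & (df["coverage_env1"] > min_gene_cov)
        & (df["coverage_env2"] > min_gene_cov)
    )
    return df[flagged.fillna(False)].copy()


def run_sweep_screens(matrix: pd.DataFrame, genes: Sequence[GeneModel],
                      reference: str, genome_length: int,
                      groups: tuple[str, str] = ("env1", "env2"),
                      min_cov: int = DEFAULT_MIN_COV,
                      min_freq: float = DEFAULT_MIN_FREQ,
                      min_count: int = DEFAULT_MIN_COUNT,
                      sigma: float = DEFAULT_SIGMA,
                      min_gene_cov: float = DEFAULT_MIN_GENE_COV,
                      sulfur_tags: Iterable[str] = DEFAULT_SULFUR_TAGS,
                      ) -> tuple[SweepCallSet, FstResult, pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: stats for both groups, FST, and both screens."""
    stats1 = gene_group_stats(matrix, genes, reference, groups[0],
                              min_cov, min_freq, min_count)
    stats2 = gene_group_stats(matrix, genes, reference, groups[1],
                              min_cov, min_freq, min_count)
    profile1 = profile_genome(matrix, genes, groups[0], reference, genome_length,
                              min_cov, min_freq, min_count)
    fst = genome_fst(matrix, genes, groups, min_cov=min_cov)
    high, skipped = screen_high_fst_genes(
        fst, stats1, stats2, genome_pi1=profile1.pi_mean,
        genome_ns1=profile1.ns_ratio, sigma=sigma, min_gene_cov=min_gene_cov)
    sulfur = screen_sulfur_gene_fixation(
        fst, stats1, stats2, genes, sulfur_tags=sulfur_tags,
        min_gene_cov=min_gene_cov)
    callset = SweepCallSet(high_fst=high, sulfur_fixed=sulfur,
                           genome_skipped=skipped,
                           skip_reason="more than half of genes have undefined FST"
                           if skipped else "")
    return callset, fst, stats1, stats2


# ---------------------------------------------------------------------------
# serialization


def write_gene_models(genes: Sequence[GeneModel], path) -> None:
    df = pd.DataFrame([{
        "contig": g.contig, "gene_id": g.gene_id, "start": g.start,
        "end": g.end, "strand": g.strand,
        "annotation": ",".join(g.annotation),
    } for g in genes])
    write_tsv(df, path)


def read_gene_models(path) -> list[GeneModel]:
    df = read_tsv(path)
    out = []
    for rec in df.itertuples(index=False):
        ann = () if pd.isna(rec.annotation) or rec.annotation == "" \
            else tuple(str(rec.annotation).split(","))
        out.append(GeneModel(contig=str(rec.contig), gene_id=str(rec.gene_id),
                             start=int(rec.start), end=int(rec.end),
                             strand=str(rec.strand), annotation=ann))
    return out


def read_gene_models_gff3(path) -> list[GeneModel]:
    """Import gene coordinates/strand from a GFF3 file (CDS/gene features)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    out = []
    for feat in db.all_features():
        if feat.featuretype not in ("gene", "CDS"):
            continue
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        out.append(GeneModel(contig=feat.seqid, gene_id=gene_id,
                             start=feat.start, end=feat.end,
                             strand=feat.strand if feat.strand in "+-" else "+"))
    return out
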