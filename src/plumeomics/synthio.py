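"""Synthetic inputs with the statistical structure the pipeline assumes.

Every generator is a pure function of its parameters and seed (fixed seed =>
byte-identical outputs) and has a matching TSV reader/writer so generated
files round-trip exactly.

The two-population pileup generator emulates the population structure behind
gene-specific sweep detection: two pooled sample groups ("env1" = hydrothermal,
"env2" = open-ocean background) with shared standing variation, and a
designated fraction of "swept" genes in which env1 allele frequencies are
pushed toward fixation (reduced nucleotide diversity), divergence is placed at
nonsynonymous-capable codon positions (elevated N/S), and a couple of residual
intermediate-frequency nonsynonymous variants remain (recent-sweep signature).
Allele counts are multinomial draws given the true frequencies with a uniform
per-base sequencing-error channel; per-site depth is Poisson.

Coverage tracks follow an exponential ori->ter gradient on a circular genome:

    coverage(x) = depth * ratio ** (1 - 2 d(x) / L)

where d(x) is the distance from the origin (position 0), with multiplicative
lognormal noise of a given coefficient of variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import geochem, metaconnect, coremicrobiome
from ._tsv import read_tsv, write_tsv
from .microdiv import BASES, CODON_TO_AA, GeneModel

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

CONTIG_NAME = "genome"
GENE_LENGTH = 300  # bp (100 codons); scenario genes are single-exon ORFs

#: per-gene site layout of the generator (counts of selected codons)
N_BACKGROUND_SYN = 8    # standing variation at 3rd codon positions
N_BACKGROUND_NONSYN = 2  # standing variation at 1st codon positions
N_DIVERGENT = 6          # swept genes: divergent nonsynonymous sites
N_RESIDUAL = 2           # swept genes: residual young nonsynonymous variants


class ParameterError(ValueError):
    pass


@dataclass(frozen=True)
class SyntheticScenario:
    """Study conditions for all synthetic generators.

    Defaults mirror the conditions the analysis is designed for: a 50x-depth
    two-population comparison over a 100-gene genome with 5% of genes swept,
    strong sweep divergence against weak background drift, and a modest
    ori->ter replication gradient.
    """

    seed: int = 0
    n_mags: int = 4
    n_functions: int = 12
    n_genes_per_mag: int = 100
    genome_length: int = 36000
    swept_gene_fraction: float = 0.05
    divergence_background: float = 0.02
    divergence_swept: float = 0.5
    depth_mean: float = 50.0
    error_rate: float = 0.001
    oriter_ratio: float = 1.5

    def __post_init__(self) -> None:
        for name in ("swept_gene_fraction", "divergence_background",
                     "divergence_swept", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.divergence_swept < self.divergence_background:
            raise ParameterError("divergence_swept must be >= divergence_background")
        if self.oriter_ratio < 1.0:
            raise ParameterError("oriter_ratio must be >= 1")
        for name in ("n_mags", "n_functions", "n_genes_per_mag", "genome_length"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.depth_mean <= 0:
            raise ParameterError("depth_mean must be positive")
        spacing = self.genome_length // self.n_genes_per_mag
        if spacing < GENE_LENGTH + 3:
            raise ParameterError("genome_length too small for the gene count")


@dataclass
class PileupScenario:
    """Everything generate_two_population_pileups produces for one genome."""

    matrix: pd.DataFrame           # contig, pos, group, nA, nC, nG, nT
    genes: list[GeneModel]
    truth: pd.DataFrame            # gene_id, swept
    reference: str                 # reference genome sequence
    groups: tuple[str, str] = ("env1", "env2")


# ---------------------------------------------------------------------------
# pileups


def _coding_codon(reference: str, gene: GeneModel, codon_idx: int) -> str:
    if gene.strand == "+":
        s = gene.start - 1 + 3 * codon_idx
        return reference[s:s + 3]
    e = gene.end - 3 * codon_idx
    return reference[e - 3:e][::-1].translate(_COMPLEMENT)


def _genomic_site(gene: GeneModel, codon_idx: int, within: int) -> int:
    off = 3 * codon_idx + within
    return gene.start + off if gene.strand == "+" else gene.end - off


def _pick_alt(codon: str, within: int, synonymous: bool,
              rng: np.random.Generator) -> str | None:
    """A coding-space alternative base at codon position ``within`` with the
    requested effect, or None if no such substitution exists."""
    aa = CODON_TO_AA[codon]
    options = [b for b in BASES if b != codon[within]]
    rng.shuffle(options)
    for b in options:
        mutated = codon[:within] + b + codon[within + 1:]
        if (CODON_TO_AA[mutated] == aa) == synonymous:
            return b
    return None


def _select_gene_sites(gene: GeneModel, reference: str, swept: bool,
                       rng: np.random.Generator) -> list[dict]:
    """Choose variant sites for one gene: (kind, genomic pos, genomic alt base)."""
    n_codons = gene.length // 3
    wanted = [("bg_syn", 2, True)] * N_BACKGROUND_SYN \
        + [("bg_nonsyn", 0, False)] * N_BACKGROUND_NONSYN
    if swept:
        wanted += [("divergent", 0, False)] * N_DIVERGENT \
            + [("residual", 0, False)] * N_RESIDUAL
    codon_pool = list(rng.permutation(np.arange(1, n_codons - 1)))
    sites = []
    for kind, within, synonymous in wanted:
        while codon_pool:
            ci = int(codon_pool.pop())
            codon = _coding_codon(reference, gene, ci)
            alt = _pick_alt(codon, within, synonymous, rng)
            if alt is None:
                continue  # e.g. ATG/TGG have no synonymous 3rd-position change
            genomic_alt = alt if gene.strand == "+" else alt.translate(_COMPLEMENT)
            sites.append({"kind": kind, "pos": _genomic_site(gene, ci, within),
                          "alt": genomic_alt})
            break
        else:
            raise ParameterError(f"{gene.gene_id}: could not place {kind} site")
    return sites


def _site_frequencies(kind: str, scenario: SyntheticScenario,
                      rng: np.random.Generator) -> tuple[float, float]:
    """True alt-allele frequency of a site in (env1, env2)."""
    d_bg = scenario.divergence_background
    d_sw = scenario.divergence_swept
    if kind in ("bg_syn", "bg_nonsyn"):
        q = rng.uniform(0.25, 0.45)
        q2 = float(np.clip(q + d_bg * rng.uniform(-1, 1), 0.0, 1.0))
        return q, q2
    if kind in ("swept_bg_syn", "swept_bg_nonsyn"):
        q = rng.uniform(0.25, 0.45)
        q2 = float(np.clip(q + d_bg * rng.uniform(-1, 1), 0.0, 1.0))
        q1 = q * max(0.0, 1.0 - 2.0 * d_sw)  # sweep purges standing variation
        return q1, q2
    if kind == "divergent":
        q2 = rng.uniform(0.35, 0.55)
        q1 = q2 + (0.98 - q2) * min(1.0, 2.0 * d_sw)  # pushed toward fixation
        return q1, q2
    if kind == "residual":
        q1 = 0.12 * min(1.0, 2.0 * d_sw)  # young post-sweep variants, env1 only
        return q1, 0.0
    raise ValueError(kind)


def generate_two_population_pileups(scenario: SyntheticScenario,
                                    groups: tuple[str, str] = ("env1", "env2"),
                                    n_sulfur_genes: int = 8) -> PileupScenario:
    """Two-group per-site allele counts for one genome, with sweep truth.

    Swept genes (fraction ``swept_gene_fraction``) receive divergence
    ``divergence_swept`` at nonsynonymous codon positions, purged background
    variation in env1, and residual nonsynonymous env1-only variants; all
    other genes carry shared standing variation with ``divergence_background``
    drift between the groups.  Sulfur-metabolism annotation tags are placed on
    ``n_sulfur_genes`` genes (including swept ones when available) so that the
    downstream fixation screen is exercised.
    """
    rng = np.random.default_rng(scenario.seed)
    n_genes = scenario.n_genes_per_mag
    length = scenario.genome_length

    reference = "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])
    spacing = length // n_genes
    genes = []
    for i in range(n_genes):
        start = i * spacing + 1
        genes.append(GeneModel(contig=CONTIG_NAME, gene_id=f"gene_{i + 1:04d}",
                               start=start, end=start + GENE_LENGTH - 1,
                               strand="+" if i % 2 == 0 else "-"))

    n_swept = round(scenario.swept_gene_fraction * n_genes)
    swept_idx = set(rng.choice(n_genes, size=n_swept, replace=False).tolist())

    # sulfur tags: prefer a couple of swept genes so the fixation screen sees
    # real signal, fill the rest from non-swept genes
    sulfur_tags = sorted({"sat", "aprA", "sdo", "dsrA", "dsrB", "soxB", "soxC", "soxY"})
    swept_list = sorted(swept_idx)
    non_swept = [i for i in range(n_genes) if i not in swept_idx]
    n_tagged_swept = min(2, len(swept_list), n_sulfur_genes)
    picked = rng.choice(len(non_swept),
                        size=min(n_sulfur_genes - n_tagged_swept, len(non_swept)),
                        replace=False)
    sulfur_idx = swept_list[:n_tagged_swept] + [non_swept[int(i)] for i in picked]
    tagged = {}
    for k, i in enumerate(sulfur_idx):
        tagged[i] = (sulfur_tags[k % len(sulfur_tags)],)
    genes = [replace(g, annotation=tagged.get(i, ())) if i in tagged else g
             for i, g in enumerate(genes)]

    # true alt frequencies per group, dense over the genome
    q1 = np.zeros(length)
    q2 = np.zeros(length)
    alt_index = np.full(length, -1, dtype=np.int64)
    for i, gene in enumerate(genes):
        swept = i in swept_idx
        for site in _select_gene_sites(gene, reference, swept, rng):
            kind = site["kind"]
            if swept and kind in ("bg_syn", "bg_nonsyn"):
                kind = "swept_" + kind
            f1, f2 = _site_frequencies(kind, scenario, rng)
            p = site["pos"] - 1
            q1[p], q2[p] = f1, f2
            alt_index[p] = BASES.index(site["alt"])

    ref_index = np.array([BASES.index(b) for b in reference], dtype=np.int64)
    alt_index = np.where(alt_index < 0, (ref_index + 1) % 4, alt_index)

    frames = []
    for group, q in zip(groups, (q1, q2)):
        p_true = np.zeros((length, 4))
        p_true[np.arange(length), ref_index] = 1.0 - q
        p_true[np.arange(length), alt_index] += q
        e = scenario.error_rate
        p_obs = p_true * (1.0 - e) + (1.0 - p_true) * (e / 3.0)
        depth = rng.poisson(scenario.depth_mean, size=length)
        counts = rng.multinomial(depth, p_obs)
        frames.append(pd.DataFrame({
            "contig": CONTIG_NAME,
            "pos": np.arange(1, length + 1),
            "group": group,
            "nA": counts[:, 0], "nC": counts[:, 1],
            "nG": counts[:, 2], "nT": counts[:, 3],
        }))
    matrix = pd.concat(frames, ignore_index=True)
    truth = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "swept": [i in swept_idx for i in range(n_genes)],
    })
    return PileupScenario(matrix=matrix, genes=genes, truth=truth,
                          reference=reference, groups=groups)


# ---------------------------------------------------------------------------
# coverage tracks


def generate_coverage_track(genome_length: int, oriter_ratio: float,
                            depth: float, noise_cv: float, seed: int,
                            window: int = 5000, step: int = 100) -> pd.DataFrame:
    """Sliding-window coverage with an exponential ori->ter gradient.

    The genome is circular with the replication origin at position 0; window
    depth is evaluated at the window start.  ``noise_cv`` adds multiplicative
    lognormal noise with unit mean and the given coefficient of variation.
    """
    if oriter_ratio < 1.0:
        raise ParameterError("oriter_ratio must be >= 1")
    if noise_cv < 0:
        raise ParameterError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    starts = np.arange(0, genome_length, step, dtype=np.int64)
    d = np.minimum(starts, genome_length - starts)
    cov = depth * oriter_ratio ** (1.0 - 2.0 * d / genome_length)
    if noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + noise_cv ** 2))
        cov = cov * rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma,
                                  size=len(starts))
    return pd.DataFrame({"start": starts, "end": starts + window, "depth": cov})


# ---------------------------------------------------------------------------
# vent chemistry profiles


_SEAWATER = {
    "O2": 0.110, "NO3-": 0.037, "SO4--": 28.0, "HCO3-": 2.2, "N2": 0.59,
    "Na+": 464.0, "Cl-": 546.0, "Mg++": 52.8, "Ca++": 10.3, "K+": 9.8,
    "H+": 1e-5, "NH4+": 0.0001, "HS-": 0.0, "H2": 0.0, "CH4": 0.0,
    "Fe++": 0.0, "Mn++": 0.0, "S2O3--": 0.0, "S0": 0.0,
}

#: end-member profiles contrasting the major vent-fluid chemistries; the
#: methane-rich profile pins CH4 at 63.4 mmol/kg and the metal-rich profile
#: keeps Mn/Fe inside 3.9-6.3 / 3.8-13.1 mmol/kg.
_PROFILES: dict[str, dict] = {
    "methane-rich": {
        "temperature": 290.0,
        "conc": {"CH4": 63.4, "HS-": 6.0, "H2": 3.4, "NH4+": 15.6,
                 "Fe++": 0.08, "Mn++": 0.2, "S2O3--": 0.05, "S0": 0.6},
    },
    "metal-rich": {
        "temperature": 360.0,
        "conc": {"Fe++": 8.0, "Mn++": 5.1, "HS-": 3.0, "H2": 0.04,
                 "CH4": 0.01, "S2O3--": 0.02, "S0": 0.3},
    },
    "hydrogen-rich": {
        "temperature": 398.0,
        "conc": {"H2": 19.9, "HS-": 3.2, "CH4": 0.12, "Fe++": 0.3,
                 "Mn++": 0.05, "S2O3--": 0.02, "S0": 0.3},
    },
    "sulfide-rich": {
        "temperature": 330.0,
        "conc": {"HS-": 6.5, "H2": 0.5, "CH4": 0.05, "Fe++": 0.9,
                 "Mn++": 0.7, "S2O3--": 0.1, "S0": 1.0},
    },
}

_VENT_COMMON = {"Na+": 450.0, "Cl-": 550.0, "Ca++": 30.0, "K+": 20.0,
                "H+": 0.01, "SO4--": 0.0, "O2": 0.0, "NO3-": 0.0,
                "HCO3-": 5.0, "N2": 0.0, "Mg++": 0.0}


def generate_vent_chemistry(profile_name: str,
                            ) -> tuple[geochem.EndmemberFluid, geochem.SeawaterComposition]:
    """End-member fluid and bottom-seawater chemistry for a named profile.

    Profiles: methane-rich, metal-rich, hydrogen-rich, sulfide-rich.
    """
    if profile_name not in _PROFILES:
        raise ParameterError(
            f"unknown profile {profile_name!r}; choose from {sorted(_PROFILES)}")
    spec = _PROFILES[profile_name]
    conc = dict(_VENT_COMMON)
    conc.update(spec["conc"])
    vent = geochem.EndmemberFluid(label=profile_name,
                                  temperature=spec["temperature"],
                                  concentrations=conc)
    sw = geochem.SeawaterComposition(concentrations=dict(_SEAWATER))
    return vent, sw


# ---------------------------------------------------------------------------
# function / abundance / weight tables


def generate_function_table(scenario: SyntheticScenario,
                            sharing: str | float = 0.4,
                            ensure_function: str | None = None,
                            ) -> metaconnect.FunctionTable:
    """MAG x function incidence with coverage weights and MAG abundances.

    ``sharing`` is "complete" (every function in every MAG), "disjoint" (each
    function in exactly one MAG, round-robin), or a probability of presence.
    ``ensure_function`` forces one function to be present in every MAG.
    Function ids reuse the default catabolic-reaction ids where possible so
    synthetic tables plug directly into the energy-attribution stage.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    mags = [f"MAG_{i + 1:02d}" for i in range(scenario.n_mags)]
    reaction_ids = [r.id for r in geochem.default_reactions()]
    functions = [reaction_ids[j] if j < len(reaction_ids) else f"func_{j + 1:02d}"
                 for j in range(scenario.n_functions)]
    if sharing == "complete":
        inc = np.ones((len(mags), len(functions)), dtype=bool)
    elif sharing == "disjoint":
        inc = np.zeros((len(mags), len(functions)), dtype=bool)
        for j in range(len(functions)):
            inc[j % len(mags), j] = True
    else:
        p = float(sharing)
        if not 0.0 <= p <= 1.0:
            raise ParameterError("sharing probability outside [0, 1]")
        inc = rng.random((len(mags), len(functions))) < p
    if ensure_function is not None:
        if ensure_function not in functions:
            raise ParameterError(f"{ensure_function!r} not among functions")
        inc[:, functions.index(ensure_function)] = True
    coverage = np.where(inc, rng.lognormal(math.log(10.0), 0.5, inc.shape), 0.0)
    abundance = rng.dirichlet(np.ones(len(mags))) * 0.9
    return metaconnect.FunctionTable(
        incidence=pd.DataFrame(inc, index=mags, columns=functions),
        coverage=pd.DataFrame(coverage, index=mags, columns=functions),
        mag_abundance=pd.Series(abundance, index=mags),
    )


def generate_abundance_table(n_plume: int, n_background: int, n_genera: int,
                             core_spec: list[tuple[float, float]],
                             seed: int) -> coremicrobiome.AbundanceTable:
    """Sample x genus relative abundances with designated core-candidate genera.

    The first ``len(core_spec)`` genera are constructed to hit the requested
    (prevalence among plume samples, mean plume abundance) pairs exactly; the
    remaining genera share the leftover mass via a Dirichlet split, so every
    sample row sums to one.
    """
    if len(core_spec) > n_genera:
        raise ParameterError("more core_spec entries than genera")
    rng = np.random.default_rng(seed)
    genera = [f"genus_{j + 1:02d}" for j in range(n_genera)]
    samples = [f"plume_{i + 1:02d}" for i in range(n_plume)] + \
        [f"background_{i + 1:02d}" for i in range(n_background)]
    labels = ["plume"] * n_plume + ["background"] * n_background
    abund = np.zeros((len(samples), n_genera))
    for j, (prevalence, mean_abundance) in enumerate(core_spec):
        if not 0.0 <= prevalence <= 1.0:
            raise ParameterError("prevalence outside [0, 1]")
        n_present = round(prevalence * n_plume)
        if n_present == 0:
            continue
        per_sample = mean_abundance * n_plume / n_present
        present = rng.choice(n_plume, size=n_present, replace=False)
        abund[present, j] = per_sample
    designated = abund[:, :len(core_spec)].sum(axis=1)
    if np.any(designated >= 1.0):
        raise ParameterError("core_spec abundances exceed the per-sample budget")
    n_filler = n_genera - len(core_spec)
    if n_filler == 0 and np.any(designated < 1.0):
        raise ParameterError("no filler genera to absorb the remaining mass")
    for i in range(len(samples)):
        if n_filler:
            # fillers are patchily present (prevalence ~0.3) so they stay
            # below the core prevalence threshold; only designated genera
            # control the core set
            present = rng.random(n_filler) < 0.3
            if not present.any():
                present[rng.integers(n_filler)] = True
            shares = np.zeros(n_filler)
            shares[present] = rng.dirichlet(np.ones(int(present.sum())))
            abund[i, len(core_spec):] = shares * (1.0 - designated[i])
    return coremicrobiome.AbundanceTable(
        abundances=pd.DataFrame(abund, index=samples, columns=genera),
        labels=pd.Series(labels, index=samples),
    )


def generate_gene_weight_table(table: metaconnect.FunctionTable,
                               seed: int,
                               dataset_read_pairs: float = 1e8) -> pd.DataFrame:
    """Per-gene coverage/expression weights consistent with a function table.

    One marker gene per (MAG, function) incidence, with the function-table
    coverage as the normalized gene coverage, a Poisson read count, and TPM
    computed across each MAG's genes.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for mag in table.incidence.index:
        for func in table.incidence.columns:
            if not table.incidence.loc[mag, func]:
                continue
            cov = float(table.coverage.loc[mag, func])
            length = int(rng.integers(600, 1800))
            count = int(rng.poisson(cov * length / 150.0))
            rows.append({"mag": mag, "gene": f"{mag}.{func}", "function": func,
                         "count": count, "length": length,
                         "coverage": cov * 1e8 / dataset_read_pairs})
    df = pd.DataFrame(rows)
    tpm = np.zeros(len(df))
    for mag, sub in df.groupby("mag"):
        rate = sub["count"] / sub["length"]
        total = rate.sum()
        if total > 0:
            tpm[sub.index] = 1e6 * rate / total
    df["tpm"] = tpm
    return df


def generate_haplotype_counts(n_pairs: int, coupling: float, depth: int,
                              seed: int) -> pd.DataFrame:
    """Joint haplotype counts for SNV pairs with tunable linkage.

    ``coupling`` in [0, 1] scales the disequilibrium D from independence (0)
    to its maximum given the allele frequencies (1).
    """
    if not 0.0 <= coupling <= 1.0:
        raise ParameterError("coupling outside [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for k in range(n_pairs):
        p_a, p_b = rng.uniform(0.2, 0.8, size=2)
        d_max = min(p_a, p_b) - p_a * p_b
        d = coupling * d_max
        probs = np.array([p_a * p_b + d, p_a * (1 - p_b) - d,
                          (1 - p_a) * p_b - d, (1 - p_a) * (1 - p_b) + d])
        counts = rng.multinomial(depth, probs)
        rows.append({"pair_id": f"pair_{k + 1:03d}", "n_AB": counts[0],
                     "n_Ab": counts[1], "n_aB": counts[2], "n_ab": counts[3]})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# readers/writers


def write_allele_matrix(matrix: pd.DataFrame, path) -> None:
    write_tsv(matrix, path)


def read_allele_matrix(path) -> pd.DataFrame:
    df = read_tsv(path)
    for col in ("pos", "nA", "nC", "nG", "nT"):
        df[col] = df[col].astype(np.int64)
    return df


def write_truth_table(truth: pd.DataFrame, path) -> None:
    write_tsv(truth, path)


def read_truth_table(path) -> pd.DataFrame:
    df = read_tsv(path)
    df["swept"] = df["swept"].astype(bool) if df["swept"].dtype != bool \
        else df["swept"]
    return df


def write_fasta(sequences: dict[str, str], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gene_sequences(scenario_result: PileupScenario, path) -> None:
    """FASTA of coding-strand gene sequences (for N/S classification checks)."""
    seqs = {}
    for g in scenario_result.genes:
        s = scenario_result.reference[g.start - 1:g.end]
        if g.strand == "-":
            s = s[::-1].translate(_COMPLEMENT)
        seqs[g.gene_id] = s
    write_fasta(seqs, path)
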