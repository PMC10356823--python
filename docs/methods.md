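# Methods

`plumeomics` re-implements, as one tested pipeline, the quantitative analyses
used to characterize hydrothermal-plume microbiomes: a thermodynamic energy
landscape for the vent-fluid/seawater mixing gradient, omics-weighted
attribution of that energy to electron donors, community metabolic
connectivity (MW-scores) and functional networks, bipartite reaction-network
complexity, population-level microdiversity with gene-specific sweep screens,
replication-rate (ori/ter) estimation, and core-microbiome identification.
This note records the models, their assumptions, the defaults that matter,
and the limits of what the synthetic data can show.

## Geochemical mixing and energy landscapes

A plume parcel is modeled as a conservative two-end-member mixture: for
vent-fluid mass fraction `f`, every species concentration and the temperature
are linear interpolations between the end-member fluid and bottom seawater
(2 °C default). Conductive cooling, mineral precipitation/dissolution, and
redox re-speciation along the mixing path are deliberately omitted; full
reaction-path models treat these, and their omission is the main fidelity
limit of this desk-scale model. Consequences: metal and sulfide
concentrations at low `f` are upper bounds (no sulfide/metal precipitation),
and the temperature–composition relation is exactly linear.

In-situ reaction energetics use `ΔG_r = ΔG°(T) + RT ln Q` with activities
`a_i = γ_i·m_i` (molality), the Davies equation (`A = 0.51`) for ionic
activity coefficients, unit activity for water and solid phases, and `γ = 1`
for dissolved neutral species. `ΔG°(T)` comes from a packaged per-reaction
table at {2, 25, 55, 100, 121} °C with linear interpolation; the packaged
values are rounded literature magnitudes for the reactions as written
(nominal 500 bar) and are user-overridable — analyses that depend on the
absolute calibration of `ΔG°` should supply their own tables. The default
reaction set couples the eight plume electron donors (HS⁻, S⁰, S₂O₃²⁻, H₂,
CH₄, NH₄⁺, Fe²⁺, Mn²⁺) to O₂, with NO₃⁻(→N₂) variants for the sulfur species
and hydrogen; every stoichiometry is charge- and element-balanced (validated
at load time).

Available energy density per reaction is `E_r = max(0, −ΔG_r) · L_r` (J per
kg fluid), where `L_r = min_i m_i/|ν_i|` over consumed species — the
limiting-reagent rule. Water, H⁺ and OH⁻ are excluded from the minimum:
seawater pH (~10⁻⁸ mol/kg free protons) would otherwise cap every
proton-consuming oxidation at negligible yields, which misrepresents a
buffered system. Solid phases (S⁰ as suspended elemental sulfur) do count as
limiting inventory; a chemistry table without S⁰ gives S⁰ oxidation zero
energy. Percent yields are `P_r = 100·E_r/ΣE` (summing to 100 whenever
`ΣE > 0`), and biomass is `B = ΣE / biomass_yield` with `biomass_yield` an
explicit parameter (default 10⁴ J per g dry cells); no canonical constant is
asserted, and only proportionality is meaningful.

## Omics-weighted donor attribution

Community energy is attributed to electron donors by
`contribution(d) ∝ Σ_{r∈reactions(d)} w_r · |min(0, ΔG_r)|`, where `w_r` is
the summed marker-gene weight mapped to reaction `r` — normalized gene
coverage (per 100 M read pairs) on the metagenome basis, TPM on the
metatranscriptome basis; the two bases run through the same code path and
differ only in the weight column. Endergonic reactions are clamped to zero
so they never contribute regardless of coverage. `|ΔG|` is taken per mole of
reaction as written (not per mole of donor); this is the documented
convention. The marker→reaction map is packaged as editable data
(sqr/fccB→sulfide, dsrAB/sdo→S⁰, soxB→thiosulfate, hydrogenase→H₂,
pmoA/mmoX→CH₄, amoA→NH₄⁺, cyc2→Fe, mnxG→Mn), with an identity fallback for
weight tables that already use reaction ids.

The O₂/NO₃⁻ acceptor balance enters as a single ratio `ρ` (default
`[O₂]/([O₂]+[NO₃⁻])` from the mixture state): aerobic reaction terms are
weighted by `ρ`, nitrate-coupled terms by `1−ρ`, each with the ΔG of its own
landscape. Per-function taxon shares are each taxon's fraction of the
function's total gene weight; shares strictly above 10% are flagged as major
contributors.

## MW-scores and functional networks

For a MAG×function table with incidence `g_m(F)`, per-(MAG, function) gene
coverage `a_m(F)` and MAG relative abundance `A_m`:

    w(F) = Σ_m A_m g_m(F) a_m(F)      s(F) = (#MAGs encoding F) / #MAGs
    MW(F) = 100 · s(F) w(F) / Σ_G s(G) w(G)

so widely shared *and* abundantly covered functions score high; scores sum
to 100. The scoring function is pluggable (`weight_fn`) so an alternative
community-metabolism scorer can be swapped in without touching the network
code. Note that because both `s` and `w` grow with sharing, two functions
with equal per-MAG coverage but 4:1 sharing differ 16:1 in score; a fixture
that isolates sharedness must hold `w` equal.

The functional network connects two functions when at least one genome
encodes both (genome-co-occurrence reading of connectivity; a shared-compound
variant is available behind `edge_mode`). Node size is the function's total
gene coverage and edge weight the mean of the two node sizes, matching the
convention that edge thickness reflects the average coverage of the two
connected steps.

## Reaction-network complexity (BDM)

The community reaction network is bipartite: compound nodes and reaction
nodes (with percent-yield attributes, default taken at 3.0 °C), directed
substrate→reaction→product edges. Complexity is estimated by the Block
Decomposition Method on the binary adjacency matrix in a fixed canonical
ordering — compounds then reactions, each lexicographic — because BDM is
ordering-sensitive and a canonical ordering makes `C` well-defined and twin
motifs exactly symmetric. The matrix is partitioned into `block_size²`
zero-padded blocks (default 4×4) and

    C = Σ_{unique block patterns} ( κ(pattern) + log₂ multiplicity ).

The default per-block complexity `κ` is a Shannon block-entropy surrogate,
`κ(u) = block_size²·H(bit frequency) + 1`, which preserves the BDM
aggregation structure (the `log₂ multiplicity` law, pattern deduplication)
without external lookup tables; a Coding-Theorem-Method table can be loaded
from TSV (`--kappa ctm:<file>`) when absolute algorithmic-complexity
estimates are wanted. Absolute `C` values therefore depend on `κ` and are
comparable only within one configuration.

Each reaction node's contribution is `ΔC(v) = C(G) − C(G∖v)`, computed by
removing the node with its incident edges, recomputing `C` from scratch, and
restoring the node — so results are independent of evaluation order.
Positive `ΔC` means the reaction contributes structure.

## Microdiversity and sweep screens

Inputs are per-site A/C/G/T counts for two pooled groups (`env1` =
hydrothermal, `env2` = open-ocean background) mapped against one genome.
Upstream read filtering (read-pair identity >95%, paired-insert-size rules)
is an input contract, not re-implemented: the counts are assumed clean.

Calling and statistics follow strain-profiling conventions: callable sites
have coverage ≥ `min_cov` (5); variant alleles need frequency ≥ `min_freq`
(0.05) and count ≥ `min_count` (2); consensus ties break alphabetically;
π = 1 − Σp² from read frequencies with no sample-size correction; consensus
frequency means are taken over called SNV sites; genome N/S is the ratio of
total N to total S SNV counts (robust to genes with S = 0). Per-gene N/S
uses S=0,N>0 → +∞ (passes strict `>` comparisons) and S=N=0 → NaN (fails
all comparisons). SNV effects are classified strand-aware against the
reference codon; stop↔sense counts as N. Note that at sites where the
consensus differs from the reference, a residual reference allele above the
calling threshold is reported as a (trivially synonymous) variant — the
inStrain convention of reference-relative calls. Genomes with
breadth_minCov < 50% are flagged excluded.

Per-gene differentiation uses the Hudson FST estimator as a ratio of sums
over usable sites (both groups covered ≥ `min_cov`, ≥2 reads over the two
retained alleles, pooled minor allele observed):

    num = (p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)
    den = p1(1−p2) + p2(1−p1)

with `n` the retained read counts. The genome-wide mean and standard
deviation are computed over genes with defined FST (per-site pooling is
available as an option); negative FST values are retained in the mean/std —
the positivity requirement appears only in the sulfur screen. A gene's FST
is NA when no site is usable or the summed denominator is zero.

The **high-FST screen** flags a gene only when all hold: FST > mean + 2.5·sd;
both gene coverages (mean depth over the gene) strictly > 5×; env1 gene π
below the genome mean and below the gene's env2 π; env1 gene N/S above the
genome ratio and above the gene's env2 N/S. A genome is skipped when more
than half its genes have undefined FST. The **sulfur fixation screen**
(sat, aprA, sdo, oxidative dsrAB, soxBCY tags) is deliberately less
stringent: FST above a strictly positive genome mean, π lower and N/S higher
in env1 than env2, both coverages > 5×. Because it drops the 2.5σ rule, it
can produce occasional calls under a pure null; the high-FST screen does not.

`r²` linkage is computed from joint haplotype counts per SNV pair
(`(p_AB − p_A p_B)² / (p_A(1−p_A) p_B(1−p_B))`, monomorphic pairs skipped);
read-level haplotype extraction is out of scope, so counts are supplied (or
simulated).

## Index of replication

Replicating populations have more coverage near the replication origin; the
coverage model on a circular genome is `depth · ratio^(1−2d(x)/L)` with
`d(x)` the distance from the origin, so the window depths' quantile function
is linear in log₂ with slope log₂(ratio). The estimator smooths the track
with a circular moving average (default width 5% of the track, mirroring the
~50× overlap of 5000-bp windows at 100-bp step), log₂-transforms, sorts,
assigns normalized ranks over the *full* sorted track, trims outside the
5/95 percentiles, decimates to one value per smoothing width, and fits a
least-squares line; the index is `2^slope`. Keeping pre-trim ranks makes the
slope an unbiased estimate of log₂(ratio); the pre-smoothing is what keeps
the estimate within a few percent under independent per-window noise (CV
0.1), because sorting otherwise inflates the quantile spread by the noise
variance. Sorting makes the estimate exactly invariant to genome rotation
(origin unknown) and to uniform depth rescaling; a perfectly flat track is
returned as index 1.0 with R² defined as 1.

Acceptance gating: R² ≥ 0.90 and mean depth ≥ 5×. The R² gate screens
violations of the single-origin exponential *shape* (multimodal or plateaued
coverage); it is not a noise detector — heavy iid window noise (CV ≈ 1)
still yields a smooth quantile curve with high R² while biasing the index
upward, so over-dispersed tracks should be judged by their residual noise,
not by this flag. GC-bias correction is omitted (synthetic tracks carry no
GC structure).

## Core microbiome

A genus is core when it occurs (abundance > `presence_eps`, default 0: any
nonzero value) in strictly more than 66% of plume samples *and* its mean
relative plume abundance strictly exceeds 1%; background samples never enter
the filter. ">66%" is the literal decimal 0.66, not 2/3 — the difference
matters only at exact boundaries, which the strict inequality excludes
anyway. Trait profiles join core genera to MAG function tables by the union
rule (a trait is present iff any mapped MAG encodes it); genera without
mapped MAGs get NA rows. Tightening either threshold can only shrink the
core set.

## Synthetic data: what it emulates and what it does not

The generators are pure functions of (parameters, seed) — fixed seed gives
byte-identical outputs — and every table round-trips through the package's
TSV readers/writers.

**Two-population pileups.** One 36-kb genome with 100 non-overlapping 300-bp
genes (alternating strands), per-site depth Poisson(50), and multinomial
read counts through a uniform 0.1% error channel — a post-filter Illumina
error scale, consistent with the >95%-identity read-filter contract. Each
gene carries 8 synonymous (3rd-position) and 2 nonsynonymous (1st-position)
standing variants at ancestral frequencies U(0.25, 0.45), with a ±2% drift
between the groups. Swept genes (5%) additionally get: standing variation
purged from env1; six 1st-position, codon-verified nonsynonymous divergent
sites pushed to ~0.98 in env1 while env2 stays near 0.45; and two
env1-private nonsynonymous variants at 12% (young post-sweep mutations). All
transformations scale with `divergence_swept`, so a null scenario (both
divergences 0) makes the two groups draws from identical truths. This
emulates the *signal structure* the screens assume — it does not emulate
linked selection, recombination tracts, strain mixtures, mapping bias, or
compositional reference bias; passing recovery tests shows the screens
detect the designed signature at 50× depth, not that they are robust to
those real-data effects.

**Coverage tracks** follow the circular ori→ter exponential with window
depth evaluated at the window start and multiplicative lognormal noise of
unit mean. **Vent chemistry** ships four contrast profiles (methane-rich,
anchored at CH₄ = 63.4 mmol/kg; metal-rich with Mn/Fe in the 3.9–6.3 /
3.8–13.1 mmol/kg ranges; hydrogen-rich; sulfide-rich) over a common major-ion
matrix. **Function tables** use complete/disjoint/Bernoulli sharing with
lognormal coverage weights and Dirichlet MAG abundances. **Abundance
tables** hit requested (prevalence, mean abundance) pairs exactly for
designated genera and fill the remainder with patchy (≈30% presence) filler
genera that rarely clear the prevalence threshold by chance; with few plume
samples an occasional filler can still pass — controlled experiments should
judge designated genera, not the filler tail.

## Numerical conventions and degenerate inputs

- TSV everywhere, header line, missing values "NA"; floats written at full
  round-trip precision.
- Consensus and pooled-allele ties break alphabetically (A<C<G<T).
- A mixture with total energy 0 is reported as a degenerate landscape with
  all percent yields 0 (not an error).
- Zero product activities enter ln Q at a 10⁻¹² floor; a missing reactant
  makes ΔG = +∞ (and the limiting rule independently zeroes the energy).
- FST std uses ddof = 1; "more than half undefined" genome skips are strict.
- All RNG is `numpy.random.default_rng(seed)`; the pipeline derives stage
  seeds by fixed offsets from the run seed.

## Problem sizes

Tests and the acceptance script run the study conditions at desk scale: the
sweep experiments use the 100-gene, 50×-depth scenario over 10 recovery
seeds and up to 100 null seeds; replication-rate recovery uses 1000-window
tracks over ratios {1.2, 1.5, 2.0} × CV {0, 0.1} × 30 seeds; ΔC oracle
checks use 50 random bipartite networks of ≤12 nodes. The demo pipeline
(`plume run --demo`) completes in a few seconds on one CPU.

## Known limitations

- Conservative mixing only; no mineral equilibria, no pressure corrections
  beyond the fixed nominal-pressure ΔG° tables, no kinetics.
- Packaged ΔG°(T) values are approximate; treat absolute energies and
  biomass as order-of-magnitude unless calibrated tables are supplied.
- The entropy-surrogate κ is not an algorithmic-complexity estimate; only
  the BDM aggregation structure and relative ΔC patterns are meaningful
  without a CTM table.
- The MW-score formula realizes the documented sharedness×abundance
  definition; the upstream community-metabolism tool's exact scoring can be
  substituted via `weight_fn` if its definition differs.
- Single-contig genomes are assumed for microdiversity and growth
  estimation; draft-genome scaffold ordering is out of scope.
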