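# Methods

## The inference problem

A typical modern sugarcane cultivar carries about twelve hom(oe)ologous
copies of each chromosome segment. Sequence comparison of such haplotype
sets reveals three clusters — a major group A and two minor groups B and C —
and the question is where each group came from. The package infers this by
combining five analyses: presence/absence genotyping of accession panels
against a monoploid reference, reciprocal specific-SNP classification
between haplotype groups and germplasm pools, synonymous-divergence dating
of the group splits, an alignment-free phylogeny of the haplotype segments,
and an ordination step that screens the accession panels for interspecific
hybrids before they can contaminate the pool definitions.

## Simulator

`simdata` generates the study conditions every stage is validated under.

**Founders.** A uniform-random ancestral sequence of length L evolves on the
fixed topology ((A,B),C) with split ages t_AB = 0.84 Myr and t_ABC = 1.29
Myr and clock rate μ = 6.5 × 10⁻⁹ substitutions·site⁻¹·yr⁻¹. Each of the
four branches (A, B, their internal ancestor, C) receives a Poisson number
of substitutions with expectation T_branch · μ · L under a Jukes–Cantor
model (uniform base exchange, no indels). Substitution positions are drawn
without replacement across branches, so every planted allele is
re-derivable by diffing the emitted sequences; expected substitutions ≥ L
raises a saturation error rather than being modelled. At the Ks ≤ 0.1
scales used here this single-hit bookkeeping is adequate.

**Mapping reference.** The default reference is the ancestral (root)
sequence. With the reference taken from inside one lineage, every
substitution fixed on that lineage's branch is baked into the reference
and can never surface as an alternate allele, making that group's private
alleles structurally unobservable in a clean simulation; the root
reference keeps all three lineages' private alleles visible as ALTs (the
real-world analogue — a cultivar-derived mosaic reference — recovers
A-specific SNPs through within-group polymorphism instead).
`SimulationConfig(reference="A")` selects the lineage-A reference for
experiments on that regime.

**Accessions.** Each species class is a haplotype multiset over the
founders: *S. officinarum* and *S. robustum* {A:6, B:2}, *S. spontaneum*
{C:8}, modern cultivar {A:9, B:2, C:1}; default panel sizes 4 + 2 vs 6
accessions plus one cultivar. Within-pool polymorphism adds
Poisson(θ · L) extra sites per class (default θ = 10⁻³), each private to a
random non-empty subset of that class's accessions and to a random number
of copies of one lineage — enough structure to perturb pool-specificity
without a full coalescent. The defaults emulate the published panel shape
at desk scale; published SNP totals depend on the real accession panels
and are not reproduction targets.

**Depths.** Per site and accession, depth ~ negative binomial with mean 60
and dispersion 0.2 (variance m + d·m²; Poisson at d = 0), mimicking
capture/WGS overdispersion. Alt reads ~ Binomial(depth, p_eff) with
p_eff = p(1−e) + (1−p)e/3, p the alt-haplotype dosage fraction and
e = 10⁻³ the per-read error rate (a non-alt read is misread to the
specific alt base a third of the time). Fixtures serialize to FASTA,
multi-sample VCF 4.2 with DP/AD, and TSV panel/metadata/truth tables.

**Haplotype panel.** The panel mirrors BAC haplotypes of the cultivar
class: one panel haplotype per copy (A1..A9, B1, B2, C1), full site
coverage by default, with an optional coverage fraction that masks a
contiguous block per haplotype to emulate partial BAC overlap.

## Genotype coding

Rules and boundary semantics: MISSING below depth 30 (inclusive
threshold); PRESENT at alt ≥ 2 and frequency ≥ 4 % (both inclusive);
ABSENT at alt = 0, or alt = 1 with frequency strictly below 1 %; all other
cells MISSING. The frequency denominator is the total site depth by
default; since read counts other than ref+alt could arguably be excluded,
`freq_denominator="refalt"` is available and the choice is recorded in the
config. Multi-allelic VCF records are decomposed into independent
presence/absence tests per alternate allele; indels are skipped. VCF
coordinates are 1-based inbound and on all outputs.

## Specificity analysis

A site is **group-specific** when every group has at least
`min_group_coverage` (default 1) covered haplotypes there and carriers
occur in exactly one group. Carriage by a single haplotype suffices —
diagnostic alleles need not have fixed within a group — and uncovered
haplotypes do not veto a call, though the per-group coverage minimum must
hold; the per-SNP carrier counts are emitted so stricter readings can be
applied downstream.

Group-specific SNPs are then located among pool representatives:
POOL-labelled when ≥ `min_carriers` (default 2) accessions of exactly one
pool carry them and none of the other pool does, ANCESTRAL when both pools
carry them (pre-dating the pools' separation), UNINFORMATIVE otherwise.
Classification requires data in ≥ `min_pool_data` accessions of both pools
(default 5; configurable per run, e.g. 3 for sparsely covered regions).
The reciprocal analysis applies the same carrier rule genome-wide and maps
each pool-specific SNP to the combination of haplotype groups carrying it
(A, B, A-and-B, C); combinations outside these four are reported under an
explicit `other` column rather than dropped.

**Verdicts.** Each group is assigned the pool with the strictly greater
supporting count in *both* cross-tabulations; minority SNPs are listed as
exceptions and more than `max_exceptions` (default 1) of them marks the
verdict as conflicted. Ties or disagreements give UNRESOLVED. In the
second analysis the A-and-B column supports groups A and B alike, since
such SNPs attest to the pool origin of both groups. Hybrid accessions
(flagged by ordination or supplied explicitly) are excluded from the pool
representatives before any carrier counting; the exclusion list is an
explicit input for reproducibility.

## Ks dating

NG86 site counts: per codon position, the synonymous fraction of viable
single-base neighbours, mutations to stop codons excluded from the viable
set; s + n = 3 per codon. Differences: multi-base codon pairs are averaged
over all orderings of single-base steps whose intermediates are sense
codons (classical unweighted pathway averaging); pairs whose every pathway
crosses a stop are masked and logged. S is the mean of the two sequences'
site totals, ps = Sd/S, and Ks = −(3/4)·ln(1 − (4/3)·ps); ps ≥ 3/4 raises
a saturation error. Codon columns containing gaps, ambiguity or stops are
masked pairwise (per sequence pair), not alignment-wide.
Back-translation threads each CDS onto its aligned protein row, verifying
the translation residue-by-residue.

Group-pair summaries report both pooled means (arithmetic over all gene
pairs across regions — regions with more pairs weigh more) and per-region
means; published per-region tables imply count weighting that cannot be
reconstructed from printed region means alone, so the pooled mean is the
primary statistic and no attempt is made to force agreement. Ages use
T = K̄s/(2μ) with μ = 6.5 × 10⁻⁹ yr⁻¹, reported in Mya rounded half-up to
2 decimals. One reported value (the *Miscanthus* duplication, mean Ks
0.0513) prints as 3.94 Mya although half-up rounding of 0.0513/(2μ) gives
3.95; the package reproduces the other six conversions exactly and leaves
this one to the rounding convention.

## k-mer phylogeny

Profiles are the sets of distinct 30-mers (windows containing N skipped);
"homopolymeric" is read literally as a k-mer of a single repeated base —
no low-complexity filter beyond that. Distance is the raw symmetric
difference count, matching the definition "number of k-mers that differ";
a normalized variant |p △ q| / (|p| + |q|) is available behind a flag.
Haplotype segments are co-oriented, so no strand canonicalization is done
by default (a flag enables it for unoriented input). Tree building is
neighbour-joining (Saitou–Nei criterion with Studier–Keppler updates, via
scikit-bio) with negative branch lengths clamped to zero — the
distance-tree algorithm is our choice, recorded here, as the alignment-free
toolchain this step models does not pin one down.

## Ordination

Accession dissimilarity is the simple mismatch proportion of
presence/absence calls over co-genotyped sites (the simplest convention
consistent with presence/absence data; pairs with no shared sites are
flagged and mean-imputed before embedding). The factor analysis of a
distance table is realized as classical metric multidimensional scaling
(principal coordinates, via scikit-bio): double-centred Gower matrix,
eigendecomposition, coordinates scaled by √eigenvalue; negative-eigenvalue
axes are dropped and their total magnitude reported. Hybrid flagging is
advisory: an accession whose axis-1 coordinate falls strictly between the
two pools' coordinate envelopes (optionally shrunk to central quantiles)
is returned for review — exclusion is an explicit user decision fed back
into the specificity stage, replacing a hand-drawn selection rectangle
with a reproducible rule.

## Validation scales and what passing shows

The validation experiments (in `triorigin.evaluate`, exercised by the test
suite and `scripts/acceptance.py`) use desk-scale problem sizes chosen to
keep full runs in minutes: clean recovery on 30-kb genomes with 13
accessions at 100× Poisson depth over 10–20 seeds; clock round trips on
~100-kb coding pairs over 25–50 seeds; NJ topology recovery on 25-kb
segments with 12 haplotypes over 20–40 seeds. On clean fixtures (error
rate 0, within-pool θ 0) the specific-SNP labels recover the planted
registry with precision and recall 1.0 and verdicts A→officinarum/robustum,
B→officinarum/robustum, C→spontaneum in every seed.

The simulator omits several features of real data: no recombination or
mosaic haplotypes, no aneuploidy, no alignment/mapping artefacts, no
shared ancestral polymorphism between pools (so the ANCESTRAL column is
populated only via within-pool mutation coincidences), and no selection.
Passing the recovery tests therefore shows the classification rules and
their thresholds are implemented and composed correctly — not that the
rules are robust to reference bias, paralogous mapping, or panel
mislabelling in real accession collections.

## Numerical and degenerate-input choices

Codon-pair and site counts are precomputed into 64-index lookup tables, so
Ks over long alignments is vectorized; results are identical to the
per-codon enumeration functions that build the tables. NJ input matrices
must be symmetric (enforced by the distance-matrix container); three taxa
use the closed-form star formulas. PCoA eigenvalues below 10⁻¹² are
treated as zero. Zero-length genomes, empty haplotype multisets,
non-positive depth means, stop-containing CDSs, k ≤ 0, and pools without
representatives raise errors; k longer than the sequence yields an empty
profile (logged), and an empty VCF body yields an empty matrix.
All randomness flows from per-stage `numpy` generators seeded from the run
seed, so one seed gives byte-identical outputs.
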