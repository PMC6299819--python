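# Methods

## The problem

ComEC is the inner-membrane channel that imports single-stranded DNA during
bacterial natural transformation. Because full-length ComEC sequences are too
divergent for global identification, the analysis operates on *Competence*-
domain-containing proteins (CDCPs): any protein with a filtered profile-HMM
hit to Pfam PF03772. Each protein is summarized by the combination of three
domains — *DUF4131* (PF13567, "D"), *Competence* (PF03772, "C"), and
*Lactamase_B* (PF00753, "L") — giving the profile states C, DC, CL, DCL; any
additional co-occurring domain folds the protein into OTHER, and a strain
with no CDCP is NC. The package implements four analysis stages over these
states plus a synthetic-data generator that makes every stage testable at
desk scale.

## Hit filtering and classification (`domarch.profiles`)

Domain hits are read from the HMMER3 `--domtblout` column layout in the
hmmsearch orientation (query = profile HMM, target = protein), so the model
length is the `qlen` column and model coverage is
`(hmm_to − hmm_from + 1) / qlen`. The filtered score is the independent
("i-Evalue") column. A hit survives if e-value ≤ 1e-5 **and** model coverage
≥ 0.70; both boundaries are inclusive keeps, since the removal rule excises
strictly-greater e-values and strictly-smaller coverages. Protein names
follow the convention `<proteome>|<protein>` so each hit is attributable to
a strain; this is a convention of this package, as the HMMER format carries
no proteome column.

A strain with several CDCPs takes its state from the longest one (ties by
lexicographically smallest protein id): the only multi-CDCP case observed in
real data is a truncated duplicate of the full-length protein. Domain
multiplicity within a protein collapses to presence/absence for state
assignment; the ordered multiset of domains is retained for reporting. A
strain with no CDCP is checked for a genomic *Competence* fragment via
blastn hits (`-outfmt "6 qseqid sseqid pident length evalue qcovs"`)
filtered at e-value ≤ 1e-5, query coverage ≥ 30%, identity ≥ 60% (all
inclusive).

Presentation rounding in the census report is half-up (presence percentages
to integers, per-domain occurrence percentages to one decimal); stored
weights and distances are never rounded.

## Proportional species weighting (`domarch.weighting`)

Genome collections over-represent heavily sequenced species. Every strain
contributes a relative count of 1/(number of strains of its species), so
each species carries unit weight; taxon-level state frequencies divide the
summed relative counts by the taxon's species count and therefore sum to 1
per taxon. The defining property — invariance to k-fold duplication of a
species' strains — is asserted as a property test. Where one state per
species is needed (tree leaves), the dominant state is used, with ties
broken by the fixed order NC < C < DC < CL < DCL < OTHER. Exact fractional
weights are used throughout rather than integer subsampling of proteomes;
the subsampled representative set of the original study is not reproduced.

## Equal-rates ancestral-state reconstruction (`domarch.asr`)

The five-state model (NC, C, DC, CL, DCL) is the Mk/ER continuous-time
Markov chain: one rate μ for every ordered pair of distinct states,
generator Q = μ(J − kI), and closed-form kernel
P_ii(t) = 1/k + (1 − 1/k)e^{−kμt}, P_ij(t) = 1/k(1 − e^{−kμt}). OTHER
strains are reduced to the core state implied by their D/L content before
reconstruction (a protein with extra domains still carries at least the
Competence domain).

The likelihood of tip states uses Felsenstein's pruning algorithm with
per-node rescaling against underflow and a uniform root prior (1/k). Zero-
length branches are allowed (P(0) = I); tip configurations of probability
zero return −∞. μ is fitted by bounded scalar search on [1e-8, 100]: a
50-point log-spaced grid locates the basin (guarding against flat surfaces)
and Brent's bounded method refines to an absolute tolerance of 1e-8 on the
rate. Monomorphic tips make the rate unidentifiable (the likelihood is
monotone decreasing in μ); the lower bound is returned with a
`rate_at_bound` flag. Note the usual rate–time confounding: doubling all
branch lengths halves μ̂ and leaves the maximized likelihood unchanged.

Posteriors are **true marginal posteriors** from the up–down (outside)
algorithm — posterior ∝ inside × outside per node — not root-conditional
scaled likelihoods; some implementations of `ace`-style reconstruction
report the latter, and the two conventions differ away from the root. Both
the log-likelihood and the posteriors are verified in the test suite
against an exhaustive enumeration oracle (matrix-exponential kernel, sum
over all joint ancestral assignments) on hundreds of random small trees, to
1e-10 relative and 1e-9 absolute respectively.

## Distance comparison and transfer screening (`domarch.treedist`)

Cophenetic (patristic) distances are computed by a single post-order sweep
(O(n²)). Two normalization conventions are used: domain-tree matrices are
divided by their own maximum pairwise distance; species-tree matrices by
the maximum over CDCP-containing strains only, so entries involving
CDCP-free strains may exceed 1. Pairs of strains sharing a profile are
grouped per domain tree — C/DC/DCL/CL for *Competence*, DC/DCL for
*DUF4131*, CL/DCL for *Lactamase_B*; each unordered pair is counted once.
Within each group, domain distance is regressed on species distance by
unweighted OLS (matching common practice, despite the non-independence of
pairs sharing a strain — a Mantel-type correction is a noted extension).

Candidate horizontal acquisitions are pairs whose standardized residual is
below −z (default z = 3): the domain copies are far closer than the species
history predicts. Residuals above +z flag unexpectedly divergent domains.
The quantitative threshold is this package's addition — the original
screening was visual — and is configurable. When the relation is exactly
linear the residual SD is numerically zero and nothing is flagged.

## Synthetic data (`domarch.synth`)

The generator emulates the statistical structure of the real corpus:

- **Species trees** are ultrametric pure-birth (Yule) trees: with k
  lineages the epoch lasts Exp(kλ), so expected height is Σ_{k=2..n} 1/(kλ)
  (asserted over replicates). An optional LogNormal(0, σ) branch jitter
  emulates the rate variation of real trees, which are not ultrametric.
- **Profiles** evolve by Gillespie simulation of the ER process (waiting
  times Exp((k−1)μ), uniform jumps), checked against the analytic kernel by
  Monte Carlo. The default rate (μ = 0.05, giving μ·height ≈ 0.2 on the
  default 64-leaf tree) reflects the observed conservation of profiles
  within taxa; at much higher rates the process mixes and root information
  is genuinely lost (root-state recovery degrades — a property of the
  model, not of the inference).
- **Transfers** form a Poisson process on branches (or an exact requested
  count). An event copies the donor lineage's profile state at the event
  time into the recipient lineage (whose subtree re-evolves from it) and,
  in the emitted domain tree, regrafts the recipient subtree as sister to
  the donor at the event time, preserving the tip count. Transfers are
  modeled at the domain/state level, not the sequence level — sufficient to
  exercise the distance-based screening.
- **Strain corpora** draw per-species strain counts from a configurable
  oversampling distribution (default 90% singletons, 7% five-strain, 2%
  twenty-strain, 1% 199-strain species, echoing the *E. coli*-like extreme)
  with a 5% per-strain chance of a deviant profile; 64% of CDCP-free
  strains carry a genomic fragment, the fraction observed in the real
  census (409 of 640).
- **Hit tables** realize each strain's profile as domtblout rows with
  e-values log-uniform on [1e-30, 1e-5] and coverages uniform on
  [0.70, 1.0]; a configurable fraction of decoy hits is placed just past a
  threshold (e-value 1.0001e-5, or coverage 0.69) to exercise the filter.
  Integer model spans are rounded toward the intended side of the coverage
  threshold.

What the generator does **not** emulate: sequence evolution (no alignments,
no FASTA), realistic Pfam score distributions, gene duplication beyond the
one scripted truncated copy, and non-binary or non-ultrametric species
histories (beyond the jitter option). Passing tests therefore demonstrate
correctness of the algorithms under the stated model, not robustness to
real-data artifacts such as annotation errors or alignment uncertainty.

A separate census builder constructs a 5,574-strain corpus whose profile
totals match the published counts (4,934 CDCP proteomes; one strain with a
second truncated Competence-only copy, for 4,935 CDCPs; 3,279 DUF4131 and
2,583 Lactamase_B occurrences; 409 genomic rescues; 231 residual strains).
The published material states only the marginal D and L occurrence counts,
not the joint profile split; the builder fixes n(DCL) = 2000, which
determines DC = 1279, CL = 583, C = 1022 + 1, OTHER = 50 — all reported
percentages depend only on the marginals.

## Problem sizes

The shipped analyses and checks run at desk scale by design: 64-species
demonstration corpus (~300 strains), 128–256-leaf trees for rate and
root-state recovery (30–50 replicates), ≤ 6-leaf trees for the enumeration
oracle (200 draws), 5,574 strains for the census. The full published corpus
(5,574 genomes against Pfam, 2,373-leaf trees) and its figure-level numbers
(slopes 0.61–0.91, offsets 0.16–0.25, R² 0.38–0.69) are out of scope; the
property-based suite covers those claims qualitatively.

## Known limitations

- The ER model's single rate cannot express asymmetric gain/loss dynamics
  (e.g. domain loss being easier than gain); all-rates-different variants
  are out of scope.
- Transfer detection conditions on both strains sharing a profile, so
  transfers that change the recipient's profile relative to the donor's
  clade, or old clade-level transfers, can evade the low-residual flag (the
  demonstration analysis shows exactly this).
- OLS over strain pairs ignores pair non-independence; slopes are
  descriptive, not inferential.
- The dominant-state rule for species with heterogeneous strains is a
  declared convention; other choices (e.g. weighted likelihoods at tips)
  would be defensible.
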