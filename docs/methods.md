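# Methods

`clutchkin` reconstructs the parentage of brood-parasite clutches from embryo
genotypes alone.  The study system is the cuckoo catfish (*Synodontis
multipunctatus*), whose embryos are recovered from the buccal cavities of
mouthbrooding cichlid hosts in Lake Tanganyika; no candidate parents are ever
sampled, so all inference rests on the progeny array itself.  This note
records the models, the numerical choices, and what the simulation-based
validation does and does not establish.

## Marker diagnostics

Allele frequencies are gene-copy counts over non-missing calls, estimated
from the adult reference sample (n = 81 wild adults genotyped at 17
species-specific microsatellite loci).  Expected heterozygosity uses the
small-sample unbiased estimator He = (2n/(2n−1))(1 − Σp²); a flag switches to
the uncorrected form.  Haplotype diversity uses the analogous Nei correction
Hd = (n/(n−1))(1 − Σp²).

The Hardy–Weinberg exact test conditions on the observed allele counts.  The
genotype-table space is enumerated completely when it holds at most 50,000
tables and at most 6 alleles (the probability of a table given allele counts
is n!·Πmᵢ!·2^het / ((2n)!·Πf_ij!); the p-value sums the probabilities of all
tables no more probable than the observed one).  Above those bounds, tables
are sampled i.i.d. from the exact conditional null by randomly permuting the
2n gene copies and pairing consecutive copies — this sampler *is* the
conditional distribution, so no Markov-chain burn-in or mixing diagnostics
are needed; the p-value is (hits+1)/(reps+1) with a fixed seed, reproducible
bit-for-bit.

Exclusion probability is reported in three classical forms: the probability
that a random non-parental *pair* is Mendelian-incompatible with a random
offspring (the default here, since this design samples no parents), the
single-candidate form, and the second-parent form.  All are exact summations
over genotype combinations under Hardy–Weinberg proportions, algebraically
collapsed to O(k²)–O(k³) sums; the test suite checks them against literal
brute-force enumeration over all genotype triples.  Multi-locus power
combines as 1 − Π(1 − P_l).

## Dyadic kinship (maximum likelihood)

Embryo pairs are classified among unrelated (UR), half sib (HS), full sib
(FS) and parent–offspring (PO) hypotheses via their IBD-sharing coefficients
k = (k0, k1, k2): UR (1,0,0), HS (½,½,0), FS (¼,½,¼), PO (0,1,0).  The
likelihood of a dyad under a hypothesis is Π_l (k0·P0 + k1·P1 + k2·P2) with
the standard genotype-pair probabilities given 0/1/2 IBD alleles; loci with a
missing call in either member are skipped.  Because every sample is an
embryo, PO has no direction; PO-maximal dyads are reported as FS.

Significance uses a Monte-Carlo likelihood-ratio test: dyads are simulated
under the alternative hypothesis at the pair's jointly typed loci (default
10,000 simulations per dyad) and the p-value is the fraction of simulated
likelihood ratios at least as large as the observed one.  When the test
cannot reject the second-ranked hypothesis at α = 0.05 the dyad is annotated
with both labels ("HS or FS").  Simulation frequencies come from the adult
reference sample; alleles seen in a dyad but absent from the reference get a
floor frequency of 1/(2n+1) with renormalisation, avoiding zero likelihoods.
Per-dyad random substreams are derived from the master seed and the two
sample ids, so batch order and pool composition never change a dyad's result.

Calibration: on unrelated dyads simulated from the default panel, the
FS-versus-UR test rejects at the nominal 5% level within Monte-Carlo error
(the acceptance suite measures this on 500 null dyads).

## Minimum-parent parsimony

The core reconstruction asks: how many parents, at minimum, can explain a
clutch?  The search space is (i) partitions of the clutch into full-sib
groups and (ii) "sharing topologies" assigning two abstract parents per
group, with parents shared across groups (half-sib links).  Candidate
parental genotypes at a locus are built from the alleles observed in the
offspring plus one wildcard allele per parent (a parent may carry an allele
it transmitted to no sampled embryo).  A shared parent's genotype is unified
across groups by enumerating concrete genotypes over the union allele space
plus an "other" symbol and checking each group's constraint after projection
to its own observed alleles.

Two structural constraints prune the space without losing solutions:

* distinct full-sib groups never share both parents — their union would then
  be a full-sib group, and that partition is enumerated anyway;
* the parent–group incidence graph must be two-colourable, because every
  mating needs one dam and one sire.  This is not cosmetic: without it,
  three parents carrying A/C, A/B and B/C arranged in a triangle would
  "explain" the single-locus clutch {A/A, B/B, C/C}, which no dam/sire
  assignment can realise; the true minimum there is four.

For clutches of up to 12 embryos (`exact_cap`; the largest field clutch holds
14) the search is an exhaustive branch-and-bound and returns *all* minimal
solutions.  A bipartite edge-capacity bound (P parents carry at most ⌊P²/4⌋
distinct group pairs) and memoised shared-parent feasibility keep it fast.
Larger clutches use seeded greedy full-sib merging with pairwise-merge local
search, flagged `exact=False`.

Ties among minimal solutions are adjudicated by the sibship likelihood
`partition_loglik`: per locus and per connected family cluster, the sum over
parental genotype assignments of Hardy–Weinberg priors times Mendelian
offspring probabilities, with shared parents collapsed to one genotype and
all unobserved alleles pooled into a single residual class (an exact
lumping).  The default scoring mode gives every observed allele equal weight
1/N_A — the flat-frequency convention that avoids inferring spurious allele
sharing between parents and hence over-counting them; empirical-frequency
scoring is available and gives nearly identical rankings on simulated data.

Genotyping-error tolerance defaults to zero mismatches.  A configurable
mismatch budget lets a putative full-sib group ignore up to that many single
locus calls when no witness parent pair exists; any solution consuming budget
is annotated with the ignored (embryo, locus) calls rather than silently
absorbed, so extra-parent inferences resting on one or two allelic
mismatches are surfaced for re-checking.

## Matriline overlay

Microsatellites cannot say which reconstructed parent is the dam.  The
mitochondrial control-region haplotype, inherited maternally, can: all
members of a full-sib group must carry their dam's haplotype, and half-sib
groups with different haplotypes must share their *father*.  Haplotypes are
obtained by stripping every alignment column containing a gap, N or IUPAC
ambiguity in any sequence (complete deletion — one informative length for the
whole alignment; a pairwise-deletion mode exists) and grouping identical
stripped sequences, labels assigned in lexicographic sequence order so the
labelling is order- and duplication-invariant.

Sexing a solution is a proper two-colouring of the parent graph (vertices =
parents, one edge per full-sib group), filtered so a dam linking several
groups sees one haplotype.  The number of distinct haplotypes in a clutch is
a hard lower bound on its dam count.  When several valid sexings exist the
one with fewer dams is preferred — one shared mother is more parsimonious
than two mothers that coincidentally share a haplotype — and every
alternative (dam, sire) profile is retained and propagated into the scenario
classification as a secondary label.  A full-sib group spanning two
haplotypes is recorded as a conflict, never repaired.  Embryos without
sequence data constrain nothing; a clutch with no haplotypes at all is
reported unsexed.

## Scenario classification and reporting

Sexed counts map to mating patterns: (1 dam, 1 sire) monogamous; (1, ≥2)
polyandrous; (≥2, 1) polygynous; (≥2, ≥2) with a shared parent
polygynandrous, without one separate pairs.  Clutches of one or two embryos
are reported "untestable", never "monogamous": any two embryo genotypes can
always be explained by a single parent pair, so only clutches with at least
three embryos carry information about multiple parentage.  Dataset summaries
report the testable count, the multi-parent fraction over testable clutches,
the median and range of testable clutch sizes, and parasitism prevalence as
parasitised/screened rounded to the nearest integer percent.  All report
files are deterministic byte-for-byte given inputs and configuration.

## Synthetic data

The simulator generates the study conditions rather than arbitrary data: the
default panel mirrors the published 17 loci (allele counts 4–22, per-locus
expected heterozygosities 0.33–0.93), realised as one major allele plus
equifrequent minors with the major frequency solved in closed form to hit the
target Σp² (monotone in He, reproducible); equifrequent and symmetric
Dirichlet schemes are available.  The maternal haplotype pool defaults to 13
haplotypes weighted to a diversity of 0.89, matching the field validation
sample, so the rate of dam-haplotype collisions (~11% per dam pair) — the
main failure mode of mtDNA sexing — is reproduced faithfully.  Parents are
drawn under Hardy–Weinberg equilibrium; embryos receive one uniformly chosen
allele per parent per locus and inherit the dam's haplotype exactly; an adult
reference sample (default 81) is drawn from the same population.  Optional
post-meiotic error applies allelic dropout (heterozygote becomes homozygous
for the remaining allele), mistyping (an allele replaced by a random other
allele of the locus) and missingness.  One seed drives everything; identical
seeds give byte-identical outputs.

The canned `study_like_design()` reproduces the field collection's shape: 13
clutches (7 monogamous, 1 polyandrous, 2 two-pair, 2 polygynous, 1
polygynandrous) with the observed clutch sizes, including one 14-embryo
clutch that exercises the heuristic search path.

What passing simulation tests establish — and what they do not: the
simulator draws unlinked loci, no null alleles, no population structure and
no relatedness among parents beyond the design.  Recovery rates measured on
it (≥95% exact parent counts for one-shared-parent designs, ≥85% for
two-family designs, on clutches of ≥5 embryos with zero error) are therefore
upper bounds on field performance.  Two limitations seen in simulation also
apply to real data and match the study's own caveats: a 3-embryo polyandrous
clutch is genuinely explainable by a single pair in a nontrivial fraction of
draws (allele sharing), so small clutches under-report extra parents; and
when two dams share a haplotype the polygyny/polyandry distinction rests on
the fewer-dams tie-break, with the alternative retained.

## Problem sizes used in validation

The acceptance checks run the exhaustive-oracle comparison on 100 random
clutches of up to 6 embryos (4 loci, 4 alleles — sizes where full partition ×
topology enumeration is tractable), LR-test calibration on 500 null dyads
with 1,000 simulations each, and parameter recovery on 200 simulated clutches
per design family.  These sizes give Monte-Carlo standard errors comfortably
inside the stated tolerance bands while keeping the full suite to a few
minutes on one CPU.

## Known limitations

* COLONY's full likelihood model (genotyping-error likelihoods, sibship-size
  priors, parental sampling fractions) is out of scope; the parsimony search
  plus likelihood tie-breaking reproduces its adjudicated outcomes on
  simulated data but is not a COLONY reimplementation.
* Null alleles are not modelled anywhere (the study's markers were screened
  for them upstream).
* The pairwise-deletion haplotype mode joins samples transitively and can
  chain through heavily ambiguous sequences; complete deletion is the
  default for exactly that reason.
* `min_parent_search` above `exact_cap` embryos is heuristic; its solutions
  are upper bounds on the true minimum and are flagged `exact=False`.
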