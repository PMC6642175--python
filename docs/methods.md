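# Methods

## The estimation problem

The package estimates the completely dispensable fraction of a PPI network:
the share of true physical interactions whose disruption is effectively
neutral with respect to organismal fitness. Direct measurement would require
deleting PPIs one at a time and measuring fitness; instead the estimator
exploits mutations that disrupt one interface at a time (edgetic mutations)
and contrasts how often *neutral* versus *deleterious* mutations do so.

## Bayesian core

Fitness classes for a new missense mutation: effectively neutral (N),
mildly deleterious (M), strongly detrimental (S), with priors
P(N) = 0.27, P(M) = 0.53, P(S) = 0.20 taken from population-genetic
estimates of the human missense fitness-effect distribution. Three
assumptions connect data to classes:

1. common variants (minor allele frequency > 1%) in healthy individuals are
   effectively neutral;
2. curated Mendelian disease mutations are mildly deleterious on average;
3. strongly detrimental mutations act by destabilizing the protein
   (quasi-null), not its interfaces, so P(E|S) = 0. Any positive P(E|S)
   (exposed via the `p_E_given_S` argument) only lowers the estimate, so
   the default is the conservative upper-bound choice.

With edgetic rates P(E|N) = k_N/n_N and P(E|M) = k_M/n_M,

    P(E)   = P(E|N)P(N) + P(E|M)P(M) + P(E|S)P(S)
    P(N|E) = P(E|N)P(N) / P(E),
    equivalently 1/P(N|E) = r·P(M)/P(N) + 1,  r = P(E|M)/P(E|N).

All arithmetic uses exact count fractions; rounding to one decimal in
percent happens only at reporting.

**Confidence interval.** The 95% CI uses the Katz log interval for the
ratio of two binomial proportions, `log r ± z·sqrt(1/k_M − 1/n_M + 1/k_N −
1/n_N)` with z = 1.96, with each ratio bound mapped through the identity
above (the ratio's lower bound gives the upper bound on P(N|E)). z = 1.96
rather than the exact normal quantile is deliberate and configurable. Zero
numerators make the log interval undefined; the estimator refuses by
default and offers a Haldane-style +0.5 correction behind a flag. A
parametric-bootstrap percentile interval (binomial resampling of both
rates) is used in the test suite as an independent cross-check; the two
intervals agree closely except that the bootstrap interval is shorter when
a numerator is very small (heavy discreteness), so agreement is measured as
overlap relative to the shorter interval.

**Variants.** `mono_edgetic` tallies only mutations disrupting exactly one
PPI in the numerators; `quasi_null_as_edgetic` accepts counts where
experimental quasi-null calls were folded into the edgetic numerators. The
arithmetic is unchanged — the tag records what the counts mean.

## Structural interactome construction

Interface residues: a residue of one chain is an interface residue iff the
minimum Euclidean distance over all atom pairs to some residue of the
partner chain is ≤ 5 Å. The rule is read inclusively at the boundary and
uses every atom present in the record (hydrogens included when present; a
heavy-atom-only flag exists because deposited structures vary in hydrogen
content). Chain coordinates are validated against the declared backbone
(SEQRES) sequence; residues disagreeing with it, or numbered outside it,
are dropped and counted. Only the first model of multi-model files is read.
Residue numbering is the 1-based SEQRES index; insertion codes are outside
the dialect.

Annotation filters, applied in order: alignment E-value ≤ 1e-10; best hit
per (protein, chain) by smallest E-value (ties: longer alignment, then
lexicographic); a candidate chain pair needs ≥ 50% of each chain's
interface residues mapped onto the respective protein; at most five
annotations per PPI, ranked by joint E-value. The joint E-value is the
product of the two hits' E-values — order-preserving for independent
alignments — with lexicographic (structure, chain, chain) tie-breaks, and a
zero E-value sorts before any positive one. The protein-side interface is
the union of mapped interfaces over the retained annotations; a
best-annotation-only mode can be had by setting `max_annotations=1`. The
coverage denominator is the chain-side interface size: "interface residues
mapped" counts chain interface residues that have an aligned protein
position. Homodimers evaluate the one protein against both chains and take
the union of both images.

## Mutation curation and mapping

Disease (ClinVar-style) records are kept when strictly labelled pathogenic
only, with at least one review star and no conflicting interpretations.
Non-disease (dbSNP-style) records are kept when validated, not withdrawn,
free of disease-assertion labels (pathogenic, likely pathogenic,
drug-response, uncertain significance, other), and common (MAF strictly
> 1%); positions overlapping mapped disease mutations are discarded. Both
sets are de-duplicated per (protein, position), keeping the smallest
mutation id — the convention is arbitrary but deterministic.

Mapping verifies the flanking sequence — up to 10 residues on each side of
the mutated residue (all available when fewer), wild-type residue included —
against the protein sequence, and requires the match to land at exactly the
transcript-reported position. The strict same-position rule is the default;
an offset-tolerant mode exists for real data where UniProt and RefSeq
coordinates can disagree by a leader peptide.

## Edgotype calls and γ

Geometry: disrupted PPIs are those whose interface on the mutation's
protein contains the mutated position; edgetic means ≥ 1 disruption,
mono-edgetic exactly 1. Quasi-null is never predicted structurally — it
exists only as a label convention in experimental-style inputs. Physics:
among geometrically interfacial mutations, a PPI is disrupted iff
ΔΔG > 0.5 kcal/mol (strict); interfacial mutations with no ΔΔG record for
any of their PPIs are excluded from the physics denominators, which is why
physics denominators are slightly smaller than geometry ones. γ (the
disruption probability of an interfacial mutation) is estimated per
(mutation, PPI) pair — a mutation on several interfaces contributes several
pairs — with the binomial standard error of the fraction.

Comparative statistics: substitution radicality uses the canonical NCBI
PAM30 matrix (via Biopython; ambiguous codes rejected); group comparison is
a two-sided bootstrap test whose statistic is the difference in means,
recentered at the observed difference, with a +1 continuity numerator so p
is never exactly 0 (the statistic is a design choice; only the test's name
and sidedness are fixed by convention). Class-versus-edgetic contingency
uses the two-sided Fisher exact test (scipy), cross-checked in the tests by
exhaustive hypergeometric enumeration.

## QC metrics

SimGIC between two proteins is the information-content-weighted Jaccard
index of their ancestor-closed annotation sets, with
IC(t) = −log(fraction of corpus proteins whose closure contains t). The IC
corpus is the supplied annotated protein set — not an external corpus — so
the metric is self-contained; terms present in every closure (roots) get
IC 0. Tissue co-expression is the Pearson correlation over tissues where
both profiles are defined, requiring ≥ 5 shared tissues; for categorical
(0–3) sources a present value of 0 counts as defined. Constant profiles
return "undefined" rather than NaN. The QC report contrasts interacting
pairs with seeded random non-interacting pairs via group medians and a
Mann-Whitney test.

## Synthetic world generator

The generator emulates the study's input surface, not protein physics:

* **Geometry** — chains are jittered lattices (Cα plus a dummy side-chain
  atom, 10 Å residue spacing) on parallel lines 30 Å apart; each declared
  contact pair is realized at ~4.2 Å while all other inter-chain residue
  distances exceed a 6 Å guard band. This makes declared interfaces exactly
  recoverable under the 5 Å rule, which is the property the pipeline needs;
  folds, rotamers and energetics are intentionally absent.
* **Alignments** — exact identity hits at E-value 1e-50; optional decoy
  hits above the cutoff exercise the filters.
* **Mutations** — each mutation is independently interfacial with its
  class probability (defaults 0.051 non-disease / 0.186 disease, the rates
  measured on the Y2H-derived network, with 376 and 145 mutations), then
  assigned an unused position of the right type, so class counts are exact
  binomial draws and no two mutations collide in position. Curation fields
  are generated to pass the filters; records that should fail them are
  constructed directly in the tests.
* **ΔΔG** — class-truncated Gaussians: with probability γ (defaults
  0.60/0.66) a draw from the destabilizing component truncated above
  0.5 kcal/mol, else from the neutral component truncated below it. Only
  the exceedance probability at the threshold is consumed downstream, and
  truncation makes it equal γ exactly, which keeps parameter-recovery
  bounds clean. Component means/SD (1.5, −0.2, 0.8 kcal/mol) are
  plausible magnitudes for destabilizing vs neutral interface mutations.
* **Side tables** — interacting pairs share a GO term and a latent
  expression factor, so QC signal exists by construction.
* **Seeding** — one integer seed spawns per-stage substreams; changing
  mutation counts does not perturb structures.

Default network size is 486 PPIs among 573 proteins (the Y2H-derived
structural interactome's dimensions); protein lengths are drawn around 150
residues — enough to leave ample non-interface positions — rather than
realistic human protein lengths, a deliberate simplification since only
position identity, not length, enters the analysis.

What passing on synthetic data does **not** show: robustness to gapped or
paralogous alignments, to disagreeing transcript/protein coordinates, to
structures with missing density, or to non-binomial clustering of real
mutations. Those belong to real-data validation.

## Problem sizes and numerical choices

Parameter-recovery tests run the full pipeline on worlds of 5,000 mutations
per class over a 110-PPI network (140 proteins, 120-residue average) —
large enough that 3-binomial-SD recovery bounds are tight, small enough to
iterate on — and check the four configured rates (interfacial placement and
disruption per class) plus CI coverage of the analytic truth across 100
seeded replicates (expected ≥ 93/100 for a 95% interval). Interface
detection is exact vectorized brute force over all atom pairs (no spatial
approximation); a grid acceleration, if ever added, must stay exactly
equivalent. Distance comparisons square the cutoff rather than taking roots.
Bootstrap p-values are computed in chunks to bound memory.

## Known limitations

* The priors P(N)/P(M)/P(S) are treated as constants; their uncertainty is
  not propagated into the CI.
* The Katz interval is asymptotic; for very small numerators (k ≈ 1–2) it
  is wider than resampling intervals.
* The physics exclusion rule (no ΔΔG ⇒ dropped from denominators) matches
  how incomplete ΔΔG tables are handled upstream, but other conventions
  (impute, carry geometry call) are possible and would shift physics
  denominators.
* ID consistency across tables is assumed; no UniProt/Entrez mapping is
  performed.
* The minimal PDB dialect has no insertion codes, altlocs or assemblies.
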