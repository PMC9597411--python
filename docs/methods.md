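# Methods

This note documents the models implemented in `trifrac`, the synthetic
data that exercises them, and the numerical and design choices a user
should know about before trusting a result.

## The loss process

Each pillar (ancestral triplicated locus) evolves independently along the
rooted species tree under a 7-state continuous-time Markov chain: the
triplicated state `T` decays through the three duplicated states
`D_X.Y` (copy of the third subgenome lost) into the absorbing single-copy
states `S_X`.  Nine loss transitions are possible; their rates are
relative, with the base loss rate α absorbed into branch lengths
`u = α·t` (so `u` has units of expected loss events per unit relative
rate) and `ρ(T→D_LF.IF) := 1` as the scale anchor.  There is no gain,
re-duplication or whole-pillar extinction, so every genome retains at
least one copy at every pillar; this matches the construction of pillar
datasets, which require an observed gene somewhere at each locus.

Model families constrain the nine rates: `null` (shared T→D rate, shared
D→S rate σ; 1 free rate), `1d` (+`f_T`, `f_D` scaling the transitions
that remove the LF copy; 3), `3g` (+`g_T`, `g_D` for the IF copy; 5),
`arb` (all free; 8).  The deltas 2, 2, 3 are the degrees of freedom of
the nested likelihood-ratio tests.  Arrival variants start pillars in the
founder-pair duplicated state evolved for a tetraploid phase of length τ
(u units) with D→S rates scaled by κ, then map the surviving founder
states onto the 7-state space at the (instantaneous) second merger; this
adds exactly 2 parameters.  The root variant gives the stem branch a
second full rate set (+8).  Transition matrices use `scipy.linalg.expm`;
the triangular closed forms (e.g. `P(T→T) = exp(−3u)` under `null`)
serve as independent oracles in the test suite, not as the
implementation.

Subgenome labels are not identified by the likelihood (any consistent
relabeling of rates leaves it unchanged).  After an `arb` fit, labels are
standardised post hoc: the subgenome with the lowest total loss flux
(sum of the rates removing its copy) becomes LF, the highest MF, and
rates are renormalised to `ρ₁ = 1` with branch lengths absorbing the
scale.  Families below `arb` encode the distinguished subgenome in their
parameterisation and are left as fitted.

## The orthology HMM

Per genome, the hidden state is the permutation assigning its three
syntenic tracks to {LF, IF, MF} (6 per genome, `6^n` jointly; `n ≤ 5`
genomes are supported with full enumeration).  A pillar's emission given
a joint state is the pruning likelihood over the 7 loss states, with each
genome's leaf vector the indicator of the loss state implied by which
subgenomes its occupied tracks map to; a genome with no genes at a pillar
is missing data (all-ones vector).  Between adjacent pillars each
genome's permutation persists with probability 1−θ and jumps to each of
the 5 alternatives with probability θ/5 (a synteny break), independently
across genomes; θ is shared across genomes.  At contiguity breaks —
explicit `#BREAK` rows, or derived positions where no genome has any
syntenic-neighbour pair — the chain re-initialises to the uniform
distribution.  Posteriors come from the scaled forward–backward
recursions; MAP ties break lexicographically.

Fitting maximises the forward likelihood over branch lengths, family
rates, θ (and τ, κ, root rates where present) with L-BFGS-B on
log-transformed parameters (logit for θ), converging at a relative lnL
change of 1e-8.  Gradients are forward differences (step 1e-6), computed
for all parameters in one batched likelihood pass.  The default is five
seeded starts (one neutral, four log-normal perturbations) to guard
against label-switching multimodality; replicate studies in the test
suite use one or two starts from staged initialisations
(`init_from_fit`), which warm-start a richer family at a simpler
family's optimum.  One caveat matters there: a simpler family's optimum
is a *stationary point* of every richer family (under the null model the
permutation posterior is exactly uniform, so symmetry-breaking score
components vanish), so a staged fit should always include at least one
perturbed start.

### Properties of the nested tests

Two structural facts, documented because they affect calibration:

* The LRT of `1d` against `null` is not chi-square(2) under the null in
  finite samples: the score degeneracy above puts an atom at 0 (about
  10–15% at four genomes and a few hundred pillars), while in large
  samples the hidden-label marginalisation makes "one subgenome special"
  an implicit maximum over three labeled modes, inflating the statistic
  (empirically mean ≈ 3 at 1000 pillars).  The chi-square reference
  matches the printed degrees of freedom and is what practitioners use;
  for the huge effects these models are fitted to, the distinction is
  immaterial, but marginal p-values near a threshold should not be
  over-read.
* The three arrival scenarios are label-symmetric reparameterisations of
  one family: their global maxima coincide, and what distinguishes them
  is which labeled mode a staged optimizer occupies.
  `compare_arrival_models` therefore canonicalises each fitted candidate
  by loss flux and reports its *effective* last-arriving subgenome;
  conclusions should be drawn from `best_last` (the effective scenario of
  the best fit), not from the nominal candidate names.  A candidate whose
  tetraploid phase fits at zero length has collapsed into plain `arb`
  (tolerance |ΔlnL| < 1e-3).

## Gene assignment and SAIRs

Genes are assigned to subgenomes from the per-genome marginal posterior
that their track maps to each subgenome; the joint-state posterior is
reserved for SAIR filtering, where confidence in the whole regional
arrangement is what matters.  Expected survivor counts sum marginals over
occupied tracks and always conserve each genome's total gene count
(permutations are bijections); MAP-based hard counts are an option.

A SAIR group is accepted for subgenome s at a pillar pair when: the MAP
joint state at both pillars has posterior ≥ 0.95 (both pillars, the
stricter reading of the ≥95% rule), maps the *same* track of every genome
to s, that track holds a gene in every genome at both pillars, and each
genome's two genes are syntenic neighbours (same chromosome, no other
pillar gene between them).  Strict adjacency is the default; `max_gap`
relaxes the pair distance while keeping the neighbour test, which
automatically tolerates only pillars whose focal track is empty.  The
interval is the gap between gene bodies (annotated gene span; no
UTR/intron refinement), 0-based half-open; abutting or overlapping
flankers drop the group with a logged reason.  Strand is carried through
I/O but ignored by all likelihood computations and sequence extraction.

## Repeat analysis

Hit tables (BLASTN outfmt-6 or nhmmer tblout) are filtered at
E ≤ 1e-5 (inclusive) and normalised to 0-based half-open coordinates.
Regions merge hits overlapping by ≥ 1 base (abutting hits stay separate).
Local alignment is Smith–Waterman with match +4, mismatch −5, gap open
(first gapped base) −8, gap extension −4, `N` scored as a mismatch,
implemented with Biopython's `PairwiseAligner`; a region is ancestral
when every other genome's orthologous SAIR yields an alignment of ≥ 80
columns scoring ≥ 200.  The parsimony caller instead requires a passing
hit to the same element in every genome of the group.

Density is hits per kilobase of SAIR sequence per subgenome.  The
randomization test shuffles the pooled hits of the two subgenomes and
places each uniformly among the positions remaining in SAIRs at least as
long as the hit (`length − hit_length` positions per SAIR); a SAIR that
receives a hit is removed for subsequent hits, so placements never
overlap — consequently the test requires no more hits than SAIRs, which
in practice means running it on conserved (ancestral) regions or other
sparse hit sets.  p = (exceedances + 1)/(replicates + 1), two-sided by
default, 10 000 replicates by default.  Because the statistic is a count
ratio it is discrete: one-sided p-values are uniform under the null,
while the two-sided fold concentrates mass at exactly p = 1 (the minimal
attainable |difference|), making the two-sided test conservative but
valid.

## Synthetic data

`simulate_pillars` is the exact generative counterpart of the inference
machinery: root state from the arrival-aware root distribution, states
sampled down the tree from the family's transition matrices, per-genome
permutation chains with switch probability θ, presence emitted through
the permutations.  A permutation switch starts a new chromosome segment,
so adjacency flags derived from coordinates reflect the simulated breaks;
an optional `block_size` inserts explicit breaks.  Because simulator and
fitted model share the break kernel by construction, recovery tests are
well-posed tests of the estimator, not of kernel misspecification.

`simulate_sairs` draws ancestral intergenic sequences (uniform base
composition, lengths 800–3000 b), plants non-overlapping copies from a
bundled 12-element library (60–400 b) at per-subgenome Poisson densities,
evolves each genome's copy by per-site substitutions (default 10%) and
geometric indels (rate 0.01/site, mean 3 b), adds genome-private recent
insertions (repeat turnover), and emits sequences, a perfect-knowledge
hit table standing in for an external search, and the planted truth.
Defaults make the fractionated subgenomes three times repeat-denser than
LF ancestrally (0.1 vs 0.3 /kB) with recent turnover on top — the
qualitative regime the method is meant to detect.  A requested density
whose expected occupancy cannot be placed raises; rare per-SAIR Poisson
overflows saturate that SAIR and plant the remainder nowhere.

What the generators do *not* emulate: real TE biology (bursts, families,
insertion preference), gene order rearrangement beyond the permutation
kernel, annotation errors, pillar-construction noise, and missing
genomes.  Passing recovery tests therefore demonstrate estimator
correctness under the model, not robustness to everything real genomes
do.

## Problem sizes in the shipped studies

The test suite and `scripts/acceptance.py` fix their own study sizes:
parameter recovery uses 20 replicates of 5000 four-genome pillars
(single staged start per fit); LRT calibration uses 200 four-genome
400-pillar null datasets; arrival recovery uses 20 replicates of 1500
three-genome pillars; the randomization calibration uses 500 datasets of
250 hits over 520 SAIRs at 199 replicates each; the end-to-end script
uses 3000 pillars.  These are the package's chosen desk-scale conditions
for exercising every stage with meaningful statistics.

## Known limitations

* Full `6^n` state enumeration only (n ≤ 5 genomes); no sparse/beam mode.
* θ is shared across genomes and branches.
* Chi-square references are used for all LRTs, including boundary (τ)
  and label-symmetric cases, with the caveats above.
* The matrix exponential, not a closed form, computes transition
  matrices; for extremely long branches (u ≫ 10) entries underflow to
  the absorbing states, which is the correct limit.
* Real-genome headline numbers (pillar counts, SAIR counts, conserved-RE
  counts) require the original genome-scale inputs and are outside the
  shipped studies' scope.
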