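# Methods

`convfuse` re-implements, as a tested library, the comparative-genomics
inference chain used to establish that two gene-fusion families with the
same domain architecture (the motivating case: the bacterial ALDH-ADH
fusions AdhE and BdhE) arose by independent fusion events — and to
characterize the genomic and ecological context of such events.  Because
the real inputs are consortium-scale (tens of thousands of genomes, domain
databases, metagenomic habitat scores), every analysis here runs against a
synthetic-data module that plants the same signals with known ground
truth.  This note records the models, the defaults and why, the numerical
choices, and what the synthetic tests do and do not establish about real
data.

## 1. Coverage–identity screening (`convfuse.align`)

A database protein is characterized by its best alignment against a panel
of known fusion queries:

* **identity** — identical aligned residue pairs / alignment columns × 100,
  gap columns included (the MMseqs-style `pident`; the denominator choice is
  a documented convention, configurable in principle but fixed here);
* **query coverage** — query residues inside the aligned span / query
  length × 100.  Coverage is asymmetric by design: the screen is run with
  fixed query panels, so only query coverage drives classification (target
  coverage is reported but unused).

Alignments are exact affine-gap dynamic programming
(`Bio.Align.PairwiseAligner`, BLOSUM62, gap open 11 / extend 1, a gap of
length *k* costing `11 + (k−1)·1`).  Three modes: `local`
(Smith–Waterman, used for full-length screening), `glocal` (global in the
query, free end gaps on the target side — the natural mode for domain
queries against full-length proteins) and `global`.  There is no E-value
model: at desk scale the screen is exhaustive and identity/coverage are the
operative statistics.  Co-optimal alignments are resolved by the aligner's
deterministic first traceback.

Classification partitions hits: coverage ≥ 90% splits into `quasi_full`
(identity < 30%) versus `full_homolog` (≥ 30%); coverage inside the 45–50%
band is `partial` (the single-domain contrast band); everything else is
`background`.  The quasi-full signature — full-length match at low
identity — is what flags a candidate independently fused family.

## 2. Domain splitting and family collection (`convfuse.domains`)

Fusion candidates are split positionally: N-terminal 480 residues (the
ALDH span) and C-terminal 370 residues (the ADH span).  The split is
deliberately not HMM-based; it reproduces the fixed-span procedure that
works because the two domains occupy predictable ends of the fusion.
Proteins between ~800 and 850 residues make the two spans overlap; this is
flagged, not rejected, because such proteins are legitimately screened.
Length filters are strict (`> 800` candidates, `> 700` final members).

Family membership is the conjunction rule: a protein joins if, for at
least one seed, **both** the N-segment and the C-segment queries exceed
40% identity (any-seed disjunction, both-domain conjunction).  The
alternative reading — max-over-seeds per domain — differs only when
different seeds carry the two domains best; we implement any-seed and note
the alternative here.  Membership is monotone in the threshold, which the
tests assert.

## 3. Convergence testing on domain trees (`convfuse.phylo`)

Monophyly is read in the rooted, exact sense: a tip set is monophyletic
iff some node's descendant set equals it exactly.  Polytomies are treated
as hard (no soft resolution) — a conservative choice that can only turn
borderline cases into `unresolved`, never fabricate support.  Branch
supports live as numeric internal-node labels on the edge above each node
(the convention of common ML tools; UFboot-style percentages).  Outgroup
rooting re-attaches supports by unrooted-bipartition identity, which the
tests verify directly.

The origin verdict for families A and B combines both domain trees:

* `independent_origin` — in **both** trees, A and B are each monophyletic,
  A∪B is not, and the path between the two clades carries at least one
  edge (configurable, `min_separating_edges`) with support ≥ 95;
* `shared_origin` — in **either** tree A∪B is monophyletic with defining
  support ≥ 95;
* otherwise `unresolved`.

Requiring both trees to agree mirrors the logic that a fusion family's
independence must hold for each constituent domain; one well-supported
union suffices for shared origin because a single domain tree placing the
families together already contradicts independence.

## 4. Two-trait gain/loss model and LRT (`convfuse.coevolution`)

Presence/absence of two families evolves as a CTMC on (00, 01, 10, 11).
Trait *i* has gain and loss rates per unit branch length; in the dependent
model the partner's presence multiplies trait *i*'s gain rate by `g_i` and
loss rate by `l_i` (8 free parameters; independent model: multipliers 1, 4
parameters).  Double transitions have rate 0.  This multiplicative
parameterization was chosen over Pagel's unconstrained 8-rate model
because "complementary" has a direct reading: `g < 1` and `l > 1` mean the
partner suppresses gain and accelerates loss.

Likelihood: Felsenstein pruning, per-branch `expm(Q·t)` computed for all
branches at once via the eigendecomposition of Q (clipped and
row-renormalized against roundoff) with a scaling-and-squaring fallback
when the eigenvector matrix is ill-conditioned; per-level scaling guards
underflow on large trees.  Pruning is validated to 1e-9 against full
enumeration over internal states.  Root prior: stationary distribution of
the candidate Q (uniform fallback for reducible generators); switchable to
uniform.

Fitting runs in log-parameter space (bounds [1e-4, 1e4]) with L-BFGS-B and
an adaptive multistart (up to 5 seeded restarts, stopping once two agree
within 0.01 logL; the convergence flag records that agreement).  The LRT
statistic is `2·(logL_dep − logL_indep)`, floored at 0, against chi-square
with df = 4; the multipliers are interior parameters, so no boundary
correction is needed.

**Ridge canonicalization.**  With binary tip data the dependent model is
only weakly identified along certain directions: suppressed gain (g ≪ 1)
and accelerated loss (l ≫ 1) of a trait are nearly observationally
equivalent, and the two traits' multipliers trade off.  A raw optimizer
endpoint is then an arbitrary point of a near-flat set, and its quadrant
(the basis of the sign call) is noise.  The dependent fit therefore
proceeds in stages: (i) a trait-symmetric fit (`g_a = g_b`, `l_a = l_b`, 6
parameters, multistart); (ii) an unconstrained 8-parameter polish, whose
likelihood is the one reported and used in the LRT; (iii) two
quadrant-profile refits constrained to the complementary (`g ≤ 1 ≤ l`) and
correlated (`l ≤ 1 ≤ g`) quadrants.  If one quadrant beats the other by
more than 2 logL units, its constrained optimum — a representative of the
near-optimal set with an interpretable sign — is reported as the fitted
model; otherwise the direction is genuinely unresolved and the
unconstrained (or symmetric, on a flat ridge) point is reported.  The sign
call itself is unchanged: complementary iff the geometric means satisfy
`√(g_a·g_b) < 1` and `√(l_a·l_b) > 1`, correlated for the reverse, `none`
otherwise.  In simulations this canonicalization raised sign recovery
under strongly planted interactions from roughly half to essentially
always, without measurably moving the LRT (type-I error stays inside the
binomial band).

**Study sizes** (all in `tests/test_acceptance.py`, scaled-down versions
in `scripts/acceptance.py`): pruning oracle on 200 trees of ≤ 6 tips;
type-I calibration with 300 replicates on a fixed 200-tip tree (gains 1.0,
losses 0.5); power/sign with 50 replicates per regime on a fixed 400-tip
tree — complementary (gains 1.0, losses 0.5, g = 0.3, l = 15) and
correlated (gains 0.15, losses 0.5, g = 12, l = 0.08).  The strong-regime
parameters were chosen so that *both* the gain- and loss-side effects are
identifiable from tip data (e.g. near-total gain suppression leaves the
loss multipliers unvisited and hence unidentified — such a regime cannot
test sign recovery even in principle); rate recovery uses 50 fresh
1000-tip trees with independent rates (0.8, 0.4, 1.5, 0.6), median
relative error ≤ 30%.

## 5. Adjacency enrichment (`convfuse.synteny`)

Two genes are adjacent when they share contig and strand with at most 9
annotated genes strictly between them ("within ten genes" = rank
difference ≤ 10; the boundary is configurable and unit-tested at 9 vs 10).
Intervening genes count regardless of their own strand — the rule
constrains the pair, not the interveners.  The enrichment ratio divides
adjacent gene pairs by co-existing gene pairs, counting cross-product
pairs for multi-copy families; a per-genome variant (genomes instead of
pairs) sits behind `per_genome=True` for sensitivity analysis.  The scan
is exhaustive and quadratic by design (oracle-grade); a second independent
implementation in the tests must agree exactly.

## 6. Habitat enrichment (`convfuse.habitat`)

Per environment: mean habitat-preference score of carriers minus mean of
non-carriers, species weighted equally.  Species missing from the habitat
matrix are dropped with a count (real habitat scoring covers only species
with usable 16S data).  No significance test is attached — the statistic
is a descriptive contrast; a permutation check lives in the test suite
only.  Ties in ranking break lexicographically.

## 7. Synthetic data (`convfuse.simulate`)

* **Species trees** — forward Gillespie birth–death conditioned on n
  extant tips (stop at n lineages, plus one Exp(n(λ+μ)) hold so terminal
  branches are positive).  Under pure birth the expected root-to-tip depth
  is Σ_{k=2..n} 1/(kλ), which the tests check by Monte Carlo.  Stopping at
  first passage to n is a mild conditioning bias relative to sampling
  uniformly over n-tip histories; irrelevant for its role here.
* **Traits** — exact event-driven (Gillespie) simulation of the 4-state
  chain branch by branch, returning full node histories as ground truth.
* **Sequences** — symmetric 20-state substitution model, events per site
  at rate (20/19)·rate redrawing the residue uniformly; identity between
  tips at distance d is 1/20 + (19/20)·exp(−(20/19)d) in closed form,
  which serves as an exact oracle.  Realism (LG/WAG exchangeabilities,
  indels, rate heterogeneity) is intentionally absent.  An
  `invariant_sites` mask freezes chosen positions, emulating the conserved
  core motifs that anchor full-length alignments between deeply diverged
  superfamily members; without such anchors, ~25%-identity local
  alignments of uniformly evolved sequences truncate, and the quasi-family
  coverage signature cannot be realized at all.
* **Fusions** — concatenation of species-paired domain sequences with a
  10-residue GS linker; forward (ALDH-ADH) or reversed order.
* **Genomes** — block-based assembly: a planted pair is adjacent (same
  strand, uniform 0..max_gap intervening fillers) with the planted
  probability, otherwise the second gene moves to a separate contig
  (guaranteed non-adjacent under any cutoff); fillers carry per-genome
  unique labels so denominators are unambiguous.
* **Habitat** — baseline 0.5 plus the planted effect for carriers in the
  focal environment plus Gaussian noise, truncated at 0.

Every generator draws from an RNG stream derived from (seed, stream-id),
so outputs are bit-reproducible and adding a generator call never perturbs
another's stream.

## 8. The bundled scenario (`convfuse.pipeline`)

40 species; fusion families famA/famB evolve under a strongly
complementary model (gains 0.5, losses 0.25, g = 0.05, l = 15, root state
10); each domain has a four-clade superfamily
((famA, sisterA), (famB, sisterB)) with stems 0.4 and a join of 1.1
substitutions/site, within-clade evolution following the species tree
scaled by 0.04.  The resulting between-family identity sits near 25% with
full-length alignability (8 and 7 invariant 8-residue motif blocks in the
480- and 370-residue domains); sisters sit near 50%.  The famB-sister
single-domain pair is planted adjacently with probability 0.8 (gaps
0..4); famB carriers get a +0.4 habitat effect in "marine_sediment" with
noise SD 0.08.

The superfamily constants (root sequences, motif masks, deep divergence)
derive from a fixed scenario constant rather than the run seed: the
between-family identity level is a property of the scenario, not of one
evolutionary replay, and keeping it fixed makes the screen's behavior
stable across seeds.  The run seed drives the species tree, trait
histories, within-clade sequences, genome assembly and habitat noise.
Carrier sets are resampled (deterministically, bounded) until every family
has ≥ 2 carriers, since empty families would make the domain trees and
screens degenerate.

## 9. What passing tests show — and what they don't

The synthetic generators match the *statistical structure* the methods
assume (binary gain/loss on a known tree, no-indel sequence divergence
with conserved anchors, planted adjacency, additive habitat effects).
Passing tests therefore demonstrate correctness of the algorithms and
calibration of the test under the stated models — not robustness to real
data's failure modes: alignment ambiguity from indels and compositional
bias, gene-tree estimation error and rogue taxa, annotation errors in
ortholog labels, draft-genome contig fragmentation (ranks are required to
be consecutive; order is never inferred across contigs), phylogenetic
non-independence between the habitat statistic's species, or model
misspecification in the CTMC (rate heterogeneity across lineages,
hidden states).  The LRT's chi-square reference is asymptotic; at a few
hundred tips it calibrates well in our checks, but very small trees or
nearly constant traits leave parameters weakly identified (flagged by
warnings, not errors).

## 10. Reproducibility

All randomness flows from explicit integer seeds; reruns are
bit-identical.  `scripts/acceptance.py --seed S --out f.json` recomputes
the headline quantities from scratch at reduced study sizes (~3 minutes on
one CPU); the full-size studies run inside the test suite (~10 minutes).
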