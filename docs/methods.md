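# Methods

This note documents the models, the simulator, the numerical choices and
the known limitations of `isdgkit`. It is the package's own account of
what each stage computes and under which assumptions the tests are
meaningful.

## The analysis in one paragraph

Given a small set of functionally characterized IsdG-family heme
oxygenases, the pipeline expands the family: a profile built from the
aligned seeds is searched against a protein database with calibrated
E-values (sequence cutoff 0.01, per-domain cutoff 0.03); hits are
filtered on composition, deduplicated, and tandem two-ABM-domain
proteins are split into `NTERM`/`CTERM` halves; the curated set is
aligned; the reference's catalytic (N/W/H) and auxiliary (F/G/W) residue
positions are projected through the alignment and counted per sequence;
a maximum-likelihood tree is inferred under LG(+G4) with BIC model
choice, bootstrapped, midpoint rooted, and exported with taxonomy and
triad-count color strips.

## Substitution model and likelihood

The rate matrix is `Q_ij = s_ij * pi_j` with the published Le–Gascuel
exchangeabilities `s` and stationary frequencies `pi`, normalised to one
expected substitution per site per unit time. Transition matrices come
from the symmetrised eigendecomposition
`P(t) = D^{-1/2} U exp(Lambda t) U' D^{1/2}` with `D = diag(pi)`, which
all gamma categories share. Rate heterogeneity is the usual 4-category
discrete gamma with equal category probabilities; category rates are the
conditional **means** of the quantile bins (not medians), renormalised
to mean one, so closed-form checks against quadrature are exact.

Likelihoods use Felsenstein pruning over compressed site patterns with
per-pattern rescaling at every internal node; gaps and `X` are missing
data (all-ones conditional vectors). Branch-length optimisation works on
one edge at a time: the "outer" partial excluding the target branch is
computed once, the edge likelihood is then a one-dimensional function of
that branch length, and bounded Brent search (branch lengths in
`[1e-9, 10]` substitutions/site, tolerance `1e-4`) can only improve the
full likelihood — the accepted log-likelihood trace is non-decreasing by
construction. Tree search is NNI-only hill climbing from a
neighbor-joining start (pairwise ML distances, Q-criterion NJ with
smallest-index tie-breaks, negative branch lengths clamped to zero);
SPR is deliberately out of scope at these problem sizes (<= ~64 taxa).

Model choice fits LG and LG+G4 on the start topology (branch lengths per
fit, alpha by alternated bounded search in `[0.05, 50]`) and minimises
`BIC = k ln(n_columns) - 2 ln L`, ties going to the smaller model.

Bootstrap supports are a plain nonparametric site-resampling bootstrap:
each replicate resamples columns with replacement and infers an
NJ-on-ML-distances tree; an internal edge's support is the fraction of
replicate trees containing its bipartition. The default of 1,000
replicates follows the convention of the family analysis this package
re-implements; replicate trees use NJ rather than full ML so that the
default is affordable — supports are annotation, not inference.
Midpoint rooting places the root halfway along the longest
leaf-to-leaf path, ties broken by the lexicographically smallest leaf
pair; the result is checked in tests against a dense scan over all edges.

## Profile search and E-values

The profile stores per-column frequencies
`f_c = (counts_c + tau * pi) / (n_c + tau)` (pseudocount weight `tau`,
default 1) and natural-log odds against the LG background. Scoring is
local affine-gap dynamic programming (Gotoh recurrences; gap of length k
costs `open + (k-1) * extend`, defaults 4.0/0.4 in nat units — small
against the ~1 nat/column signal of a true family member, so the
45-residue insert costs far less than the domain match gains).
Statistical calibration scores `n >= 100` (default 200) i.i.d.
background sequences per target-length stratum (geometric buckets,
factor 1.25) and fits a Gumbel law by maximum likelihood;
`E(s) = N_db * SF(s)` with the database size counted in sequences. The
empirical null is retained for a conservative rank-based p-value,
`(#{null > s} + 1) / (n + 1)`. Per-bucket RNG streams are derived from
(seed, bucket), so results are independent of database order. Domain
spans are found by iteratively masking the best local span and
re-scoring until the next span's E-value exceeds the hit cutoff; the
masking guarantees non-overlap.

`X` scores zero (background); `B/Z/J/U/O` are mapped to `X` with a
warning on input.

## Curation

Three auditable composition tests replace ad-hoc filtering scripts: a
dominant-residue cap (default 0.5), a length window (default 30–5000),
and a 19-df chi-square of each record's composition against the pooled
composition of the input set. The chi-square default of 100 is
deliberately tolerant: family members carrying the low-complexity
S/G/H-rich insert sit around 50–90 under the simulator's conditions and
must survive, while i.i.d. decoys with strongly skewed composition sit
well above (and are usually caught by the dominance cap first). The
pooled-composition test loses power when outliers dominate the pool;
it is meant for a minority of contaminants, which matches its position
after the homology search.

Redundancy collapse is greedy clustering in input order at >= 97%
identity (global-alignment identity = matches / columns with both
residues; equal-length pairs short-circuit to Hamming identity), with
the reported representative re-chosen as the longest member. Tandem
records are split at the integer midpoint between adjacent domain spans
— the neutral automated stand-in for what is a manual judgement call in
practice — and more than two spans (beyond the two-domain convention)
yields `_DOM1..` pieces flagged as synthetic. Curation never edits
sequence content: concatenating a split pair reproduces the original
exactly, and `curate` is idempotent on its own output.

## Alignment

Progressive alignment with a k-mer (k=3) distance
`1 - shared / min(total)` and average-linkage guide tree; profiles are
merged by profile–profile global alignment under BLOSUM62 (gap open 11,
extend 1). All tie-breaks are lexicographic, making the alignment
invariant under input-order permutation (up to row order, which always
equals input order). There is no iterative refinement and no trimming:
downstream stages need a valid, reproducible alignment, not parity with
any particular aligner. All-gap columns cannot survive construction;
`.` is normalised to `-` on input.

## Triad mapping

Reference residue positions are 1-based on the reference sequence;
alignment columns are 1-based; the mapping simply walks the reference
row skipping gaps. Matching is residue identity by default — the
conservative reading of "conserved residue" — with an optional fixed
similarity partition (AG | ST | C | DE | NQ | KR | H | ILMV | FWY | P)
for sensitivity analysis. A gap or `X` never matches. `is_isdg_like`
means all three catalytic positions match. The default coordinates
(41/100/110 catalytic, 69/70/91 auxiliary) are the printed numbering of
the algal reference enzyme; they are treated as coordinates on whatever
reference sequence the user supplies, and mapping to other rows always
goes through the alignment, never by raw position arithmetic.

## The simulator and what it does (not) emulate

The generator's defaults are the study conditions every recovery test
runs under: 16 taxa, 100-residue domains, a 45-residue insert in one
small clade, triad degraded in a quarter of the taxa, 8 decoys, 2
near-duplicates, 2 fusions, branch lengths Gamma(shape 2, mean 0.25)
substitutions/site, per-site rates from a continuous Gamma(alpha=1).

Design choices:

* **Coordinates.** Planted positions live on the insert-bearing
  ancestral sequence (length `domain_length + insert_length`; defaults
  put N/W/H at 41/120/130 and F/G/W at 30/50/115 around an insert at
  61–105). Taxa outside the insert clade simply lack the insert block.
  This mirrors a reference whose printed residue numbers include its
  unstructured insert, makes a planted position inside the insert span a
  meaningful configuration error, and keeps every emitted non-clade
  domain at ~100 residues.
* **Substitutions only.** The single indel event is the clade insert;
  everywhere else length is fixed, so true site homology is known
  exactly and column-recovery statistics are well-defined. The insert
  itself is treated as a compositionally conserved low-complexity
  segment (rate zero, >= 75% of sites drawn from {S,G,H} by
  construction, hence always >= 60% S/G/H).
* **Degradation.** Planted sites evolve at their ordinary gamma rate,
  but only along branches whose entire descendant set is degraded;
  elsewhere they are invariant. This is the simplest "lost constraint"
  null, guarantees intact taxa really carry N/W/H, and lets a degraded
  taxon retain a residue by chance — truth records the *realized*
  per-taxon count, which is what the classifier is scored against.
* **Confounders.** Decoys are i.i.d. LG-background sequences, lengths
  uniform on 0.5–1.5x the domain length (they must straddle the family
  length), with an optional composition-bias knob for filter tests.
  Duplicates differ from their source at <= 2% of positions by
  construction. Fusions concatenate two family members with a GGSGGS
  linker, junction recorded.
* **Randomness.** Everything flows from one seed through named
  `default_rng` streams; equal configurations give byte-identical
  fixtures.

What the simulator does **not** emulate: indel processes outside the
insert, heterotachy, codon-level effects, profile-HMM emission
statistics, and real database composition. Passing recovery tests
therefore demonstrate the pipeline's internal correctness and its
behaviour under a realistic but idealised family model — not search
sensitivity against real proteomes, where domain architectures and
compositional biases are richer.

## Problem sizes and tolerances used in verification

The test suite and `scripts/acceptance.py` run: exact oracles (pruning
vs brute-force enumeration on 4-taxon/30-column instances to 1e-8;
total site probability over all 20^3 three-taxon columns to 1e-8; NJ on
path-metric distances of 50 random 8-taxon trees; midpoint rooting vs a
dense edge scan on 100 random 10-taxon trees to 1e-9; affine-gap scores
vs exhaustive enumeration on 100 pairs of length <= 8) and statistical
recoveries (ML topology within RF 2 on 16-taxon/400-column families;
triad labels on 16 taxa with 5 degraded; search with 20 family members
against 200 decoys; ml_distance at true divergence 0.5 over 50
replicates of 10,000 sites; LG-vs-LG+G4 selection on 8-taxon/500-column
data; byte-identical pipeline manifests across two runs). These sizes
were chosen as the smallest instances at which each property is
informative; the bootstrap recovery check uses a fixed well-separated
8-taxon topology because support values are only expected to saturate
when internal branches are long ("strongly diverged").

## Known limitations

* The internal search is a PSSM, not a profile HMM: no forward-scored
  marginal alignments, no heuristic filters, and Gumbel tail
  extrapolation beyond the fitted null is approximate.
* NNI-only search can in principle be trapped by local optima that SPR
  would escape; at the supported scales the NJ start makes this rare.
* The per-edge branch optimiser recomputes partials per edge, giving
  O(n^2) work per sweep — fine to ~64 taxa, wasteful beyond.
* Greedy order-dependent deduplication is not a globally optimal
  clustering; determinism, not optimality, is the design goal.
* Midpoint rooting assumes a roughly clock-like deepest path; it is the
  convention of the original analysis, not a claim about the true root.
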