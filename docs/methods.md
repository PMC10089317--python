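# Methods

This note documents the models, algorithms, numerical choices and
limitations of `copair`, in the order the pipeline runs them.

## Data model

Both families are aligned MSAs over a 21-symbol alphabet: the 20 amino
acids plus the gap `'-'`, which is treated as an ordinary symbol everywhere
(gap–gap is a match, gap–residue a mismatch). Sequences are assumed
pre-aligned (e.g. by profile HMMs); `copair` never builds alignments.
Distances are raw Hamming mismatch counts — they are only ever compared
within one family, so normalisation is unnecessary and the network scale
`D` absorbs units. Each species must contribute equally many sequences to
both families; the pairing is a within-species bijection. Species with a
single pair are paired trivially and trigger a warning. Indices are 0-based
internally and 1-based in reports.

## Similarity networks

*kNN flavor.* Each sequence is linked to its `k` nearest sequences
(tie-break: distance, then index; self excluded; same-species links
allowed). Directionality is ignored — an edge survives if chosen in either
direction — so degrees are ≥ k. The scale `D` is the mean over nodes of the
distance to the node's own k-th neighbor, computed before symmetrization.

*Orthology flavor.* Reciprocal best hits: for each sequence and each other
species, the closest sequence there is its best hit, and an edge is kept
iff the choice is reciprocal. `D` is the mean, over nodes with at least one
retained edge, of the distance to the most distant retained ortholog
(isolated nodes are excluded from this average — a deliberate choice, since
they have no ortholog distance to contribute). Intra-species edges cannot
occur; a species with one sequence may legitimately reach degree N−1.

Weights are `w = exp(−d²/D²)`, strictly decreasing in distance. If all
sequences are identical (`D = 0`), `D` falls back to 1 so that all weights
are a well-defined 1.

## Graph alignment by simulated annealing

The cost of a matching is the negated total weight of overlapping edges
(see README). The infinite penalty on cross-species pairs is enforced
*structurally*: moves exchange the partners of two pairs within one
species, so every reachable matching is feasible and no numerical infinity
is needed.

Schedule and constants (the cooling form is exponential,
`T(t) = T0·αᵗ`; the constants are this package's defaults, chosen so that
enumerable instances reach their known optimum):

| parameter | default | meaning |
|---|---|---|
| `t0` | auto | 95th percentile of \|ΔC\| over 1000 random proposed swaps on the initial matching, so early acceptance is near-uniform; 1.0 if all probes are zero |
| `alpha` | 0.95 | cooling factor per level |
| `accepted_per_level` | 10·M | accepted-move quota per temperature level |
| `t_stop` | 10⁻⁴·T0 | final temperature |
| `stall_factor` | 100 | a level also ends after `stall_factor · quota` attempts; after 3 consecutive zero-acceptance levels the run stops (the system is frozen) |
| `replicates` | 100 | independent runs differing only in RNG stream |

The first pair of a move is drawn uniformly over all M pairs and the second
uniformly over the same species' other pairs, so species are hit in
proportion to their size; single-pair species contribute no moves.
Acceptance is Metropolis: `min{1, exp(−ΔC/T)}`, with ΔC evaluated
incrementally over the edges incident to the two swapped nodes (the
incremental delta is tested against full recomputation to 1e−9). The final
reported cost is always an exact recomputation. The inner loop is compiled
with numba (a pure-Python fallback with identical semantics exists).

Robust pairs are the (A, B) pairs present in *every* replicate; the
occurrence histogram of all candidate pairs is also returned. Replicates
vary both the initial matching and the move sequence through their seed.

## Coevolution models

*Reweighting.* Each co-MSA row's weight is the inverse of the number of
rows within fractional identity ≥ 0.8 of it (itself included); the
effective depth is the weight sum.

*Mean-field DCA.* Weighted one- and two-site frequencies are mixed with a
pseudocount λ (default 0.5): `f̃_i = (1−λ)f_i + λ/q`,
`f̃_ij = (1−λ)f_ij + λ/q²` (q = 21). The connected-correlation matrix is
built over the reduced alphabet with one reference symbol — the gap, last
in the alphabet — removed per site, and couplings are `J = −C⁻¹`. Only the
inter-family blocks are stored: with balanced within-species pairing, the
intra-family energy terms are identical for all candidate partners of a
given sequence and cancel in ranking. Pair energy is
`E(a,b) = −Σ_ij J(i,j,a_i,b_j)`, lower is better. λ = 1 is allowed and
yields exactly zero couplings (a useful null); λ → 0 can make C singular,
which raises an error advising a larger pseudocount.

*PMI.* `pmi(i,j,a,b) = ln[f̃_ij(a,b)/(f̃_i(a)·f̃_j(b))]` on the same
regularised frequencies, inter-family column pairs only; pair score is the
summed PMI, higher is better. Both model kinds expose a common
larger-is-better score matrix, so the IPA is agnostic to the model.

*MirrorTree score.* A candidate pair can also be scored by the Pearson
correlation between the two sequences' Hamming-distance profiles to the
training co-MSA's A- and B-halves. Constant profiles have undefined
correlation and score −∞ with a warning.

## Iterative pairing

Within each species, unresolved pairs are scored, an optimal one-to-one
assignment is solved (Hungarian algorithm), and each chosen pair gets a
confidence gap — the optimal total minus the best total with that pair
forbidden (for a 1×1 species: +∞; such forced pairs are always promoted
immediately). Exact score ties are broken toward the lexicographically
smallest assignment via a hierarchical perturbation ~10⁻⁹ of the score
scale, applied only to the solver's working copy.

*Seeded mode.* The seed co-MSA is frozen — never re-scored, never removed.
Each iteration fits the model on the current gold standard (seed plus all
previously promoted pairs), scores only unresolved pairs, and promotes the
`N_increment` (default 6) top-gap proposals. Promoted pairs stay in the
gold standard permanently, so it grows monotonically and the loop ends in
at most ⌈M/N_increment⌉ iterations. (An alternative reading re-selects the
promoted set each iteration; we freeze promotions, which keeps the
seed-integrity contract simple and the gold standard monotone.)

*Seedless mode.* The first model is fit on a uniformly random
within-species matching. Every iteration re-scores and re-assigns *all*
pairs; the gold standard for the next fit is the `n·N_increment` top-gap
pairs of the current assignment (re-selected each iteration, so membership
may change while the size grows). The output is the last full assignment.

*GA-IPA.* Replicated annealing → robust pairs → seeded IPA. If no pair is
robust, the pipeline warns and falls back to seedless IPA.

## MirrorTree baselines

The global variant maximizes the Pearson correlation between all
off-diagonal entries of the two distance matrices (intra-species entries
included), after reordering one family by the candidate matching. The
optimizer reuses the annealing move set and schedule on the negated score;
swapping two partners leaves the y-sums invariant (the swap permutes
entries), so only the cross-term updates, in O(M) per proposal. Replicate
consensus defines MirrorTree robust pairs exactly as for GA. No trees are
built and no multiple-hit corrections are applied; distances are raw
Hamming counts throughout.

## Synthetic data generator

The generator plants a known pairing and gives each evolutionary signal its
own knob.

A pure-birth (Yule) species tree with `n_species` tips is drawn and
normalised to unit depth (`tree="star"` instead hangs every tip directly
off the root, removing all cross-species phylogenetic structure). A fixed
number of *copy lineages* — ancient duplicates of the ancestral A–B pair,
separated by a burn-in branch of length 1 — evolve independently down the
species tree. Per branch and per copy, a Gamma-distributed rate multiplier
with mean 1 and coefficient of variation `rate_cv` (default 1.0) is shared
between the A and the B member of the pair: interacting partners co-diverge
in rate, which is exactly the signal similarity-network alignment and
MirrorTree exploit. Each species then retains a random subset of copies —
the same subset in both families, sizes drawn from a geometric distribution
shifted to start at `m_min = 2`, truncated at `n_copies`, with mean
`m_mean` — and every retained copy diverges further along a
species-specific branch of length `dup_branch_frac` (default 0.1).

Substitutions follow a per-column Bernoulli(1 − exp(−μ·t·rate)) process
with uniform replacement symbols (`mutation_rate` μ = 1.5 per unit depth by
default, giving well-separated species and ~15% divergence between a tip
and its species-specific variants). `n_coupled` designated column pairs
(one A column, one B column) co-mutate: on a mutation event, with
probability `coupling_strength` both columns jump to a compatible pair
(a, φ(a)) under a fixed random symbol bijection φ, otherwise both mutate
independently. `coupling_strength = 0` leaves only shared event timing (no
symbol-level signal); 1 makes the correspondence deterministic.

Setting `rate_cv = 0` with `coupling_strength > 0` on a star tree isolates
the coevolution channel (solvable by IPA, not by GA); `coupling_strength =
0` with `rate_cv > 0` on a Yule tree isolates the phylogeny channel
(solvable by GA, not by coevolution) — both separations are tested.
Family-B rows are shuffled within species so the planted truth is never the
identity.

*What the generator does not emulate:* real amino-acid substitution
matrices and column-wise conservation profiles, alignment errors and gap
structure, duplication/loss events at internal tree positions, unbalanced
paralog counts, and promiscuous (non-bijective) interactions. Passing tests
on these fixtures demonstrates that each algorithm exploits the signal it
is designed for at realistic signal-to-noise, not that real-data accuracy
will match any particular number.

## Evaluation and experiment scale

The TP fraction is the fraction of A sequences assigned their true partner;
FP = 1 − TP. Under uniform random within-species pairing its expectation is
exactly N/M (one expected fixed point per species, by linearity of
expectation, for any species-size distribution); a Monte Carlo baseline
converges to this and is cross-checked against it.

The method-comparison experiments (tests and acceptance script) run two
hard regimes at M ≈ 220–300 — small alignments with ~11 paralogs per
species, and ~20 paralogs per species — with 10 annealing replicates per
dataset, PMI scoring for the iterative stage (the cheapest of the
equivalent score models), `k = 10`, and `stall_factor = 30`. These sizes
keep the full suite at a few CPU-minutes while leaving the qualitative
ordering (combined ≥ each ingredient; robust subset most precise) clearly
resolved; they are the package's chosen experiment scale, and larger runs
only sharpen the same ordering.

## Known limitations

* Balanced pairing only: species must hold equally many A and B sequences.
  The injective extension for unbalanced families would change only the
  per-species assignment step.
* Mean-field DCA only; no pseudolikelihood or Boltzmann-machine inference,
  and no contact prediction.
* Exact all-pairs Hamming distances (design envelope M ≲ 10⁴); the
  annealer holds a dense M×M weight matrix for the second family.
* The annealing constants are heuristics; on instances far outside the
  tested scales the automatic T0 and the quota may need adjustment.
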