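# copair

**Pairing interacting paralogs between two protein families by combining
phylogeny and residue coevolution.**

## The problem

Given aligned MSAs of two interacting protein families A and B (say,
histidine kinases and response regulators of bacterial two-component
systems), each species typically carries several paralogs of each family,
and it is unknown *which* A paralog interacts with *which* B paralog.
`copair` infers a within-species bijection `π` that assigns to every A
sequence its putative partner in B, using only the two MSAs. It is aimed at
anyone who needs accurate paired co-alignments (co-MSAs) — for
coevolutionary analysis, interaction-specificity studies, or as input to
complex-structure prediction — in families where genomic co-localization
cannot resolve the pairing.

## The method

Two evolutionary signals are combined in a two-stage pipeline:

1. **Graph alignment (GA).** Interacting partners co-diverge, so the
   sequence-similarity structures of the two families mirror each other.
   Each family is turned into a weighted similarity network — either a
   k-nearest-neighbor graph or a reciprocal-best-hit orthology graph over
   Hamming distances, with edge weights `w_mn = exp(-d_mn²/D²)` — and the
   two networks are aligned by minimizing

   ```
   C(π) = − Σ_{(m,n) ∈ E_A} w^A_mn · w^B_{π(m)π(n)}
   ```

   over within-species matchings (cross-species pairs are structurally
   forbidden). The minimization uses simulated annealing with the
   exponential schedule `T(t) = T0·αᵗ` and within-species partner-exchange
   moves. Pairs predicted identically across many independent annealing
   replicates ("robust pairs") are empirically far more precise than any
   single run and form a high-confidence partial co-MSA.

2. **Iterative pairing algorithm (IPA).** The robust pairs seed a
   coevolution-driven loop: a pair-scoring model — mean-field DCA
   (inter-family Potts couplings, statistical energy `E(a,b) =
   −Σ_ij J(i,j,a_i,b_j)`) or summed pointwise mutual information — is fit on
   the trusted co-MSA; all unresolved within-species pairs are scored; an
   optimal one-to-one assignment is solved per species; and the
   `N_increment` proposals with the largest confidence gap (optimal
   assignment total minus the best total with that pair forbidden) are
   promoted into the training set. Iterating grows a full co-MSA.

The combination ("GA-IPA") dominates both ingredients precisely where each
alone struggles: shallow alignments and families with many paralogs per
species. MirrorTree-style baselines (distance-matrix Pearson correlation,
globally optimized or used as an IPA score) and a planted-truth synthetic
generator are included, so every stage can be validated end to end. The
expected accuracy of random within-species pairing — the null — is exactly
`N/M` (species count over sequence count).

## Worked example

Generate a hard synthetic benchmark (12 species, ~14 paralog pairs per
species on average, moderate inter-family coupling), then run each method:

```bash
$ copair simulate --config sim.yaml --outdir demo --out-prefix toy --seed 7
wrote 144 pairs / 12 species to demo

$ copair ga     --family-a demo/toy_A.fasta --family-b demo/toy_B.fasta \
                --truth demo/toy_truth.tsv --outdir demo/ga \
                --seed 1 --k 8 --replicates 10
129 robust pairs across 10 runs; mean TP 0.867; robust TP 0.922

$ copair ipa    --family-a demo/toy_A.fasta --family-b demo/toy_B.fasta \
                --truth demo/toy_truth.tsv --outdir demo/ipa --seed 1 --model dca
completed in 24 iterations; TP 0.153

$ copair ga-ipa --family-a demo/toy_A.fasta --family-b demo/toy_B.fasta \
                --truth demo/toy_truth.tsv --outdir demo/run \
                --seed 1 --k 8 --replicates 10 --model dca
robust seed 129 pairs; 3 IPA iterations; TP 0.896

$ copair evaluate --pred demo/run/ga_ipa_matching.tsv --truth demo/toy_truth.tsv \
                  --family-a demo/toy_A.fasta --family-b demo/toy_B.fasta
TP fraction 0.8958 (FP 0.1042) over M=144, N=12; random baseline N/M = 0.0833
```

Reading the numbers: with ~14 paralogs per species a random pairing would be
right 8.3% of the time. Coevolution alone (seedless DCA-IPA) reaches only
15% on this small, hard dataset; graph alignment alone averages 87%, and its
replicate-consensus "robust" subset of 129 pairs is 92% correct. Seeding the
IPA with that robust subset lifts the final full pairing to 90% — the
combined pipeline beats both of its parts.

The same pipeline is available as a library (`copair.simulate`,
`copair.build_knn_network`, `copair.anneal`, `copair.robust_pairs`,
`copair.ipa_run`, `copair.ga_ipa`, `copair.evaluate`, ...); every CLI
command is a thin wrapper over these functions.

### Input format

Aligned FASTA per family, with a species token in each header
(default dialect `id|species`; configurable via `--species-pattern`, which
accepts a delimiter character or a regex with a `species` group). Every
species must contribute the same number of sequences to both families.
Ground-truth pairings, predictions and robust-pair sets are TSV
(`id_a`, `id_b`, `species`).

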