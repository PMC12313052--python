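# Methods

## Landscape model and scores

The fitness landscape is a Potts model over an amino-acid alphabet
(default: the 20 canonical residues, no gap symbol — only substitution
variants are scored). Its statistical energy is

    E(σ) = Σ_i h_i(σ_i) + Σ_{i<j} J_ij(σ_i, σ_j)

stored with the sign convention that **higher energy = higher predicted
fitness**, so the epistatic score of a variant, ΔE = E(mutant) − E(wt), is
positive for predicted-beneficial exchanges. This makes "highest predicted
fitness" unambiguous everywhere downstream. The independent score drops the
couplings: Σ over mutated sites of f_i(mut) − f_i(wt).

Coupling strength between positions uses the standard contact-ranking
pipeline: each q×q coupling block is moved to the zero-sum gauge (row and
column means removed), reduced to its Frobenius norm, and the
average-product correction (APC) subtracted. APC can produce small negative
values; these are clipped at zero so strengths are symmetric and
non-negative. The model file format is documented in the README; fitting
h and J from an alignment is out of scope (models come from external
inference tools), and import of tool-specific binary model formats is left
as future work — the plain-text format is canonical.

## Metropolis-Hastings in silico evolution

Chains start at the wild type. One step proposes a single exchange —
position uniform over allowed positions, replacement symbol uniform over
allowed symbols other than the current one — and accepts with probability
min(1, exp(ΔE/T)). Improving moves are always accepted; the temperature T
sets how readily deteriorating moves pass, which lets chains cross fitness
valleys that a greedy walk cannot.

*Trust radius.* The Hamming distance to the wild type is capped. At the
boundary, proposals are drawn only from already-mutated positions
(substitution or reversion) rather than proposed-and-rejected; this keeps
the chain irreducible inside the ball and wastes no proposals. Reversions
of introduced mutations are always permitted (required for irreducibility);
with an explicit allowed-move set, the per-position symbol pool is the
listed replacements plus the wild-type symbol.

*Correctness.* When the trust radius covers the whole space the proposal
kernel is symmetric and the stationary law is the Boltzmann distribution
exp(E/T)/Z — verified against exhaustive enumeration (total-variation
distance < 0.02 at 10⁶ steps on an L=3, q=2 landscape). At the boundary the
restricted kernel deviates slightly from detailed balance with respect to
the Boltzmann law; this is a deliberate trade for proposal efficiency and
is documented rather than corrected, since the sampler is used as a search
heuristic, not an estimator.

*Reproducibility.* Per-trajectory RNG streams are spawned from the master
seed (`numpy` SeedSequence), so records are byte-identical across runs,
worker counts (`n_jobs`, via joblib), and trajectory-count changes (chain
i is unaffected by how many chains follow it).

*Default parameters* mirror the published protocol: stage 1 runs 2000
trajectories × 500 steps at trust radius 2 for T ∈ {0.3, 0.03, 0.003};
stage 2 runs 750 × 500 at radius 3 with T = 0.03. Tests and the acceptance
script scale these to 200 × 200 to fit a single-CPU time budget; the
planted-recovery acceptance check demonstrates the protocol works at that
reduced scale.

## Two-stage library design

Stage 1 nominates positions: the exchanges occurring most frequently among
the highest-scoring sequences are shortlisted (default 30; ties broken by
higher single-mutant epistatic score, then position). Stage 2 re-runs the
sampler with moves limited to the shortlist and tallies pairwise
co-occurrence among its top sequences.

Two design choices here were genuinely open:

- **What counts as a "top sequence".** Frequencies are counted over
  per-trajectory best states *without* collapsing duplicates — a state
  found independently by many chains is evidence, and the count is the
  signal. (The ranked-output function `extract_top_sequences` does collapse
  duplicates, with deterministic tie-breaking: score, then first-visited
  order, then mutation label.) Stage 1 counts every trajectory's best (a
  wide nomination net, needed at scaled-down trajectory counts); stage 2
  counts the top quarter by score, where co-occurrence concentrates.
- **The final pick.** Occurrence and co-occurrence frequencies shortlist
  candidates, and the predicted fitness of the combinatorial variants
  decides: the recommendation is the k-subset (from the top-2k candidates
  plus the greedy co-occurrence set, one exchange per position) whose full
  combination has the highest epistatic score. The pure greedy
  co-occurrence selection is also exposed (`select_cooccurring`) and
  reported alongside. At near-greedy stage-2 temperatures chains freeze at
  their first accepted moves, so co-occurrence tallies alone are noisy at
  reduced scale; the fitness-decided step makes the recommendation robust
  without touching the sampler.

`enumerate_library` expands k ≤ 16 exchanges into all 2ᵏ member variants
(wild type included) with epistatic and independent scores. Barcodes are
random 20-mers, rejection-sampled to a pairwise Hamming floor (default 5 —
tolerant of the 20% matching error budget used in counting).

## Barcode counting

The barcode window is located by searching for the upstream flanking anchor
(exact, then best approximate match allowing 20% anchor mismatches; if the
upstream anchor is unrecoverable the downstream anchor is used and the
window counted backwards). The read is assigned to the library barcode with
minimum Hamming distance if distance/length ≤ 0.2 **and** the best hit is
strictly better than the second best — a deterministic proxy for a
mapping-quality ≥ 1 uniqueness filter. Hamming (not edit) distance is used
because barcodes are fixed-length and flank-anchored; a read with an indel
inside the window goes unmatched. Random-length phasing spacers upstream of
the amplicon are absorbed by the anchor search, not fixed offsets.

## Fitness estimation and QC

Relative abundances use a pseudocount of 0.5 (ratios would otherwise be
undefined at zero counts). Per replicate, a variant's fitness is the OLS
slope of log2 relative abundance against generations; per condition,
replicate slopes are averaged and centered by the **read-weighted** pool
mean, so the pool-average fitness is exactly 0 (the estimator is defined
this way; the exact normalization used in the original analysis notebooks
is not published, so this conventional pooled-screen definition is declared
rather than inferred). The 95% CI is a t-interval over replicate slopes.
Variants with zero counts at every time point are flagged: their estimate
is a lower bound, not a point estimate.

QC statistics: the Gini index of a sample's abundance vector (mean absolute
pairwise difference over twice the mean; 0 = perfectly uniform, (n−1)/n =
single-variant pool), pairwise replicate Pearson r on log2 abundances per
time point with a configurable pass threshold (default 0.8), and the
Pearson correlation (with two-sided t-test p) of per-variant fitness
between conditions.

Generations are related to wall-clock time by t = ln(2)/growth rate when
needed; the default sampling grid is generations 0, 2, 4, 6, 8, 10.

## Growth and assay calculators

Batch growth rates regress **raw OD** against time within a fixed window
(default 12.5–37.5 h after transfer), as the batch protocol states; an
explicit `log_od=True` mode fits ln(OD) instead, which is what "specific
growth rate" conventionally implies — both are available because the two
conventions coexist in practice, and results report which mode produced
them. Doubling time is ln(2)/rate.

The NADH-depletion assay conversion is centralized so unit factors are
never hand-applied: absorbance slope (A340/s) → concentration slope
c′ = (slope/β)/2 in M/s (β = 1569 L/mol; the factor 2 accounts for two
3-phosphoglycerate per RuBP) → k_app = −c′/[protein] in 1/s (default
[protein] = 500 nM), positive when absorbance decreases.

## Synthetic-data generator: what it emulates, and what not

The generator's defaults state one concrete world, chosen once:

- **Landscape** (L = 60, q = 20): background substitution effects are
  Normal(−2.0, 0.5), truncated above at +0.3 — the bulk of substitutions in
  a conserved protein is deleterious, and this is what makes a near-greedy
  low-temperature search meaningful. Five planted beneficial exchanges get
  field boosts drawn U(2.6, 4.7), the spread of the strongest single-
  replacement scores such models report for real targets; 50 decoys get
  U(−1.0, +0.5) (the weak near-neutral tail). All planted pairs carry a
  +1.0 coupling: the planted set is mutually compatible, and each planted
  double mutant scores above the sum of its singles by exactly that margin
  (the rescue-epistasis motif seen in the screen being emulated). Planted
  positions carry no random background couplings, so the planted exchanges
  are exactly the top-ranked singles. Background couplings are sparse
  (density 0.05, scale 0.2).
- **Competition** (16 variants, 4 replicates, 2 conditions, generations
  0–10, depth 10⁶): expected frequencies follow x_i(g) ∝ x_i(0)·2^(f_i·g);
  counts are multinomial per sample; replicates start from Dirichlet-
  jittered copies of a near-uniform pool (so starting-pool Gini lands below
  the 0.15 QC bar); true fitness forms three separated groups (0, −0.4,
  −0.9 log2/generation, jitter 0.03, wild type pinned at 0 and nothing
  above it) and the second condition adds 0.05 s.d. noise to the first
  (emulating the observed near-unity between-condition correlation).
- **Reads**: anchor + barcode + anchor with a random 0–3 nt phasing prefix
  and independent per-base substitution errors; constant quality scores.

Not emulated: realistic MSAs (no model refitting), Illumina quality-score
profiles, indels in reads, PCR amplification bias, and barcode
cross-contamination. A green recovery test therefore establishes that the
pipeline's inference is correct *under multinomial sampling and
substitution noise*, not that it is robust to those unmodelled artefacts.

## Numerical notes

- MH score updates are O(L) incremental field/coupling differences; each
  recorded score equals the full energy difference to machine precision
  (asserted in tests).
- Acceptance underflow: exp(ΔE/T) below ~1e−323 is treated as 0.
- Gini uses the sorted-vector identity for the mean absolute difference,
  O(n log n).
- Barcode rejection sampling fails loudly after 10⁴ attempts per member
  rather than looping forever on unsatisfiable constraints.
- Tie-breaks everywhere are deterministic and documented (score, then
  position order, then symbol), so identical inputs give identical designs.

## Known limitations

- The sampler's boundary proposal rule trades exact detailed balance at the
  trust-radius surface for efficiency (see above).
- The fitness estimator assumes exponential selection with constant
  per-generation effects; frequency-dependent or time-varying selection
  would bias slopes.
- The mapping-quality proxy (strict uniqueness) is conservative: reads
  equidistant to two barcodes are discarded even when both candidates imply
  the same variant set.
- `coupling_strength` recomputes the full APC matrix per call; for repeated
  queries use `coupling_matrix` once.
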