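# Methods

This note records the model, the numerical choices, and the design
decisions behind cgrphylo, in the spirit of a statistical package's methods
appendix. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Sequence preparation

All records of a taxon's FASTA file are concatenated in file order,
uppercased, and every character outside {A, C, G, T} is deleted — ambiguity
codes, Ns and gaps contribute nothing and do not reset the walk. The
reverse complement of the whole concatenated string is then appended once
(not per record), which makes every k-mer count equal its reverse
complement's count up to a single junction word and removes strand
orientation as a nuisance variable. Junction k-mers arise at record
boundaries and deletions; for the megabase-scale inputs the method targets
they contribute O(records·k) of O(L) counts and are ignored by default; a
walk-reset variant (`compute_fcgr_segments`, CLI `--reset-at-boundaries`)
counts each record separately and excludes junction words entirely, for
users who want to verify the boundary effect is negligible on their data. Softmasked
(lowercase) bases are kept: masking conventions differ between assemblies,
and dropping repeats would change the signature being compared.

`shred_subsample` (the sequence-length experiment) permutes whole records
with a seeded RNG before concatenation and takes a prefix — permuting
records, not nucleotides, preserves local k-mer structure, which is what a
"how much data is enough" experiment must keep intact.

## FCGR computation

The CGR walk is the midpoint iteration from (0.5, 0.5); it is evaluated as
a linear recurrence (scipy `lfilter`), which performs the same halving
arithmetic as the sequential loop. The walk is only used for rendering and
as a cross-check: FCGRs themselves are computed by exact integer k-mer
counting in O(L), immune to float drift. The two agree cell-for-cell for
every walk point with a full-length suffix, i.e. points i ≥ k; the first
k − 1 points (suffix shorter than k) are excluded from counts. Their
contribution would be at most k − 1 counts and no convention for them
changes any distance at the precision reported.

Cell indexing: column bit i−1 is 1 when character i of the k-mer is G or T,
row bit i−1 when it is A or T, so the last character selects the biggest
quadrant — exactly the square containing the walk point after reading the
word. Indices are 0-based, row 0 at the top (image coordinates).

k is supported in 1..8. At k = 8 a profile is 65,536 cells; distance
matrices are O(4ᵏ·s²) for s taxa, still trivially desk-scale.

## Masking, standardization, order of operations

EST libraries retain poly-A tails to a degree that varies with library
construction, so the Aᵏ and Tᵏ cells carry per-dataset artifacts unrelated
to phylogeny; at high resolution (k > 5) those two cells can dominate the
Euclidean distance outright. Masking zeroes exactly those two cells, on the
**raw counts, before standardization**: the Pearson distance is defined on
raw counts, so masking must exist at the count level, and standardizing
after masking lets the surviving cells carry the full 4ᵏ mass (mean 1).
Masking is applied whenever a dataset is declared EST-type, at every k —
the rule is harmless at low k and essential at high k. Masked cells stay in
the cell count n of the Euclidean mean (they are zeros, not missing data).

## Distances

Euclidean: d = (2ᵏ/4ᵏ)·√Σ(āᵢⱼ−b̄ᵢⱼ)² = √(mean squared cell difference).
The prefactor makes d an RMS per-cell quantity, comparable across k; any
alternative positive constant would rescale all pairwise distances equally,
and distance-based topologies (NJ, consensus) are invariant under global
scaling — a property the suite tests directly, so the normalization choice
is demonstrably inert for trees.

Weighted Pearson: with weights wᵢ = xᵢyᵢ/n_w, n_w = Σxᵢyᵢ, weighted means
x̄_w = Σxᵢ²yᵢ/n_w (symmetrically ȳ_w), weighted SDs s_x, s_y, and
d = 1 − Σ((xᵢ−x̄_w)/s_x)((yᵢ−ȳ_w)/s_y)wᵢ ∈ [0, 2]. The product weights
emphasize cells populated in both profiles. Degenerate cases raise typed
errors: n_w = 0 ("no shared support") and zero weighted variance
("degenerate profile"). The implementation clips a possible −10⁻¹⁶ float
residue at 0.

Distances are computed once per unordered pair and mirrored, so matrices
are exactly symmetric; all arithmetic is double precision.

## Tree reconstruction

Neighbor-Joining is the standard Saitou–Nei agglomeration on the
Q-criterion with rate-corrected branch lengths. Ties in Q are broken by the
first pair in row-major matrix order — deterministic across platforms, no
RNG involved. Negative branch-length estimates are clamped to 0 (common
practice; they arise only from noise). NJ is exact on additive matrices,
which the suite verifies on 50 random additive trees (topology and path
lengths to 10⁻⁹); an independent NJ implementation (scikit-bio) serves as a
cross-check on noisy matrices.

Consensus is strict majority rule: exactly the bipartitions occurring in
more than `threshold` (default 0.5) of the replicate trees, annotated with
their percentage; no greedy completion of compatible minority splits, so
unsupported regions appear honestly as polytomies. Thresholds ≥ 0.5
guarantee the retained splits are mutually compatible.

Branch lengths on a fixed topology minimize Σᵢ<ⱼ (dᵢⱼ − pᵢⱼ)²/dᵢⱼ² over
non-negative edge lengths (pᵢⱼ = tree path length) — the Fitch–Margoliash
weighting with the topology frozen. The fit is a non-negative least-squares
solve (scipy `nnls`) on the pair-by-edge incidence system: deterministic,
exact on additive inputs. Pairs at distance 0 (identical profiles) would
have infinite weight; they get unit weight instead, with a warning. A full
Fitch–Margoliash *topology search* is deliberately not implemented: NJ
serves as the search step, and fixed-topology least squares puts lengths on
consensus trees, the combination the overall method actually needs.

Newick I/O goes through dendropy; supports travel as internal node labels;
branch lengths print with 6 significant digits. All split comparisons are
label-based (canonical side: the one not containing the lexicographically
smallest leaf), independent of rooting and taxon-namespace identity.

## Bootstrap semantics

The FCGR bootstrap treats the 4ᵏ cells as the characters of a
taxon-by-character matrix: one index vector of 4ᵏ uniform draws with
replacement per replicate, applied to **every** taxon. Resampling each
taxon independently would compare different characters across taxa and
destroy the analogy to the classical sequence bootstrap; it is rejected.
On the Euclidean path each resampled vector is re-standardized (sum 4ᵏ)
within the replicate, so the distance's precondition holds for every
replicate; this choice is recorded in the run MANIFEST so the alternative
(resampling standardized values without renormalizing) can be compared.
EST masking precedes resampling: masked cells are zeros that can be drawn
but carry no signal.

RNG scheme: replicate r, attempt a of a run with master seed s uses
`SeedSequence(entropy=s, spawn_key=(r, a))` (NumPy PCG64), so any replicate
is reproducible in isolation. A degenerate replicate (all-zero Euclidean
resample, or a Pearson profile with zero weighted variance) is redrawn from
the next attempt substream and counted; 10 consecutive failures abort the
run. Identical configurations produce byte-identical outputs.

The point-estimate NJ tree is annotated with per-split bootstrap
percentages; if its topology differs from the consensus, both trees are
written and the difference is visible in the artifacts.

## Synthetic data

The generator produces (a) i.i.d. sequences with controlled GC, (b) random
additive trees with exact path-length matrices — the NJ oracle — and (c)
sequences evolved along a known tree under a Jukes–Cantor-like process:
per-site substitution probability 1 − exp(−rate·t) across a branch of
length t, mutating to a uniformly chosen different base. Indels, repeats,
isochores and codon structure are deliberately omitted: the method consumes
k-mer composition only, and an i.i.d. substitution process already yields
graded compositional divergence with a known true topology. Passing tests
therefore demonstrate correctness of the machinery and the qualitative
behavior of the method (resolution, metric, masking, length effects) — not
performance on real genomes, whose repeat content and regional structure
add signature components this simulator does not model.

Study conditions used by the tests and acceptance script, chosen once as
realistic for the regimes they probe:

* **Two-clade preset**: 8 taxa on a balanced tree, unit branches, rate
  0.03/unit (≈ 3% divergence per branch — close relatives), root length
  50,000 nt, k = 6, B = 100–500 for bootstrap checks. Small enough to run
  in seconds, large enough that k = 6–8 signatures are well populated.
* **Resolution/metric comparisons**: same preset, k ∈ {3, 8}, Euclidean vs
  Pearson, 20 seeds.
* **EST masking**: root length 30,000 nt chopped into 300-nt reads, every
  read carrying a geometric poly-A tail whose per-taxon mean is drawn from
  40–400 nt — emulating libraries trimmed to different degrees, so tail
  abundance is uncorrelated with phylogeny. At k = 8 the unmasked corner
  cells then dominate the distances.
* **Length degradation**: rate 0.001/unit (very low divergence, the regime
  where data volume is limiting), 1,000 vs 50,000 nt at k = 8.

## Known limitations

* The simulator's homogeneous composition makes recovery easier than on
  real genomes with shared repeat families; absolute recovery percentages
  are properties of the simulation, only the orderings (higher k helps,
  Euclidean ≥ Pearson, masking rescues EST data, longer sequences help)
  are the claims being checked.
* Pearson distance is undefined for disjoint-support or constant profiles;
  such inputs are rejected rather than patched.
* Consensus trees may contain polytomies; the least-squares fit then has
  fewer edges and pair paths share edges accordingly.
* No rooting is inferred; trees are unrooted and display rooting is the
  viewer's choice (use an outgroup taxon for interpretation).
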