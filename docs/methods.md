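# Methods

## The representation

`fpe` turns a DNA sequence into a numeric vector in three stages and
compares sequences by a distance between those vectors.

**Cleaning and blocking.** Input is uppercased and every character
outside Ω = {A, C, G, T} is removed (IUPAC ambiguity codes, gaps,
whitespace); cleaning is idempotent and happens strictly before
blocking, so blocks never span removed characters.  The cleaned
sequence is cut into consecutive windows of `block_size` bases
(`l_block`); a trailing window shorter than `l_block` is discarded, so a
sequence of length L yields exactly `floor(L / block_size)` blocks.
Coordinates for sub-region extraction are 1-based inclusive (the
GenBank convention), so a region a..b has length b − a + 1.

**Pattern mining.** Each block is mined independently for its *maximal
frequent patterns* with a prefix-growth miner in the PrefixSpan style,
specialised to a single ungapped sequence.  The support of a pattern is
its number of occurrences in the block, with overlaps counted (the
support of `AA` in `AAAA` is 3) — this is the convention forced by the
pseudo-projection arithmetic.  A pattern's *projected database* is the
sorted list of 1-based end positions of its occurrences; extending a
pattern by one base maps each end `c` to `c + 1` when the block has
that base at `c + 1`.  A pattern is emitted when it

1. is frequent: support ≥ `s_min`;
2. is closed under left extension: the set {c − |pattern|} of
   positions immediately preceding its occurrences is not contained in
   any single base's position set (an occurrence starting at position 1
   contributes 0 and can never be covered, correctly forcing
   "closed");
3. has no frequent single-base right-extension;
4. has length ≥ `l_min`.

Left non-closedness is inherited by every right-extension, so the miner
prunes non-closed patterns from the search without losing anything; the
`l_min` filter applies only at emission, never to recursion (short
prefixes must still grow).  The recursion order over Ω is fixed
(A, C, G, T) for determinism, and results are reported in lexicographic
order.  This "no frequent right-extension + closed" emission rule is
deliberately the operational one; a pattern can still have a frequent
*left* super-sequence of strictly smaller support.  The brute-force
oracle (`brute_force_maximal`) exposes the literal alternative — no
frequent super-sequence of any kind — behind `strict=True`; the strict
set is provably a subset of the default one, and on the 20-base worked
example the two coincide.

**Entropy.** A pattern of length `l_pat` with support `s_pat` in a
block has probability

    p_pat = s_pat / (l_block − l_pat + 1),

its support over the number of windows that could host it.  The block's
entropy is the support-weighted surprisal average over the mined set R,
in nats (natural logarithm):

    H = −(1 / Σ_R s_pat) · Σ_R s_pat · p_pat · ln(p_pat).

The weights sum to one and each term p·ln(1/p) ≤ 1/e, so
0 ≤ H ≤ 1/e ≈ 0.3679 always.  When aggressive thresholds leave R empty
the 0/0 expression is defined as H = 0, with a logged warning naming
the block; this keeps every vector well-formed while flagging the
information loss.  The ordered block entropies are the sequence's
vector, so sequences of different lengths get vectors of different
dimensions.

## The distance

For vectors V1 (dimension m) and V2 (dimension n), with V1 the shorter
(inputs are swapped if necessary, which makes the measure symmetric),
an anchor offset k in 1..n−m+1 minimises |V2[k] − V1[1]|, ties going to
the smallest k for determinism.  The distance is

    dist(V1, V2) = (n/m) · sqrt( Σ_{i=1..m} (V2[k+i−1] − V1[i])² ).

The dimension ratio multiplies the *root*, not the sum under it — only
this reading reproduces the worked-example value 0.003579
(= 1.5 × 0.002386).  With n = m the formula degenerates to the plain
Euclidean distance.  The anchor uses the first component of V1 only; a
full-window best-offset alignment would be a different (and more
expensive) measure and is intentionally not implemented.  The measure
is non-negative, symmetric and zero on identical vectors, but the
triangle inequality is not established and nothing in the package
relies on it; the "distance" is a dissimilarity score, which is why
significance testing is out of scope.

## Defaults and tunables

| parameter | default | meaning |
|---|---|---|
| `block_size` | 200 (3000 for the noise test) | window length in bases; below ~400 preserves fine-granularity location/ordering information |
| `s_min` | 3 | minimum pattern support per block |
| `l_min` | 2 | minimum emitted pattern length |
| `n_trials` | 100 | trials per robustness experiment |
| `segment_fraction` | 0.1 | shuffled-segment length relative to the sequence |
| `noise_ratio` | — | inserted bases per original base |

`s_min` and `l_min` trade off against each other: raising both tends to
empty R in some blocks (H = 0, information lost).  The 11-species
pairwise benchmark matrix uses `block_size=200, s_min=2, l_min=8`.

## Experiments

*Segment shuffle:* per trial a uniformly placed consecutive segment of
length `floor(segment_fraction·L)` is cut out, its bases permuted
uniformly, and the distance between original and shuffled segment
recorded.  *Insertion noise:* `floor(noise_ratio·L)` uniform bases are
inserted at slots drawn uniformly with replacement over the original
sequence's L+1 gaps (one-pass application; for i.i.d. uniform letters
this is equivalent to sequential insertion with re-indexing).  A block
size larger than the sequence switches blocking off: the whole sequence
is mined as a single block rather than yielding an empty vector — this
is the intended regime of the noise experiment.  Both drivers use a
`numpy.random.default_rng` generator seeded explicitly and are
bit-reproducible; `TrialSummary.std` is the population standard
deviation (ddof = 0).

*Tree building* hands the pairwise matrix to
`scipy.cluster.hierarchy.linkage` (average linkage = UPGMA by default)
and serialises the result as rooted Newick, each node at half its merge
height so that an ultrametric input is reproduced exactly.  Only the
topology (e.g. the human–chimpanzee–gorilla clade) should be
interpreted; branch lengths depend on the linkage convention.

## Synthetic data and what the tests show

Test inputs are generated in-package: the 20-base worked-example block
is reconstructed uniquely from its four single-base projected databases
(which partition 1..20) and acts as the convention gate — if its mining
result ever changes, the 1-based end-position convention has been
broken.  Random sequences are i.i.d. uniform over Ω.  Real genomic
sequence is not i.i.d. — it has composition bias, repeats and
long-range structure — so passing tests establish the algebraic
correctness and determinism of the pipeline, not biological claims;
the separate full-data integration tests (run after fetching the
11 β-globin GenBank regions with `scripts/fetch_beta_globin.py`) check
the published benchmark numbers on real data.  Robustness experiments
in the default suite run on random sequences of benchmark-gene scale
(~1.2–1.5 kb) with reduced trial counts (3–6) so the whole suite stays
in seconds; the 100-trial protocol is exercised in the full-data
integration test.

## Numerical notes

Entropies are computed at full double precision and serialised at six
decimals; matrices default to four decimals (flag-switchable).  The
miner/oracle equivalence is checked on 500 random blocks of lengths
10–100 with `s_min` in {2,3,4} and `l_min` in {2..8}.  Degenerate
inputs: an empty cleaned sequence raises; a sequence shorter than one
block yields an empty vector, and distances against empty vectors
raise with the offending ids named; anchor ties and linkage ties are
broken deterministically (smallest index / scipy's ordering).

## Known limitations

The charset is fixed to DNA; the miner is plain pseudo-projection with
no suffix-structure acceleration (adequate at gene scale, not for
chromosomes); gapped patterns and multi-sequence mining are out of
scope; the distance is not a metric; and vectors are only comparable
between runs that used the same `block_size`, `s_min` and `l_min`.
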