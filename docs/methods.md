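# Methods

## Model

The scoring parameters are derived analytically — no fitting loop — from
contact-distance frequencies in labelled decoy pools. For one
receptor–fragment case with a labelled pool of poses:

1. **Coarse graining.** Atoms are grouped into beads by a configurable
   typing table; each bead is the unweighted geometric centre of its
   group's heavy atoms. The shipped default table uses 2 backbone + 0–2
   side-chain beads per amino acid (31 protein types) and 1 phosphate +
   2 sugar + 3–4 base beads per nucleotide (17 RNA types), so at most
   31 × 17 = 527 cross-side bead-type pairs exist. The atom grouping
   itself is a package convention: group membership follows ordinary
   chemical-moiety boundaries (e.g. the arginine guanidinium, the
   tryptophan indole split into pyrrole and benzene rings), and any
   other table respecting the per-residue bead counts can be loaded
   from YAML.
2. **Labels.** Poses are labelled from their ligand RMSD (LRMSD) to the
   bound native fragment: near-native < 5 Å, non-native > 7 Å,
   intermediate otherwise (ignored in counting). LRMSD is computed in
   the fixed receptor frame with no superposition, consistent with a
   rigid, bound receptor; the 0.2 Å deduplication RMSD uses the same
   unfitted convention. Cases with fewer than 100 near-natives are
   excluded from training (the sampling problem).
3. **Distance arrays.** For each pair (i, j), all bead–bead distances
   are counted into 27 right-closed ranges — (0, 2], 0.25 Å bins over
   (2, 7], 1.5 Å bins over (7, 14.5], (14.5, ∞) — split by label into
   near-native and non-native columns, and split into three rank-based
   sub-pools of the original scoring (reference proportions 1 % / 9 % /
   90 % of the pool; for pools smaller than the reference 10^7 poses
   the sub-pool boundaries are scaled proportionally). Column totals
   A_ij, B_ij and the threshold w_ij = A_ij/60 are computed per
   sub-pool, treating each sub-pool as an independent pool part.
4. **Refinement.** Scanning ranges top-down, a range whose near-native
   count is below w_ij is merged with its successors until the merged
   count reaches the threshold ("reaches" read as ≥, which makes the
   trigger condition `d_k1 < w` and its termination consistent). A
   trailing remainder that can never reach the threshold is folded back
   into the last refined range, which guarantees termination and
   conserves both column sums; if no near-native mass exists at all the
   sub-pool part is flagged unusable and contributes nothing.
5. **Log-odds histogram.** Each refined range x gets
   `ln d*_x1 − ln d*_x2 − (ln A_ij − ln B_ij)`. Refinement guarantees
   d*_x1 > 0; a zero non-native count d*_x2 is replaced by a
   pseudocount of 1, which bounds the log-odds without discarding the
   range. Proportional columns give identically zero values, and the
   centring term makes the values invariant under rescaling either
   column.
6. **Scoring.** A pose's score sums, over every pair in the histogram
   set and every usable sub-pool part, the values of the ranges its
   contacts fall into. All sub-pool parts are applied to every pose
   (summed): a pose's geometry does not depend on its original rank,
   and this convention is the only one defined for unranked inputs.
   The vectorised pool scorer expands the per-part values onto the
   27 base ranges once (refined ranges are coarsenings of the base
   set) and is tested to agree with the direct per-pair reference
   implementation to 1e-9 relative.

## Consensus collection

One potential per training case is derived, every case is scored with
every candidate, and a candidate succeeds on a case when it places
≥ 60 % of the case's near-natives in its top 5 %. The N = 4 candidates
whose success sets jointly cover the most cases are selected by
exhaustive subset enumeration (up to 10^6 subsets, otherwise greedy
max-coverage, flagged in the result); ties break by larger summed
capture, then lexicographic candidate ids, making selection
deterministic. Applying a collection ranks the pool with each member
and pools the rankings round-robin (rank 0 of every member, then
rank 1, …), keeping each pose's first (best) contributing rank, until
exactly 20 % of the pool is selected (TopC); with a 10^7-pose universe
this is exactly 2,000,000 poses. Round-robin realises "about 5 % per
member, deduplicated to 20 %" while keeping contributions balanced.

Training/test splits are leave-homology-out: a random seed complex not
yet used in any test set, plus every complex with protein sequence
similarity above 40 %, forms a test set; the remainder trains. The
similarity statistic is pluggable; the default is global-alignment
identity (identical columns / alignment length, match 2, mismatch −1,
gap open −2, extend −0.5). With overlapping homology clusters a complex
similar to two different seeds can appear in two test sets; soundness
(no > 40 % pair across any train/test boundary) always holds and is
what the tests assert.

## Synthetic decoy generator

The generator is the package's test substrate and defines its study
conditions. A case is a quasi-spherical receptor cloud (default 120
beads on a radius-18 Å Fibonacci lattice with 0.5 Å radial jitter,
cycling through all 31 protein types) plus a trinucleotide fragment
(default GCA, 20 beads). A planted signal — default one
arginine-guanidinium (i = 23) : phosphate (j = 1) contact at
3.5 ± 0.4 Å, three contacts per pose, a salt-bridge-like geometry —
defines the native placement; non-planted fragment beads are held
outside the planted contact range so the planted pair is the closest
approach. Near-natives are the native plus 0.8 Å per-bead noise with
planted contact distances redrawn from N(μ, σ); non-natives draw each
bead independently from a shell spanning 3 Å inside to 9 Å outside the
receptor radius, giving broad, featureless contact distances. Labels
are recomputed from each pose's actual LRMSD, so label–geometry
consistency holds by construction. Ranks are a noisy monotone function
of LRMSD (Spearman ≈ 0.3), mimicking an original scoring that is weakly
but not totally uninformative, and span all three rank sub-pools.

Default pool size is 6000 poses with 300 near-natives — desk-scale
rather than the 10^7 poses of a production docking run, chosen so the
full train/score/evaluate cycle runs in seconds while preserving the
three-sub-pool structure and a realistic near-native minority. Multi-
case families share one receptor; cases are assigned round-robin to
binding modes (default: the salt-bridge mode above and a
tryptophan-ring : sugar stacking-like mode at 5.5 ± 0.5 Å), cases of a
mode share their site, and 30 % of every case's non-natives are placed
at the *other* modes' sites. These cross-mode decoys are what makes a
potential trained on one mode penalise the geometry of the others —
without them every per-case potential succeeds on every case and a
consensus collection would be pointless; with them the success matrix
is block-diagonal by mode, as expected when distinct binding modes
exist. With an empty signal list the generator emits a null-control
pool (background poses, randomly assigned labels, no native), for which
derived potentials collapse towards zero.

What the generator does **not** emulate: real RNA covalent geometry and
conformational preferences (poses are bead clouds, not conformers of a
fragment library), receptor shape beyond a sphere, excluded volume,
any energy landscape, and the contact correlations of real binding
interfaces. Passing tests therefore demonstrate that the potential
machinery recovers the statistical structure it assumes — planted
preferred contact distances against a featureless background — not that
it reproduces benchmark success rates on experimental complexes, which
would require production docking decoys.

## Numerical choices and degenerate inputs

- Range bins are right-closed, (a, b]; a distance exactly 2.0 Å falls
  in (0, 2]. Distances of exactly 0 (coincident beads) are clipped into
  the first bin.
- Ranking sorts by descending score with ties broken by original rank,
  then pose position — outputs are fully deterministic.
- Deduplication scans in rank order, so the better-ranked pose of a
  redundant group survives; the contact-level case redundancy check
  uses multiset-Jaccard over (i, j, range) triplets with a 0.8 default
  cutoff.
- Pools smaller than the rank sub-pool cover: boundaries scale
  proportionally; sub-pools without near-native or without non-native
  mass are omitted from the corresponding histogram part.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical configurations produce
  byte-identical pool files.

## Limitations

- The atom→bead grouping of the default table is a reasonable
  moiety-based convention, not a reproduction of any particular docking
  engine's reduction; potentials derived with different tables are not
  interchangeable (the histogram set records its table shape and
  scoring refuses mismatched inputs).
- Bead centres are unweighted; mass-weighting is not implemented.
- The per-pair threshold divisor (60) and the consensus size (N = 4)
  are adopted as-is; no sensitivity analysis is performed here.
- Enrichment statistics at desk scale use thousands of poses; binomial
  noise on capture fractions is correspondingly larger than at 10^7
  poses.
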