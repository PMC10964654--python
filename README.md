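# hippo

A histogram-based pseudo-potential for rescoring coarse-grained
protein–ssRNA fragment docking poses.

Single-stranded RNA is disordered when unbound, so docking it onto a
protein (typically an RNA-recognition motif, RRM) proceeds fragment by
fragment: trinucleotides are docked independently, producing pools of
millions of candidate *poses* per receptor–fragment case, of which only
a tiny minority is near-native (ligand RMSD to the bound native below
5 Å). The bottleneck is scoring: picking those near-natives out of the
pool. This package implements a knowledge-based contact potential that
does exactly that, together with everything needed to train, apply and
evaluate it — including a synthetic decoy generator, so the whole
pipeline runs and is tested without any docking engine.

## The potential

Structures are coarse-grained into beads: up to 31 protein bead types
(indexed *i*; 2 backbone + 0–2 side-chain beads per residue) and 17 RNA
bead types (indexed *j*; 1 phosphate + 2 sugar + 3–4 base beads per
nucleotide), up to 527 (*i*, *j*) pairs. For each pair, bead–bead
distances over a labelled decoy pool are counted into 27 right-closed
ranges — (0, 2], 0.25 Å steps over (2, 7], 1.5 Å steps over (7, 14.5],
and (14.5, ∞) — separately for near-native and non-native poses
(column totals `A_ij` and `B_ij`) and separately for three rank-based
sub-pools of the original scoring. Ranges whose near-native count falls
below the signal threshold `w_ij = A_ij / 60` are merged with their
successors until the merged count reaches it. Each refined range *x*
then gets the centred log-odds value

    H_ij[x] = ln d*_x1 − ln d*_x2 − (ln A_ij − ln B_ij)

and a pose is scored by summing, over all pairs and sub-pools, the
values of the ranges its contacts fall into (`S_pose = Σ_i Σ_j R_ij ·
H_ij^T`, linear in the contact counts `R_ij`). The histogram set ℋ of
one training case is a complete scoring parameter set; because a single
ℋ cannot cover the diversity of protein–ssRNA binding modes, several
per-case ℋ are cross-scored on all cases and the *N* = 4 that jointly
cover the most cases form a consensus collection. At application time
each member ranks the pool, the members' top slices are pooled
round-robin into a consensus selection (TopC) of 20 % of the poses, and
scoring a case counts as successful (very successful) when TopC holds
at least 60 % (80 %) of its near-natives — a threefold (fourfold)
enrichment over random selection.

## Worked example

```python
import hippo as hp

cfg = hp.GeneratorConfig(seed=7)            # 300 near-native / 5700 non-native
pool = hp.generate_pool(cfg)                # planted Arg-guanidinium : phosphate
print(f"pool {pool.case_id}: {len(pool)} poses, "
      f"{pool.n_label('near_native')} near-native / {pool.n_label('non_native')} non-native")

h = hp.derive_histogram_set(pool)           # contact at 3.5 ± 0.4 Å
print(f"histogram set: {len(h)} bead-type pairs")

scored = hp.rank_pool(pool, h)
rep = hp.evaluate_selection(scored, pool.labels, fraction=0.05)
print(f"top 5%: capture {rep.near_native_capture:.2f}, "
      f"enrichment {rep.enrichment_factor:.1f}x, success {rep.success}")
```

prints

```
pool SYN7-GCA: 6000 poses, 300 near-native / 5700 non-native
histogram set: 434 bead-type pairs
top 5%: capture 1.00, enrichment 20.0x, success True
```

i.e. the potential derived from the pool's labels recovers every
near-native pose into the top 5 % of its own ranking (capture 1.0 at a
selection fraction of 0.05 is a 20-fold enrichment; the success
criterion is capture ≥ 0.60).

The same machinery is scriptable from the shell: `hippo simulate`,
`hippo label`, `hippo dedup`, `hippo filter`, `hippo derive`,
`hippo score`, `hippo partition`, `hippo split` (see `hippo --help`).

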