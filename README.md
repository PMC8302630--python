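# protokaryo

Reconstruction of pre-polyploidization ancestral karyotypes from modern
gene orders and homology pairs.

Vertebrate-style genome histories — one or two rounds of whole-genome
duplication (1R/2R), possibly a whole-genome triplication, followed by
gene loss and chromosome rearrangement — leave a characteristic
macrosynteny signature: the genes of each ancestral chromosome are
scattered over a small set of descendant chromosomes, and ohnologue
(duplication-born paralogue) pairs concentrate *between* those
descendants.  `protokaryo` turns that signature into a reconstruction:

1. **Segmentation.**  Each scaffold of a duplicated ("post-WGD") genome is
   partitioned into blocks of conserved macrosynteny with a
   Dirichlet-multinomial changepoint model solved exactly by dynamic
   programming, run in two passes (within-clade comparators, then
   outgroups) whose breakpoints are merged.
2. **Mixture inference.**  A probabilistic macrosynteny (topic) model links
   a non-duplicated reference genome to the post-WGD segments: gene *g* of
   reference segment *s* derives from ancestral chromosome *k* with
   responsibility *q*<sub>s,g</sub>(k), inferred by collapsed variational
   Bayes (CVB0) from the counts n<sup>s,g</sup><sub>t,c</sub> of its
   co-orthologues in segment *c* of species *t* (capped at D=4 per
   species).  The ancestral chromosome number K is chosen by a
   hypergeometric enrichment criterion: the reconstruction under which
   paralogue pairs are most improbably concentrated on same-chromosome
   gene pairs wins.
3. **Proto-chromosome refinement.**  Within each ancestral chromosome's
   segment group, significantly paralogous segment pairs must not share a
   descendant chromosome, while orthologous / same-scaffold /
   same-linkage-group segments attract.  After greedy constrained
   clustering, *all* set partitions of the clusters are enumerated
   (restricted growth strings; the unconstrained count is the Bell number)
   and scored by a product of exact hypergeometric tails; the most
   significant partition defines the proto-chromosomes and the
   multiplicity Y<sub>k</sub> of each ancestral chromosome.
4. **Duplication-scenario test.**  Could the observed multiplicities
   converge to a ploidy level M without polyploidization?  Under a null of
   uniform sequential chromosome-scale duplications growing K·N
   chromosomes into Y, the probability
   P(Σ<sub>k</sub>|Y<sub>k</sub> − M| ≤ D | Σ<sub>k</sub>Y<sub>k</sub> = Y)
   is computed *exactly* (rational arithmetic, dynamic program over the
   per-chromosome history counts S(Y₁…Y_K) = (Y₁−N,…,Y_K−N)! ·
   Π<sub>k</sub> Γ(Y<sub>k</sub>)/Γ(N)).
5. **Simulator.**  A karyotype-evolution simulator (polyploidization,
   fusion/fission/translocation, inversion, biased gene loss, noisy
   homology calls) provides ground-truthed synthetic clades so every stage
   is testable at desk scale.

## Worked example

Simulate a clade whose two ingroup genomes went through a
tetraploidization and then a hexaploidization (sixfold duplication in
total, like the lamprey hypothesis), and reconstruct:

```bash
protokaryo run-all --config run.yaml
```

with `run.yaml`:

```yaml
simulation:
  k_anc: 3                  # ancestral chromosomes
  genes_per_chromosome: 80
  branches:
    ref: []                                                # non-duplicated reference
    x: [[tetraploidize], [hexaploidize], [invert, 1.0]]
    y: [[tetraploidize], [hexaploidize], [invert, 1.0]]
  roles: {ref: reference, x: post_wgd, y: post_wgd}
  retention: {ref: 1.0, x: 0.75, y: 0.75}                  # per-copy gene retention
roles: {ref: reference, x: post_wgd, y: post_wgd}
k_range: [3]
out_dir: out
seed: 3
```

Output:

```
chosen K: 3
 ancestral_chromosome  multiplicity  n_genes  fraction
                    1             6      732  0.303861
                    2             6      737  0.305936
                    3             6      700  0.290577
N=1: P = 7.353e-03 (rejected)
N=2: P = 2.020e-02 (rejected)
```

Every ancestral chromosome is reconstructed with multiplicity six — the
tetraploidization × hexaploidization product — and the exact scenario test
rejects both duplication-only nulls: starting from single copies (N=1) or
from an initial doubling (N=2), independent chromosome-scale duplications
reach so tight a convergence on sixfold with probability below 0.05.

The scenario test also runs standalone on a multiplicity vector.  For the
17-chromosome vector (6,5,6,6,7,7,6,6,4,6,8,5,6,4,9,6,6) — total Y=103,
deviation D=13 from M=6:

```bash
protokaryo multiplicity-test --scenario A,B,C
Scenario A: K=17 N=1 M=6 Y=103 D=13  P = 1.822e-09  (rejected)
Scenario B: K=17 N=2 M=6 Y=103 D=13  P = 3.030e-06  (rejected)
Scenario C: K=17 N=4 M=6 Y=103 D=13  P = 2.142e-02  (rejected)
```

Scenario A is duplications with no tetraploidization, B one
tetraploidization then duplications, C two tetraploidizations then
duplications; all fail to explain the convergence at multiplicity six, so
the history must include a triplication (hexaploidization) component.

Other subcommands: `simulate`, `segment`, `fit`, `screen`, `reconstruct`,
`benchmark` — see `protokaryo <cmd> --help`.  The same functionality is
available as a library (`protokaryo.segmentation`, `protokaryo.cvb`,
`protokaryo.reconstruct`, `protokaryo.multiplicity`, ...).

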