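# epifold

Coarse-grained simulation of ligand-binding proteins for studying
**epistasis** — the non-additivity of pair mutations — in a physically
explicit folding model.

The model is an off-lattice chain of point monomers (one bead per
residue). Consecutive beads are linked by harmonic bonds
`U_κ(r) = κ/2 (r − l)²`; non-adjacent beads interact through potentials
built from the unit Morse function
`μ(r) = e^(−2α(r−l)) − 2e^(−α(r−l))`, with an excluded-volume core of
strength ε and a sequence-dependent tail ε′ μν = ε·E μν/E₀ derived from a
threonine-rescaled Miyazawa–Jernigan contact-energy matrix. Chains fold by
Langevin dynamics, are quenched in two temperature steps, and a
single-monomer ligand is docked onto a designated binding site by an
iterative spherical shell sweep. A replica is *active* when every pairwise
distance in its binding complex matches a target geometry within 1 Å, and
the fitness of a sequence is the active fraction over N independent
replicas,

    P = N* / N          (N = 127 by default).

For a pair of mutations the fitness changes ΔP_ν = P_ν − P₀ of the two
single mutants and the double mutant combine into the epistasis statistic

    ε = ΔP₁₂ − ΔP₁ − ΔP₂,

positive when the double mutant is less deleterious than additivity
predicts, negative when it is more. The package implements the whole
pipeline — potentials, Langevin folding of replica ensembles,
reference-fold selection and Lindemann order profiling, shell docking,
fitness, genetic-code-constrained mutation scanning, and the ε statistics
(λ-filters, inter-site distances, error model, distribution widths) — at
configurable scale, from desk-size fixtures to the full published
operating point.

Who it is for: researchers in protein biophysics and molecular evolution
who want a transparent, fully seeded sandbox in which epistatic effects
(including long-range ones, R > 1.5·l between mutated sites) emerge from
folding physics rather than from a fitted statistical model.

## Worked example

Epistasis arithmetic on a published worked example — single-mutant
changes ΔP₁ = −0.61, ΔP₂ = −0.29, double ΔP₁₂ = −0.13:

```python
>>> from epifold import epsilon
>>> epsilon(-0.13, -0.61, -0.29)
0.77
```

A positive ε of 0.77: each mutation alone is strongly deleterious, but
together they fold to a re-configured structure that preserves the
binding site.

A full physical measurement on the shipped 12-mer fixture (16 replicas,
capped 240 ps folding schedule):

```python
from epifold.fixtures import make_fixture
from epifold.fitness import (fitness, apply_mutation, propose_mutation,
                             genetic_code_exchange_matrix)
from epifold import epsilon

fx = make_fixture("minimal-folder", 7)
proto = fx.protocol()
xm = genetic_code_exchange_matrix()
m1 = propose_mutation(fx.sequence, 4, xm, 1)   # L5P, in the binding site
m2 = propose_mutation(fx.sequence, 9, xm, 2)   # S10W, on the surface
p0 = fitness(fx.sequence, proto, 100).P                      # 1.0
p1 = fitness(apply_mutation(fx.sequence, m1), proto, 101).P  # 0.5625
p2 = fitness(apply_mutation(fx.sequence, m2), proto, 102).P  # 0.875
p12 = fitness(apply_mutation(fx.sequence, m1, m2), proto, 103).P  # 0.25
print(epsilon(p12 - p0, p1 - p0, p2 - p0))     # -0.1875
```

The proline substitution inside the binding site halves the active
fraction, the surface tryptophan alone is mild, and their combination is
worse than additive (negative epistasis, ε = −0.19).

The same pipeline is scriptable from the shell:

```bash
epifold fitness --fixture-seed 7 --seed 11
# P: 1.0
# n_active: 16
# n_replicas: 16
epifold scan-pairs --n-pairs 25 --fixture-seed 7 --seed 3 --out records.tsv
epifold report records.tsv --out report   # widths, significance, plots
```

All commands are bit-reproducible for a fixed seed.

## Layout

- `epifold.energetics` — potentials and the contact-energy table
- `epifold.dynamics` — BAOAB Langevin integrator (numba kernels)
- `epifold.folding` — random coils, fold/quench schedule, replica ensembles
- `epifold.structure` — iterative-core alignment, reference fold, order
- `epifold.docking` — shell-sweep docking, activity test, target building
- `epifold.fitness` — P = N*/N, exchange matrix, mutations, selection loop
- `epifold.epistasis` — ε, pair scanning, λ-filter, error model, summaries
- `epifold.pdbio`, `epifold.config`, `epifold.cli`, `epifold.fixtures` —
  multi-model PDB I/O, YAML configs, CLI, deterministic test systems

See `docs/methods.md` for the model, parameter choices and limitations.
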