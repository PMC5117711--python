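# Methods

## The model

A protein is a chain of point monomers, one per residue, with no side
chains, solvent or secondary structure. Three interaction classes define
the energy (all energies in reduced units of k_B·T₀, lengths in Å,
times in ps):

- **Bonds.** Consecutive monomers: `U_κ(r) = κ/2 (r − l)²` with
  l = 3.8 Å and κ = 11 k_B·T₀/Å². The printed stiffness is "11 k_B T₀";
  we read it as 11 k_B·T₀/Å² so the expression is dimensionally
  consistent.
- **Cross-chain pairs** (|i − j| ≥ 2). Built from the unit Morse function
  `μ(r) = e^(−2α(r−l)) − 2e^(−α(r−l))` (α = 2.1 Å⁻¹, minimum −1 at
  r = l), split at r = l into a core part μ^{r≤l} and a tail μ^{r≥l}.
  Attractive pairs (ε′ ≤ 0) use `ε μ^{r≤l} + (ε + ε′)θ(l−r) − ε′ μ^{r≥l}`;
  repulsive pairs (ε′ ≥ 0) use `ε μ^{r≤l} + ε θ(l−r) + ε′ e^(−α(r−l))`.
  Both are continuous with value ε′ at r = l and vanish at infinity; the
  split uses θ(0) = 1 on the r ≤ l component and θ(0) = 0 on the other,
  which is the unique convention making the junction continuous.
- **Sequence dependence.** ε′_μν = ε·E_μν/E₀, where E is the
  Miyazawa–Jernigan contact-energy matrix rescaled with threonine as the
  reference solvent (`E′_ij = E_ij − E_iT − E_jT + E_TT`), E₀ the mean
  |E′| over the upper triangle, and ε = 2 k_B·T₀ the excluded-volume
  strength. The raw matrix ships as a swappable whitespace TSV; after
  rescaling, hydrophobic–hydrophobic pairs are attractive (ε′ < 0) and
  like-charged pairs repulsive, and the threonine row is exactly zero.

The cross-chain potentials have a second-derivative kink at r = l.
This is intrinsic to the split construction; it makes long
zero-friction trajectories lose strict energy conservation when the
junction is crossed repeatedly (a slow random walk of the shadow energy,
a few percent per 10⁴ steps), while on the smooth regions the integrator
conserves to ~0.03 % per 10⁴ steps. Thermostatted runs are unaffected.

## Dynamics

Langevin dynamics with monomer mass m = 1.66×10⁻²² g, friction
γ = 10 ps⁻¹ and step Δt = 0.01 ps. We integrate with the BAOAB splitting
(half-kick, half-drift, exact Ornstein–Uhlenbeck velocity update,
half-drift, half-kick). The published work used a van Gunsteren–Berendsen
integrator; that scheme has several published variants, and any scheme
reproducing the equilibrium statistics at this Δt is equivalent for our
purposes. BAOAB was chosen because it reduces exactly to velocity Verlet
at γ = 0, samples the configurational Boltzmann distribution with O(Δt²)
accuracy, and its free-particle diffusion constant at γΔt = 0.1 is within
0.1 % of k_BT/(mγ). Verified oracles: equipartition of a free monomer,
the stationary variance k_BT/κ of a harmonic bond, and the free-monomer
MSD slope 6k_BT/(mγ).

Velocities are drawn fresh from the Maxwell–Boltzmann distribution at
each stage temperature. Every replica stage has its own RNG stream keyed
by (base seed, replica index, stage), so ensembles are bit-reproducible
and independent of execution order. Non-finite coordinates abort a
replica with the failing step index; coincident nonbonded monomers get a
deterministic capped force instead of a singular one.

## Folding protocol

Each replica starts from a self-avoiding random coil (exact bond lengths,
non-consecutive pairs ≥ 0.8·l apart), folds at T_fold = T₀ = 302.15 K —
below the folding transition, taken as the constant T_f ≈ 1.25·T₀ — and
is then equilibrated for t_q = t_fold/3 at each of T₁ = 218.2 K and
T₂ = 134.3 K. The quench time is read as *per stage*; the source is
ambiguous between per-stage and total, and the per-stage reading is the
more conservative equilibration.

The folding-time estimate is exposed in three variants:
`literal` (N³·e^N·Δt_f, with Δt_f = 10 ps), `sqrt_exponent`
(N³·e^√N·Δt_f, the default) and `fixed` (a user cap). The literal
formula as printed yields ~10¹⁶ ps already at N = 27 and cannot be what
was executed; since the printed rendering has lost radicals, the square
root variant is the default and the literal form is retained for
fidelity. Fixtures use `fixed` caps (hundreds of ps).

## Reference fold and order

The ensemble of N quenched replicas is summarised by a reference
structure x\* and the basin subset ΔΓ\* of the floor(3N/4) members
closest to it. Alignment is iterative-core superposition: least-squares
superposition (improper rotations allowed, so mirror folds match) on the
current matched set, re-selection of the floor(2n/3) closest monomer
pairs, repeated until the matched set recurs (≤ 50 iterations;
oscillations keep the lowest-RMS iterate). Candidates for x\* are the
ensemble members themselves, searched exhaustively (O(N²) alignments);
an averaged non-member reference is conceivable but the member-restricted
search is simpler and reproducible. Ties break to the lowest member
index; all fractional counts use floor().

Per-monomer order is Lindemann-style: rmsf_j over the aligned basin,
ordered when rmsf_j < c·l. The classic Lindemann constant is ~0.10–0.15
of the interparticle spacing; quenched (cold) ensembles justify a looser
default, c = 0.25, exposed in configuration and reported in logs. A
sequence is viable when at least 15 monomers are ordered. No acceptance
check depends on the exact value of c.

## Docking and activity

The ligand is a single monomer. Shells of ~10⁴ near-uniform points
(generalized-spiral construction; centroid norm < 0.01, nearest-neighbour
spacing within a factor 2 of √(4π/n)) are centred on the monomer
centroid and swept from max‖x_i − c‖ + 2l down to min‖x_i − c‖ in steps
of 0.25 Å. At each point the ligand energy is Σ_site μ(r) plus the
excluded-volume core Σ_non-site [μ^{r≤l}(r) + θ(l − r)] = (1 − e^(−α(r−l)))²
for r ≤ l. The shifted, non-negative core matters: the unshifted
μ^{r≤l} is ≈ −1 near contact, which would reward burying the ligand
among arbitrary monomers and make every dock collapse into the densest
pocket; the shift is exactly the pairing used in the chain potentials'
own excluded-volume part. The minimum-energy point over the whole sweep
is the pose.

A replica is active when every pairwise distance within the complex
(site monomers plus ligand) is within 1 Å — inclusive — of the target
state. Target states are built by averaging complex distances over
replicas active under a provisional target; the provisional target
breaks the circularity and in fixtures is derived from the docked
reference fold of a calibration ensemble.

## Fitness, mutations, epistasis

Fitness is the exact rational N\*/N. Mutation proposals are restricted
to amino-acid exchanges reachable by a single nucleotide substitution
under the standard genetic code (the default exchange matrix counts the
codon pairs; a Dayhoff-style 20×20 count file can be swapped in). The
target residue is uniform over the allowed set by default, or
proportional to the exchange probabilities. A minimal single-lineage
selection loop (propose → measure → pluggable acceptance rule) is
provided as a convenience scaffold; reproducing full evolutionary
trajectories is out of scope.

Pair scanning samples unordered distinct site pairs uniformly, measures
P₁, P₂, P₁₂ with independent seeds, and records ΔP_ν = P_ν − P₀,
ε = ΔP₁₂ − ΔP₁ − ΔP₂ and the inter-site distance R in the initial
reference fold (direct interaction when R < 1.5·l, strictly). The
λ-filter keeps records with ΔP₁₂ ≥ λ, or ΔP₁ ≥ λ and ΔP₂ ≥ λ (default
λ = −0.2). Since the single-measurement error δP enters the three
measurements independently, the propagated errors are √2·δP on
ΔP₁ + ΔP₂ and √3·δP on ε; this quadrature mode is the default, with a
literal linear mode (2δP, 3δP) selectable, and the significance
multiplier (default 3) configurable. Distribution widths are Gaussian
MLE fits; ΔP values are stored at full precision and rounded only in
reports.

## Fixtures and what passing tests mean

The deterministic fixtures are 8–12-mers with capped schedules and
reduced replica counts and shell densities, so the full pipeline runs in
seconds to minutes:

- `minimal-folder`: KSKGLLLGKSKS with binding site (4, 5, 6) — a central
  hydrophobic patch in a soluble chain. Its target is rebuilt at
  creation time from a calibration fold keyed to the fixture seed, so no
  coordinates are pinned in source. At the shipped seed its fitness is
  ≈ 1 and stays above 0.5 across seeds.
- `planted-epistasis`: a mock activity protocol whose fitness is 1 only
  when two designated sites are jointly non-wildtype, planting ε = +1 at
  that pair.
- `docking-toy`: a frozen 8-mer coil for grid-oracle comparisons.

These emulate folding funnels, binding geometry and the statistics of
replica-fraction measurements. They do not emulate the size, sequence
diversity, evolved structure or mutational robustness of real evolved
sequences, so passing tests validates the machinery and its statistics,
not biological magnitudes. The full-scale distribution widths
(σ(P) ≈ 0.037, σ(ε) ≈ 0.14) additionally require the original evolved
sequences and ~10³-measurement campaigns; the test suite checks instead
the statistical identities behind them (binomial width of ω(P) at
N = 127, Gaussian σ-recovery on synthetic ε records at σ = 0.14), at
sizes chosen to keep the default suite within minutes.

## Numerical choices

- floor() for all fractional counts (2n/3 core, 3N/4 basin).
- Alignment convergence = recurrence of the matched index set.
- Activity tolerance boundary inclusive (≤ 1 Å).
- Docking shell step 0.25 Å; inner stopping radius = smallest
  centroid–monomer distance ("until the shell lies inside the fold");
  both configurable.
- Degenerate inputs raise typed errors: collinear point sets
  (alignment), zero-normalisation contact tables, empty sweep ranges,
  targets missing complex pairs, exchange rows with no allowed move.
- Seeds: every stochastic entry point takes a seed or Generator;
  derived streams use `SeedSequence([base, index, stage])`.

## Known limitations

- No secondary structure, side chains, solvent or electrostatics beyond
  the contact-energy abstraction; structural conclusions transfer to
  real proteins only qualitatively.
- The literal folding-time law is impractical beyond toy chains; all
  practical runs use the square-root variant or a cap.
- Mirror-image folds are treated as identical (reflections allowed in
  alignment), consistent with the model's achiral potentials.
- The van Gunsteren–Berendsen integrator is represented by an
  equivalent-statistics BAOAB scheme, not reproduced coefficient by
  coefficient.
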