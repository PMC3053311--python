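# Methods

This note documents the models and conventions implemented in `ensdyn`, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical decisions that affect results.

## Structure handling

Structures are read from (multi-model) PDB files via biotite; author residue
numbering, 1-based, is used everywhere, so GroEL domain and helix ranges
(equatorial 1–133 + 409–548, intermediate 134–190 + 377–408, apical 191–376;
helices A 8–27, C 65–85, D 88–107, E 113–134, F 141–152, G 155–169, M
386–409, R 496–514; stem loop 36–51) can be quoted directly. Alternate
locations keep the highest-occupancy conformer. Nucleotide/solvent atoms are
parsed as hetero atoms: excluded from ensembles and contact maps, available
to hydrogen-bond analysis.

Subunit extraction keeps every protein chain with at least `min_length`
residues carrying a Cα (default 500 — co-chaperonin chains at ~97 residues
fall out) and at most `max_missing_fraction` of Cα positions absent relative
to the chain's own residue-number span (default 0.1). The missing-coordinate
threshold is a package convention: the criterion "too much missing density"
is qualitative in crystallographic practice, so the default is deliberately
configurable.

Ensembles are built on the intersection of residue ids present (with Cα) in
every conformer, ascending. Trajectories interchange as multi-model PDB;
frames must share the first model's topology.

## Superposition and the invariant core

Rigid fits are least-squares (Kabsch, SVD with the determinant correction);
batched over frames for trajectory work. Ensemble superposition alternates
fit-to-mean and mean recomputation until the mean moves < 1e-6 Å.

The invariant core is found by iterated peeling: superpose on the current
candidate set, score each candidate residue by the volume of its positional
covariance ellipsoid (product of the square roots of the per-residue 3×3
covariance eigenvalues), remove the single worst residue (ties broken toward
the higher residue id), and stop when the summed remaining volume reaches
`stop_volume` (default 0.5 Å³) or the set reaches an optional size floor.
The procedure is deterministic and invariant to conformer order. On a
GroEL-sized ensemble the threshold localizes the core to a small part of the
equatorial domain; on planted-rigidity fixtures it recovers the rigid subset
exactly (tested over 10 seeds).

## Ensemble PCA

The covariance of Cα positional deviations is taken with the
ensemble-average (1/n) convention and diagonalized exactly (`eigh`).
Consequences: the eigenvalue sum equals the total ensemble variance
(trace identity, asserted to 1e-6 relative), and projecting the source
ensemble gives per-mode score variances equal to the eigenvalues.
Eigenvector signs are fixed by making the largest-magnitude component
positive; exactly degenerate eigenvalues are ordered by the first differing
component — together these make the fit bit-reproducible.

Projections default to `fit=True`: conformers are Kabsch-fitted to the PCA
model's mean structure on the model's core residues before centering on the
model mean, which is the convention for overlaying trajectory frames on an
experimental PC plane (a shared reference frame, not the trajectory's own
mean). For conformers already expressed in the model frame — interpolated
frames, the source ensemble itself — use `fit=False`; the exact round-trip
identity project(interpolate(a)) = a holds only in that mode, because a
re-fit perturbs coordinates at the 1e-3 Å level.

Score tables carry a `density` column (Gaussian KDE, Scott's rule, on the
first two PCs) for density-shaded conformer plots; it is presentation
metadata only.

RMSIP between two models is sqrt((1/n) ΣᵢΣⱼ (vᵢ·wⱼ)²) over the first n modes
(default 10) plus the n×n squared-overlap matrix. For random subspaces the
expectation of RMSIP² is n/3N, which the tests verify by Monte Carlo.

## Trajectory observables

All Cα observables fit frames on the invariant core first (or on all
residues if no core is given), so composited rigid-body motion cannot leak
into internal fluctuations — an invariant the tests exercise explicitly.

**RMSd series** — per-frame all-Cα RMSd to a reference after core fitting.

**RMSF** — per-residue fluctuation about the window mean after fitting
frames to that mean. The default window is the whole trajectory; analyses of
equilibrated segments should pass an explicit frame window (the pipelines
expose `rmsf_window`). Note one systematic: fitting absorbs 6 rigid-body
degrees of freedom, deflating RMSF by ≈ sqrt(1 − 6/3N); at 100 residues this
is a 1% effect, which is why the calibration fixtures use 100-residue
chains.

**Group comparison** — each replicate contributes one RMSF value per
residue; a two-sided Welch t-test across replicates flags residues at
p < alpha (default 0.05, no multiple-testing correction by default,
Benjamini–Hochberg available). The replicate, not the frame, is the unit of
inference: frame-level correlation makes per-frame tests anticonservative.

**Clustering** — agglomerative average linkage (UPGMA, scipy) on the dense
matrix of pairwise best-fit Cα RMSd; cut at `n_clusters` (default 5, in the
range used for chaperonin trajectory analyses). Cluster averages are member
means after fitting to the cluster medoid; the result table reports each
average's RMSd to named reference conformers (the closed/open crystal
structures, in the chaperonin workflow). The implementation is checked
against a hand-written exhaustive O(F³) linkage on every instance up to 30
frames.

**DCCM** — normalized covariances of Cα displacement vectors,
c_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨Δr_i²⟩⟨Δr_j²⟩), after core fitting; zero-variance
residues give NaN rows and a logged warning. With sub-trajectory windows
(e.g. thirds of the run, mimicking 10/20/50 ns intervals), pairs with
|c| ≥ `consistency_threshold` (default 0.5) in **every** window are reported
as consistently correlated — the guard against correlations that are
artifacts of one segment.

**Quasi-harmonic entropy** — at each checkpoint the first n frames are
fitted to their running mean, the mass-weighted Cα covariance
σ = M^½ C M^½ (carbon mass for Cα) is diagonalized, each eigenvalue λ maps
to an oscillator ω = sqrt(k_B T / λ), and the molar entropy is the quantum
harmonic-oscillator sum S = R Σ [α/(e^α − 1) − ln(1 − e^{−α})],
α = ħω/k_B T, at T = 300 K by default. The six smallest eigenvalues
(residual rigid-body freedom) and any mode below 1e-8 Å²·amu are dropped;
very stiff modes contribute nothing (α capped at 500 to avoid overflow,
far past where the contribution underflows). This is the standard
quantum quasi-harmonic estimator; it is length-sensitive by design, which
is what the entropy-vs-checkpoint curve exposes.

Validity regime worth stating: the analytic oracle (entropy from the true
covariance of a prescribed Gaussian) agrees with the estimator only while
fluctuations are small against the geometry, because finite-rotation fitting
distorts the apparent covariance once displacements rival the structure's
smallest principal extent. The 3-atom oracle fixture therefore plants
eigenvalues of 0.006/0.004/0.002 Å² on internal (rigid-orthogonal) modes;
agreement is then ~0.5% at 10⁵ frames against a 2% assertion.

**Hydrogen bonds** — occupancy is the fraction of frames with donor–acceptor
heavy-atom distance ≤ `d_cut` and donor–H–acceptor angle (at the hydrogen)
≥ `angle_cut`. Defaults 3.5 Å / 120° are the package's convention — common
values for protein–nucleotide hydrogen bonding, configurable, and not
claimed to match any particular legacy tool's rule. Hydrogens are taken from
the topology; attachment is inferred geometrically (same residue, ≤ 1.3 Å).

## Contacts and difference contact maps

Residue–residue minimal distances are over heavy atoms (hydrogens excluded —
crystallographic inputs lack them), optionally side-chain-only
(`--sidechain-only` drops N/CA/C/O): published chaperonin contact analyses
describe the map both as "all heavy atoms" and as "side chain contacts", so
both are provided, defaulting to all-heavy. Pairs closer than 4 residues in
sequence are masked.

A contact is a pair with minimal distance < 4 Å; occupancy is the fraction
of conformers in contact; mean distances are over **all** conformers
regardless of contact state (unconditioned means are the only reading under
which a ruptured pair can report a mean-distance change of tens of Å). A DCM
row is emitted when occupancy ≥ 0.5 in exactly one ensemble (unique-contact
classes) or in both with |Δd| ≥ 0.5 Å; Δd = mean_A − mean_B, negative =
closer in ensemble A, with ensemble A the unliganded one by convention.
dcm(A,B) and dcm(B,A) contain the same pairs with negated Δd and swapped
classes; raising either threshold never adds pairs. Grouped panels
(`dcm_xray_panels`) compute one DCM per ordered pair of named state groups
and can flag consensus pairs also present in a simulation-derived DCM.

## Synthetic generators

All generators are pure functions of (spec, seed) — repeated calls are
bit-identical — and return machine-readable ground truth beside the data.
The base geometry is an idealized extended chain (N, CA, C, O, CB per
residue, 3.8 Å Cα spacing by default, configurable) with a small
deterministic off-axis wobble so short Cα subsets are never collinear. No
excluded volume or chemistry is enforced.

- **Linear ensembles** — conformers = base + Σ aᵢvᵢ + ε with aᵢ ~ N(0, ampᵢ²)
  and isotropic (or per-residue) noise ε. Planted modes are random
  orthonormal vectors projected off the rigid-body subspace at the base
  geometry, so superposition leaves the planted variance intact — the
  property that makes eigenvalue/eigenvector recovery a clean test. Default
  study conditions for PCA validation: 500 conformers, amplitudes (3, 1) Å,
  σ = 0.05 Å.
- **Gaussian trajectories** — i.i.d. frames from N(base, Σ) for a prescribed
  3N×3N covariance, optionally composited with random rigid motions to
  exercise fitting.
- **Two-state trajectories** — state B is state A deformed by a random
  internal field rescaled to an exact best-fit Cα RMSd separation; planted
  contact pairs are repositioned side-chain-to-side-chain so the stated
  minimal distances hold exactly in each state, with >1 Å clearance to
  neighboring residues (so exactly the planted pair switches).
- **H-bond trajectories** — a donor/H/acceptor triplet with an exact number
  of qualifying frames (2.9 Å/175° bound geometry vs 5.5 Å broken).

What these do **not** emulate: real protein geometry, anharmonic and
multi-basin dynamics, time correlation within trajectories (frames are
i.i.d.), solvent, or crystal-packing artifacts. Passing tests therefore
demonstrate the correctness and calibration of the estimators under their
own statistical assumptions — not that any particular biological conclusion
would be recovered from real data.

## Study conditions in tests and the acceptance script

Problem sizes were chosen to make each statistical check sharp at desk
scale: 500-conformer ensembles for PCA (eigenvalue sampling error ~6%);
10⁴ frames for the √3σ RMSF calibration on a 100-residue chain (fitting
deflation ≤1%); 6-vs-6 replicates × 300 frames for stabilization detection
(the halved-σ effect is many standard errors); ≤30-frame instances for the
exhaustive clustering cross-check; 10⁵ frames for the entropy oracle. The
acceptance script (`scripts/acceptance.py`) re-runs all of these from a
single command-line seed and reports the measured values; nothing is cached
or hard-coded.

## Known limitations

- mmCIF and BIOMT symmetry expansion are not supported; ensembles assume one
  common sequence (no alignment of non-identical chains).
- DCD reading is not built in; multi-model PDB is the interchange format.
- The entropy estimator shares the usual quasi-harmonic caveats:
  superposition-dependent, length-sensitive, and an upper bound that ignores
  anharmonicity and mode correlation beyond second moments.
- Contact analysis is intra-chain only (single-subunit scope); quaternary
  contacts are out of scope.
- The invariant-core stopping volume is a tunable with no universal value;
  for ensembles of very different size or flexibility it should be
  revisited (the volume trace in `CoreDefinition` is the diagnostic).
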