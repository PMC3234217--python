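# Methods

This note records the model as implemented, the defaults and why they were
chosen, the design decisions taken where the method leaves room, and what
the synthetic test systems do and do not demonstrate.

## Structure model

The protein is a rigid set of Cα beads.  Residue identity is
`(chain, residue number, insertion code)` exactly as the file numbers it;
internally everything runs on a contiguous 0-based index in file order, and
all outputs map back to author numbering.  Only MODEL 1 of a multi-model
file is read (the method is single-conformation); for alternate locations
the highest-occupancy conformer is kept (first on ties).  Residues lacking
a Cα are skipped with a warning.  HETATM ligand heavy atoms (non-water) are
retained separately so sites can be derived as all residues whose Cα lies
within a cutoff of any ligand atom; the default cutoff, 8 Å, matches the
outer edge of the probe attraction well so ligand-derived sites are
commensurate with probe locations.  mmCIF and symmetry expansion of
biological assemblies are out of scope — oligomeric assemblies must be
provided pre-expanded.

## Elastic network and modes

Collective motions come from a Cα elastic network.  Two pair force fields:

- `hinsen_calpha` (default): the distance-dependent Cα pair constant with a
  stiff linear regime below 4 Å (`k(r) = 860·r − 2390` in kJ/mol/Å² with r
  in Å) and an `r⁻⁶` decay beyond (`k(r) = 1.28·10⁶·r⁻⁶`), applied to all
  pairs.  This is the classic parameterization fitted to reproduce all-atom
  low-frequency dynamics from Cα coordinates.
- `cutoff_anm`: uniform unit springs within a cutoff (default 15 Å), kept
  as a structurally simpler cross-check.

Masses are uniform (unit).  Only mode *shapes* are consumed downstream and
the leverage scale is declared arbitrary, so mass weighting and absolute
frequencies are irrelevant; low-frequency shapes are known to be robust
across ENM flavors.  The Hessian assembles `−k·d̂d̂ᵀ` off-diagonal blocks
with diagonal blocks enforcing exact block-row sums of zero (translational
invariance).  Full dense diagonalization is used; the Fourier-basis
approximation for very large assemblies is out of scope.

Modes with eigenvalue below `1e-8 ×` the largest are discarded as trivial —
six for any non-collinear structure (five for a collinear one, which loses
a rotation).  The next `n_modes` (default 10, the standard working set for
this analysis) are kept ascending, unit-normalized, with the sign fixed so
the largest-magnitude component is positive; degenerate eigenvalues are
ordered by index.  This makes results reproducible across linear-algebra
backends.

## Probe docking

The probe is a chain of `probe_size` pseudo-Cα atoms with fixed 3.8 Å
bonds (the canonical virtual Cα–Cα spacing).  Probe–protein and non-bonded
probe–probe interactions follow the square well: distances below 4.5 Å are
forbidden, and every probe-atom/residue pair between 5.5 and 8 Å
contributes −ε with ε = 1, which defines the energy and temperature unit.

Each simulation is an annealed Metropolis chain.  One move per step, drawn
uniformly from rigid translation (±1.5 Å per axis), rigid rotation about
the probe centroid (±0.4 rad), or an internal pivot of the chain tail about
a random bond (±0.4 rad) — a minimal ergodic set for a chain with fixed
bond lengths; a one-atom probe uses translations only.  Temperature follows
a geometric schedule from `t_start` (default 2.0) to `t_end` (default 0.2).
The probe starts as an extended chain with random orientation, centered at
a uniformly random point on a sphere 10 Å outside the structure's bounding
radius (re-drawn in the rare event of an initial clash), and a reflecting
spherical wall at bounding radius + 15 Å bounds the simulation region.
The wall is essential: without it a probe that detaches during a warm phase
random-walks away irrecoverably (three-dimensional diffusion is transient),
which biases the sampled locations toward whatever surface the probe first
touched.  The wall acts only in move acceptance; the potential itself is
the pure square well.

The endpoint's interacting residues — those within the attractive well
[5.5, 8] Å of any probe atom — form the probe location.  The neutral band
[4.5, 5.5) is not counted as interacting; the attraction well is the only
interaction definition the model gives.  Locations with empty residue sets
are dropped (logged).  All randomness derives from a master seed through
per-simulation SeedSequence streams, so runs are reproducible and
independent of scheduling; the whole per-run random stream is drawn up
front and consumed by a compiled (numba) Metropolis loop.

Annealing protocols trade equilibration against throughput.  The default
short anneal (2.0 → 0.2 over 5 000 steps) freezes probes near where they
first bind, which is the desired behaviour for *covering* the surface with
redundant candidate sites.  Finding the global energy minimum (e.g. a deep
pocket) requires a warm protocol (≈ 3.0 → 1.0 over 100 000 steps) during
which probes can roll along the surface and escape shallow minima before
the quench; with it, the majority of probes on the single-pocket test
system end in the pocket.

## Binding leverage

For a probe location P, springs (spring constant k = 1; the overall scale
is arbitrary) connect residue pairs of P whose Cα–Cα segment passes within
`pass_radius` of at least one probe atom.  "Passes through the ligand" has
no unique geometric reading for a point-set ligand; the point-to-segment
distance threshold, default 2.0 Å, is explicit and configurable.  The
leverage of P under mode μ is

    L_Pμ = Σ_springs ½ k (d̂_ij · (v_j − v_i))²,

the first-order (linearized) change of spring lengths under the mode
displacement field.  Linearization makes rigid translations and
infinitesimal rotations carry exactly zero leverage and absorbs the
arbitrary mode amplitude into the overall scale; it is the natural choice
for normal-mode vectors, which represent infinitesimal motion.  The
quadratic spring form is the standard harmonic strain energy.

Per-residue leverages average over the redundant locations:
`λ_iμ = Σ_P Δ_iP L_Pμ / Σ_P Δ_iP`, with `Δ_iP` the membership indicator;
residues never covered by a probe location get λ = 0.  The mode–mode
profile overlap `Λ_μν = Σ_i λ_iμ λ_iν` and its cosine normalization rank
which modes carry leverage and whether two modes involve the same sites.

## Coupling

`ℓ_P` is the mean λ row over a site's members (set size as the norm).
`D_PQ = ℓ_P·ℓ_Q`; `C_PQ = D_PQ/√(D_PP·D_QQ)`, which the nonnegativity of λ
confines to [0, 1]; sites with zero self-coupling get C = 0 by convention.
The normalization is taken in cosine form — the stated range and `C_PP = 1`
force it up to monotone equivalence.  `D_Pi` treats each residue as a
singleton second site.  The background is the mean of `λ_i·λ_j` over
unordered pairs (i < j, self-pairs excluded) of residues outside all
annotated sites; residues with zero docking coverage participate with λ = 0
(they dilute the background) — this pairwise-mean reading of "average
coupling between the residues not belonging to any sites" is a recorded
interpretation.  Single-mode matrices `D^(μ) = L_Pμ L_Qμ` are rank ≤ 1 and
sum exactly to D over modes (bilinearity), a useful identity check.

Because leverage units are arbitrary and structure-specific, only
comparisons within one run are meaningful: site couplings against the
background, C values against each other.

## Synthetic test systems

`make_toy_two_mode_system` builds an ~84-bead globule (jittered cubic
lattice trimmed to a ball) with four pockets carved along tetrahedral axes
(channel radius 5.2 Å, depth 7 Å) and two designed orthonormalized
displacement fields with angular-Gaussian (σ = 30°) falloff: "green" moves
site X radially outward and Z inward; "red" applies a tangential elliptic
deformation at X and closes Y; W is untouched.  Amplitudes make X the most
deformed site under both modes.  Site membership combines distance to the
pocket centre (≤ 8 Å) with a 45° angular gate about the pocket axis so
that core beads reachable from other pockets are not mislabeled.  The toy
injects these designed modes directly, bypassing the elastic network on
purpose: the coupling formalism is mode-agnostic, and this isolates
docking + leverage + coupling from ENM idiosyncrasy.

`make_pocket_structure` places beads on concentric Fibonacci shells
(spacing ≈ 4.6 Å within a shell, 4.4 Å between shells, 0.15 Å jitter) so
the control surface is smooth and convex, then carves one cylindrical
pocket (mouth radius 6.2 Å) of the requested depth.  The smooth surface
matters: on a rough lattice surface, grooves bind the probe nearly as well
as the pocket and no pocket preference can be measured.  The pocket-centre
probe position is the axis point seeing the most beads inside the
attraction well without clashes; the lining is everything within 8 Å of
it, and the convex control set is the outer shell of the opposite
hemisphere.

`make_random_ca_chain` is a self-avoiding random walk with 3.8 Å steps and
a 4.0 Å exclusion between non-adjacent beads, used for geometry oracles
and round-trip tests.

What passing tests show: the pipeline's algebra (λ, D, C, decompositions,
backgrounds) is exact; rigid motions carry zero leverage through the full
stack; probes preferentially locate a deep concavity; and the designed
two-mode communication pattern is recovered from docking + leverage alone
in ≥ 9 of 10 seeds.  What they do not show: that elastic-network modes of
a real protein describe its functional motions, that real binding sites
are pockets of this idealized shape, or anything about side-chain-mediated
regulation — the Cα square-well model has no side chains, so e.g.
allosteric effects driven by local side-chain rearrangement are invisible
to it by construction.

## Problem sizes and numerical choices

Test and acceptance runs use 84–100-bead systems, 100–200 simulations of
5 000–100 000 steps, and 2–10 modes; these sizes give stable statistics
for every property checked while keeping a full run in the tens of
seconds.  Key tolerances: zero-mode threshold `1e-8 × λ_max`; mode
orthogonality asserted at 1e-8; rigid-mode leverage at 1e-10; exact-algebra
identities at 1e-12.  Degenerate inputs are defined explicitly: constant
B-factor fields write 0.00 with a warning; zero-leverage sites get C = 0;
empty probe locations are dropped, and a run where all probes end unbound
is an error suggesting longer runs or a lower final temperature.

## Known limitations

- The docking temperature protocol, move set, and initialization are this
  package's choices; the underlying method does not prescribe them, and
  pocket-capture statistics depend on the protocol (see above).
- Springs are restricted to residue pairs within a probe location, and the
  spring constant is uniform; no physical force constants.
- The background average treats all non-site residues equally, including
  never-covered ones (configurable by excluding zero-coverage residues).
- Statistical significance of couplings is not assessed; D and C are
  descriptive quantities to be compared within a single structure.
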