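# Methods

## Model and assumptions

The head is modeled as a heterogeneous, isotropic, linear-elastic solid:
white matter (WM), gray matter (GM), cerebrospinal fluid (CSF) and skull,
each with its own Young's modulus E, density ρ and Poisson's ratio ν.
CSF is treated as a soft, nearly incompressible elastic *solid* — a
common simplification that ignores its fluid nature (no flow, no
fluid–structure interaction). Damping, viscoelasticity, plasticity and
geometric nonlinearity are all outside the model: the analysis is the
undamped free-vibration eigenproblem ([K] − ω²[M]){φ} = 0 over linear
(constant-strain) tetrahedra.

Units are mm / ton / s throughout, so E is in MPa, ρ in ton/mm³
(1 g/cm³ = 1e-9 ton/mm³), the eigenvalues ω² come out in s⁻², and
f = ω/2π is in Hz with no conversion factor.

## Synthetic phantom geometry

Anatomical meshes are replaced by layered phantoms: concentric
quasi-ellipsoidal shells voxelized on a regular lattice, each cell split
into six Freudenthal tetrahedra (face-conformal across neighboring
cells). Defaults: shell outer radii 40/50/55/60 mm (WM/GM/CSF/skull,
i.e. a 5 mm skull shell), axis ratios (1.0, 0.92, 0.85) to make the body
head-like rather than spherical, 6 mm target edge length (~2×10⁴
elements), and a seeded node jitter of 0.1% of the outer radius. The
ellipsoidal axes plus jitter split the eigenvalue degeneracies a
symmetric body would have, so mode-by-mode comparison is well posed.

A label-repair pass enforces the nesting WM ⊂ GM ⊂ CSF ⊂ skull that
coarse voxelization can violate where the 5 mm CSF band is thinner than a
cell: any WM cell face-adjacent to CSF/skull/outside is promoted to GM,
then any GM cell face-adjacent to skull/outside to CSF. The layering —
not anatomical realism — is what the heterogeneity experiments depend
on.

Boundary node sets: `base` (nodes within 0.75 edge lengths of the lowest
skull z-extent), `base_back_sides` (exterior nodes below the 0.35 z
quantile, behind the 0.25 y quantile, or outboard of the 0.80 |x|
quantile — the scanner-cushion contact patch is pictorial in the source
material, so the sectors are config-exposed), `exterior` (boundary-face
nodes), and `cylinder_base` (far end of an attached neck/spine
cylinder). Neck (120 mm) and spine (500 mm) cylinders are voxelized on
the phantom's own lattice, hugging the staircase of the skull bottom, so
the joint is conformal by construction; the cylinder length is padded by
the jitter amplitude so the advertised length is a guaranteed lower
bound. GM-surface nodes (shared between GM and CSF elements) are
parceled into n_parcels = 16 near-equal solid-angle sectors by
nearest-direction assignment to a spherical Fibonacci lattice; parcels
stand in for cortical regions when projecting mode shapes.

What the phantom does *not* emulate: gyrification, ventricles, real CSF
thinness, anatomical asymmetry. Consequently absolute eigenfrequencies
are phantom-specific; all experiments assert trends, exact laws and
in-print arithmetic, never published absolute frequencies.

## Assembly and boundary conditions

Element stiffness is the exact integral V·BᵀDB of the constant-strain
tetrahedron with D built from λ = Eν/((1+ν)(1−2ν)), μ = E/(2(1+ν)).
Element mass is consistent by default — (ρV/20)(1+δᵢⱼ) per direction —
with a row-sum lumped alternative (`mass="lumped"`); consistent mass is
the conservative default for eigenfrequency accuracy on linear
tetrahedra. Dirichlet conditions are applied by row/column elimination
(never penalties), which keeps M positive definite and requires no
parameter tuning. "Fixed" means all three translational DOFs;
per-direction fixing is supported.

Near-incompressibility: the published CSF value ν = 0.4999 makes plain
displacement tetrahedra lock volumetrically, biasing frequencies upward.
The experiment layer caps ν at 0.49 by default (`nu_cap`), with
`nu_cap=None` restoring the faithful value; benchmarks against closed
forms are run at ν ≤ 0.3 where locking is absent.

## Eigensolution

Shift-invert Lanczos (ARPACK `eigsh`) about σ = 0 for constrained
systems; for free-free systems σ = −10 s⁻², safely below the six
rigid-body zero eigenvalues, so the factorized operator is never
singular. The Lanczos start vector is seeded, making runs deterministic;
eigenvector sign is fixed by displacement normalization (largest-
magnitude entry scaled to +1). Eigenvalues below 1e-12 of the spectral
scale are clipped to zero before taking square roots. Residuals
‖Kφ − ω²Mφ‖ are checked against 1e-6 relative to ‖Kφ‖ plus the spectral
scale (the additive term keeps the criterion meaningful for rigid-body
modes where Kφ ≈ 0). A failed factorization retries with perturbed
shifts before raising.

Numerical cross-checks built into the test suite: dense full-spectrum
agreement to 1e-8 relative on systems ≤ 600 DOFs; fixed-free bar
fundamental axial frequency against (1/4L)√(E/ρ) within 3% with error
decreasing under refinement (the axial mode is identified by MAC against
the analytic quarter-wave shape, since bending and torsion modes lie
below it); exactly six near-zero modes for a free body; M-orthogonality
and Rayleigh-quotient consistency.

## Mode comparison

MAC is the squared normalized dot product (scale- and sign-invariant);
pairing maximizes total MAC via the Hungarian algorithm with a disclosed
threshold (default 0.5) below which pairs are dropped; NRFD divides by
the reference-model frequency (first argument). Cross-mesh comparison is
restricted to scenario meshes derived from one phantom, which share node
coordinates exactly; shapes are compared on the shared brain (WM/GM/CSF)
DOFs with skull/appendage DOFs excluded. Quantitative MAC between
unrelated meshes is deliberately unsupported.

## Experiments

* **Complexity** — heterogeneous (E_WM 0.03103, E_GM 0.01537, E_CSF
  0.299 MPa) vs homogeneous (0.02320 MPa) on the identical
  skull-stripped mesh, exterior fixed; reports paired/unique modes.
* **Boundary conditions** — skull-base, neck (120 mm), spine (500 mm),
  fMRI-style cushion patch, and skull-stripped/exterior-fixed, all with
  the reference material set (E brain 0.497, CSF 1.314, bone 8000 MPa;
  neck/spine carry bone properties); reports cross-scenario MAC/NRFD, a
  distinct-mode-shape count at the disclosed threshold, and checks that
  the fundamental frequency falls as the fixed boundary moves away
  (skull → neck → spine).
* **CSF sweep** — E_CSF over {2.19, 1.314, 0.299, 0.1485, 0.012, 0.001}
  MPa against the 2.19 MPa reference, under high (E_GM 0.01537 / E_WM
  0.03103 MPa) and low (0.001389 / 0.001895 MPa) brain-stiffness
  scenarios, skull fixed at 6000 MPa; the sweep's boundary condition is
  not specified in the source material, so skull-base fixation (the first
  scenario) is used. Softening a region can only remove stiffness, so
  ordered eigenfrequencies are non-increasing along the sweep
  (Courant–Fischer); the experiment asserts this and the monotone growth
  of the fundamental-mode NRFD.
* **Stiffness ratio** — the exact form of the ratio finding: scaling
  every region's E by one factor c leaves K → cK, hence every eigenvalue
  scales by c exactly — mode shapes invariant (MAC = 1) and frequencies
  multiplied by √c. Mixed pairs with approximately equal brain/CSF
  ratios (high-stiffness brain + 12 kPa CSF vs low + 1 kPa; high + 1 kPa
  vs low + 0.1 kPa) are reported descriptively as MAC-band counts.

Experiments default to ~10⁴-element phantoms and 25 modes; the test
suite uses 8–12 mm edge lengths and fewer modes, sizes chosen so each
property remains sharply testable at interactive run times. `run_all`
writes a manifest with a configuration hash, seed and library versions;
identical specs reproduce identical reports.

## Synthetic BOLD generator and LEiDA pipeline

The generator emulates one statistical property of resting-state
recordings: recurring instantaneous phase-locking states. All regions
share a narrowband carrier (0.05 cycles/sample); the timeline is divided
into dwell periods (Poisson, mean 25 samples — at least one carrier
cycle, so every state recurs many times in a 2000-sample series). Each
period is the global in-phase state (probability 0.5) or one of K−1
anti-phase states in which a designated region subset runs π out of
phase. Subset patterns are drawn with pairwise |cosine| ≤ 0.75 so the
states are genuinely distinct regimes. Gaussian noise (default SD 0.2 on
unit-amplitude carriers) is added; states, patterns and phases are
recorded as ground truth. Not emulated: hemodynamic response,
1/f spectra, scanner artifacts, anatomy — so passing recovery tests
demonstrates correctness of the extraction pipeline, not performance on
real fMRI.

Extraction: per-region instantaneous phase from the analytic signal
(after demeaning); per-timepoint phase-alignment matrix
A_ij = cos(θ_i − θ_j) (the standard LEiDA choice); its unit-norm leading
eigenvector, sign-flipped so most components are negative (ties broken
by component sum, then first component); k-means (seeded, 20 restarts)
into K = 8 clusters; centroids unit-normalized, occupancies as timepoint
fractions. Eigenmodes are bridged to this space by projecting the mean
signed radial displacement of GM-surface nodes per parcel, z-scored;
matching uses |cosine| (sign-invariant, since eigenvector sign is
arbitrary) with optimal assignment. This quantitative eigenmode-vs-
empirical-mode comparison is an extension beyond the visual comparisons
in the source material; no published number depends on it. The
frequency scales of the two families (tens of Hz mechanical vs ~1 Hz
hemodynamic) are reported side by side and deliberately not reconciled.

## Numerical choices and degenerate inputs

Degenerate (non-positive-volume) tetrahedra raise with the element
identified. Empty node sets are rejected at constraint time (silently
constraining nothing would leave rigid-body modes). A fully constrained
system is representable (`n_free = 0`) and refuses to solve with an
explicit error. Zero-variance signals are rejected with the region
named. Empty parcels are rejected. Z-scoring a constant parcel vector
returns zeros. Repeated eigenvalues are reported in ascending order with
index tie-breaks; phantom asymmetry plus jitter makes exact repeats
unlikely, and MAC-based pairing absorbs residual subspace rotation.

## Known limitations

Linear elasticity only; solid CSF; voxel (staircase) boundaries rather
than smooth anatomy; no damping, so mode lifetimes are out of reach;
parcels are geometric sectors, not functional networks; absolute
frequencies are not comparable across meshes or to anatomical models;
locking at ν = 0.4999 is mitigated by the ν cap, not eliminated.
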