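# Methods

This note documents the models, conventions, numerical choices, and known
limitations behind `memthick`. It is written for users who need to judge
what the analyses (and the tests that validate them) do and do not show.

## Coordinate model and conventions

All internal lengths are Å; GRO files (nm) are converted only at the I/O
boundary. The membrane normal is fixed to the z-axis — systems are assumed
pre-aligned, as is standard for bilayer simulations, and no normal
estimation is attempted. Boxes are orthorhombic; triclinic input is
rejected explicitly. Bead indices are 0-based internally; residue ids keep
file numbering, and residue-range selections (e.g. loop exclusions for
RMSD) are inclusive on both ends, matching the `resid a-b` idiom of MD
selection languages. Note that published loop-exclusion selections are
often quoted against renumbered residues; this package always interprets
ranges against the numbering present in the input file, so users must
supply ranges in that frame.

Roles (`protein_backbone`, `lipid_phosphate`, `water`, …) are a pure
function of (atom name, residue name) under a configurable naming
convention whose defaults cover Martini CG (`BB`, `PO4`, `W`) and all-atom
PDB (`CA`, `P`, `HOH`/`SOL`) names. Multi-frame GRO files are parsed
block-by-block with line-numbered errors; multi-MODEL PDB I/O goes through
MDAnalysis, with the CRYST1 record additionally parsed directly because a
header-level CRYST1 preceding the first MODEL is outside every frame's
record range for per-frame readers. PDB writes of >99,999 atoms follow
MDAnalysis's serial-overflow policy; atom counts round-trip regardless.

## Synthetic bilayer generator

The generator emulates the *geometry* of a protein-thinned bilayer, not
its physics. Each lipid is a single phosphate-like headgroup bead on a
jittered square lattice (default area per lipid 64 Å², box 150 Å — a 15 nm
cube); the two leaflets mirror one another at ±T(ρ)/2 where

    T(ρ) = T_win + (T_bulk − T_win) · (1 − exp(−max(0, ρ−r_p)² / (2 w²)))

is a smooth radial funnel around the protein axis: exactly `T_win` at the
protein surface (ρ = r_p), recovering `T_bulk` far away. The deformation
shape is a modeling choice — any smooth monotone interpolation supports
recovery testing; a Gaussian decay is the minimal such model. The decay
width defaults to w = 25 Å so that the thinned zone is nearly flat across
the 6 Å annulus the TM-window cutoff samples (the planted funnel adds
< 0.3 Å mean bias over that shell), emulating a thinned patch wider than
the selection shell. Vertical Gaussian noise (default σ_z = 1 Å) emulates
thermal undulations; frames carry independent noise by default, with an
optional AR(1) mode for autocorrelation-sensitivity studies. The protein
is a static cylinder of backbone beads placed by a golden-angle spiral.

Lipid species names are apportioned by largest remainder from an ER-like
10-species composition (DYPC:YOPC:POPI:PYPI:DYPE:YOPE:ERGO:YOPA:YOPS:POPS
= 42:28:21:14:10:10:7:6:6:6); a single-species mode mirrors POPC control
membranes. Every species — including the sterol — carries a `PO4`-named
headgroup bead; this is a deliberate simplification (sterols have no
phosphate) that keeps the phosphate selection coextensive with the lipid
count.

What the generator does **not** emulate: lipid tails and order parameters,
curvature coupling, lipid exchange dynamics (positions are redrawn, not
propagated), flip-flop, protein flexibility, and electrostatics. Passing
recovery tests therefore demonstrates that the *analysis chain* is
unbiased and correctly calibrated on known geometry — not that any real
membrane behaves this way.

Band-intensity tables use multiplicative lognormal noise with unit mean
and a chosen coefficient of variation (default 0.1, a typical densitometry
repeatability), applied independently to cleaved and full-length bands.
With cv = 0 the planted cleavage percentage is recovered exactly; at small
cv the expectation bias of the ratio is far below a percentage point.

## Density profiles and maps

Number density only (matching phosphate-bead counting): per-frame z
histograms divided by slab volume, averaged over frames; bin width
defaults to 1 Å. The integral over bins times bin volume equals the
selected bead count exactly per frame, which the tests assert. 3-D maps
are frame-averaged voxel histograms; optional Gaussian smoothing uses
periodic boundaries and therefore conserves the integral to float
precision. Profiles are reported raw — no per-leaflet normalization or
symmetrization. Coordinates are used as emitted (membrane-centered);
the default profile range is the centered box extent, and supplying an
explicit `z_range` restores translation equivariance for shifted systems.

## Thickness estimation

The TM window is a **dynamic** selection: phosphates within the cutoff
(default 6 Å, boundary inclusive) of any protein bead, re-evaluated each
frame, since headgroups exchange in and out of the window. An exhaustive
all-pairs distance computation is kept in the test suite as the oracle for
the KD-tree implementation.

Fits minimize unweighted least squares of ΣA_k exp(−(z−μ_k)²/2σ_k²) over
the profile (density-weighted residuals are available as an option; the
choice matters little for well-separated peaks). Initialization takes the
two outermost local maxima (5 % prominence) as leaflet seeds and, for the
3-component fit, seeds the third at their midpoint; amplitudes are bounded
non-negative and σ below by a quarter bin. Non-convergence is reported via
a flag, never silently; profiles with fewer than 2K+1 nonzero bins or
fewer than two detectable peaks raise an initialization error naming the
profile.

Thickness is the separation of the two outermost component means — the
only reading that reduces to the two-Gaussian bulk case. One numerical
guard: components whose fitted amplitude falls below 1 % of the largest
are excluded first. When a 3-component model is fitted to a profile with
no mid-plane population, the superfluous component collapses to ~zero
amplitude and its mean becomes unconstrained by the data; without the
floor, such vestigial components corrupt the outermost rule. The floor is
far below any physically meaningful leaflet amplitude.

Replicates aggregate as mean ± SEM (n−1 sample SD over replicate means);
frames within a replicate are autocorrelated in real data, so per-frame
SEMs are never reported. Unconverged replicates are excluded with a
warning rather than failing the aggregate; a single replicate reports
SEM 0 with a warning. Differences between thickness estimates propagate
SEMs in quadrature — note that quadrature on per-variant SEMs of 0.54 and
0.16 Å gives ±0.56 Å, which is the package's reported uncertainty for a
3.0 Å difference.

## Geometry

Superposition is Kabsch SVD with the determinant guard (always a proper
rotation); collinear selections are rejected. The test suite checks it
against an independently implemented Horn quaternion method. RMSF
superposes each frame to the ensemble mean by default (two fixed-point
iterations starting from frame 0 — ample for rigid-plus-noise ensembles);
the no-superposition mode exists chiefly because isotropic jitter then has
the closed form RMSF → σ√3, used as an analytic calibration. With
replicate ensembles, the profile is the across-replicate mean with the
across-replicate SD as the error bar.

Helix axes use endpoint centroids: mean backbone position of the first
and last `n_end` residues (default 3) of a user-supplied residue range
(no secondary-structure detection). For an ideal helix of radius r and
twist 100°/residue, a 3-residue centroid sits (1+2cos100°)/3·r ≈ 0.22r
off-axis; the resulting axis tilt is atan(2·0.22r·|sin(Δφ/2)|/L) where Δφ
is the end-to-end phase mismatch — under 1° for typical TM helices and
exactly zero when (n−3)·100° ≡ 0 (mod 360°). The tests assert this closed
form. Crossing angles are arccos of normalized dot products, reported in
[0, 180]° with an optional fold to [0, 90]° when helix directionality is
not meaningful. Helix span uses the canonical α-helical rise of
1.5 Å/residue (span = n × 1.5); no alternative rise conventions are
applied.

## Cleavage statistics

Cleavage % = cleaved·100/(cleaved+full) is scale-invariant, matching
arbitrary densitometry units. Profiles report mean ± sample SD (n−1) per
N-length. Comparisons run per-point two-tailed two-sample t tests —
pooled-variance or Welch–Satterthwaite — with the inclusive star ladder
(* ≤ 0.05, ** ≤ 0.01, *** ≤ 0.001, **** ≤ 0.0001). No multiple-testing
correction is applied by default, matching common practice for per-point
profile tests; a Holm-adjusted column is reported alongside the raw
p-values for transparency, never replacing them.

The null calibration study (`welch_type1_calibration`) simulates pairs of
identical-truth lognormal band tables and measures the rejection rate at
α = 0.05. It uses 6 replicates per group, where the Satterthwaite
approximation is accurate (measured rate ≈ 0.046 at 10⁴ simulations). A
known limitation: at the 3 replicates typical of pulse-labeling
experiments the Welch test is intrinsically conservative (rejection rate
≈ 0.034 even for exactly normal data), i.e. real n = 3 comparisons err on
the cautious side.

## Validation study and problem sizes

`run_validation` generates three systems — protein-free bulk at 38.1 Å,
a wild-type-like window at 20.1 Å, and a trimer-like window at 23.1 Å
(both inside a 38.1 Å far-field bilayer) — with 5 replicates × 100 frames
× 200 lipids/leaflet each, σ_z = 1 Å. These sizes give sub-0.1 Å SEMs
while keeping the whole study under a few seconds on one CPU; recovery is
scored against |bias| ≤ 0.5 Å (CLI-exposed). Per-replicate seeds fan out
from one global seed through `numpy.random.SeedSequence(seed, system,
replicate)`, so identical configs produce byte-identical reports.

## Known limitations

- The generator validates analysis correctness, not membrane physics
  (see above); in particular the third Gaussian component is exercised by
  constructed mixtures, not by an emergent deep-phosphate population.
- Dynamic window selection assumes the protein selection is meaningful in
  every frame; there is no contact-lifetime analysis.
- No XTC/TRR/DCD binary trajectories, no topology parsing, no
  area-per-lipid/curvature/order-parameter analyses, and no leaflet
  asymmetry metrics.
- Helix span uses a uniform 1.5 Å/residue rise; experimental estimates
  for specific helices can deviate from n × 1.5.
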