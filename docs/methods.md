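# Methods

## Model and assumptions

The package treats a nucleic-acid duplex as a chain of rigid bases
whose relative geometry is captured by 12N−6 coordinates: six
intra-basepair coordinates per pair (shear, stretch, stagger, buckle,
propeller, opening) and six base-pair step coordinates per junction
(shift, slide, rise, tilt, roll, twist), interleaved as pair 1,
step 1, pair 2, …, pair N. Helical coordinates (X-disp, Y-disp,
h-rise, inclination, tip, h-twist) are used only as derived
quantities for global length/twist analysis. The free-energy cost of
a deformation is assumed harmonic, E = ½(w−ŵ)ᵀK(w−ŵ), with
K = kB·T·Σ⁻¹; all anharmonicity, multistate behavior (kinks,
bubbles, non-canonical structures) and phosphate-level detail are
outside the model.

Sequence dependence is assumed hexameric: a step's equilibrium values
and stiffness are fully determined by the surrounding six base pairs,
a pair's by the surrounding seven (the heptamer value is the mean of
its two constituent hexamers). This is a sliding-window model — no
context effects beyond the window are representable, by construction.

## Strand-flip (parity) algebra

A duplex has no preferred strand. Reading the molecule from the other
strand reverses pair/step order and negates the odd coordinates
(shear, buckle, shift, tilt, Y-disp, tip); groove widths and all
stiffness constants are even. For stiffness matrices this transform
is the orthogonal signed permutation B ↦ SPBPᵀS, which preserves
symmetry and spectrum. Parameters for non-canonical k-mers (canonical
= lexicographic minimum of {s, revcomp(s)}) are *always derived*, never
stored, so complement consistency is exact. Self-complementary
contexts are symmetrized by averaging a record with its own
complement transform, which makes the odd central coordinates (and the
odd–even couplings of the central-step block) exactly zero — stored as
literal zeros, not ≈0.

## Sequence design

The minimal-covering-sequence designer extends a seeded random start
one letter at a time, accepting only letters whose new k-mer window
covers an unseen reverse-complement class, and restarts from a fresh
seeded state on a dead end. For odd k there are no self-complementary
k-mers, every class has two members, and the search reaches the
optimal length 4^k/2 + k − 1 within a few dozen restarts (k = 5:
516 bp covering all 512 pentamer classes exactly once, well under a
second). For even k the self-complementary classes make dead ends
frequent; after a bounded number of exact attempts the designer falls
back to a greedy cover that permits duplicated classes and reports
them — producing a shortest-possible even-k sequence is explicitly not
attempted. Partitioning into synthesis-sized oligomers tiles the
sequence with stride core_len − (k−1), right-aligns the last core so
no window is lost, and caps each core with GCGC on both ends to
isolate end fraying; caps are excluded from censuses and fitting.

## Synthetic parameter generator

The generator emulates the *structure* of an MD-derived hexamer
parameter deposit so the pipeline is testable end to end. What it
emulates: complete coverage of all 2080 hexamer classes; central-step
means anchored to published crystallographic/MD dinucleotide averages
(e.g. AT step: slide −0.71 Å, rise 3.24 Å, twist 30.70°) plus a
smooth, seeded, zero-mean context perturbation on the scale of the
observed hexameric variability (e.g. ±1.5° twist); intra-basepair
means and groove widths anchored to the sequence-averaged helix
values (DNA minor groove 12.04 Å, propeller −11.03°; A-RNA slide
−1.64 Å, roll 8.83°); per-coordinate stiffness constants with
realistic magnitudes (buckle by far the softest rotation,
<0.01 kcal/mol/deg²); and symmetric positive definite 66×66 blocks
with distance-decaying couplings, built as √D·C·√D with C a
correlation matrix of the form AAᵀ (A = I + 0.12·G, G decaying with
coordinate-position distance), on the nondimensional scale and then
converted to mixed units. RNA dimer anchors are a synthetic stand-in:
the sequence-averaged A-form values plus mild per-dimer offsets
within the printed variability.

What it does **not** emulate: genuine MD covariance structure
(couplings are generic, not physical), sequence-specific groove
patterns such as A-tract narrowing, anharmonicity, or any kinetics.
Tests passing on synthetic parameters therefore demonstrate the
correctness of the *machinery* (transforms, assembly, estimation,
geometry) and of anchored averages, not the biological accuracy of
any particular prediction.

Determinism: each canonical hexamer uses `default_rng([seed, code])`
with `code` the base-4 encoding of the sequence, so tables are
byte-identical across runs and independent of iteration order.

## Stiffness assembly and spectral repair

Assembly places each window's 66×66 block at its slice and averages
overlapping entries arithmetically (multiplicity 1–6). The assembled
matrix can have near-zero or negative eigenvalues; repair replaces
eigenvalues of the *nondimensionalized* matrix (1 Å translations,
11° rotations) below λc with λc, keeping eigenvectors — the minimal
perturbation achieving min eig ≥ λc. Defaults λc = 0.48 (DNA) and
0.44 (RNA) are applied per assembled sequence. After repair the
matrix is trimmed back to the hexameric band by default (off-band
entries introduced by the repair are small), and the result is
redimensionalized so energies can be evaluated in raw coordinates;
the cutoff-free and untrimmed variants are available behind flags.
The definiteness of a truncated band is re-checked and reported,
since truncating interactions to too narrow a band can make a matrix
indefinite.

## Maximum-absolute-entropy banding

Given a sample covariance Σ, the banded precision estimate adds the
inverses of the diagonal hexameric covariance blocks and subtracts
the inverses of the 54-coordinate overlap blocks of adjacent
hexamers, then multiplies by kB·T. This is the decomposable
Gaussian-graphical-model (junction-tree) identity with hexamer slices
as cliques and adjacent-pair overlaps as separators: the implied
covariance (K/kBT)⁻¹ reproduces Σ exactly on every in-band entry and
maximizes entropy off the band. Only adjacent-pair overlaps enter the
subtraction even though entries can belong to up to six blocks.

## Frame geometry

Step ↔ frame conversions use the mid-step triad composition (the
3DNA-style convention): the step rotation is
Rz(Ω/2−φ)·Ry(Γ)·Rz(Ω/2+φ) with Γ = √(tilt²+roll²), φ = atan2(tilt,
roll), and the displacement (shift, slide, rise) expressed in the
mid-step frame. The helical twist of a step is the signed rotation
angle about the step's rotation axis (axis oriented toward +z of the
local frame) and the helical rise is the displacement projected on
that axis; when the rotation angle is numerically zero the axis is
undefined and the documented limit h-rise = |d·ẑ|, h-twist = 0 is
used. Extraction of step coordinates from frames inverts this
decomposition, wrapping the twist into (−180°, 180°] and restoring
the matching bend phase (the atan2 branch cut otherwise shifts the
twist by 360° and flips tilt/roll). Round trips are exact to 1e−8.

## Global elasticity and persistence fits

Global length l = Σ h-rise (Å) and twist ω = Σ h-twist (rad). The
1D (relaxed) constants are Y = kB·T·l₀/var(l), reported in pN via
1 kcal/(mol·Å) = 69.479 pN, and C = l₀/var(ω), reported in nm; the
twist–stretch coupling k = cov(l,ω)/var(ω) (Å/rad) is reported in
nm/turn via the factor π/5. Positive k means overtwisting lengthens.
The 2×2 rod stiffness is Krod = kB·T·l₀·Σrod⁻¹, whose entries are
material constants (length-independent).

Persistence lengths are fit semilog: log of the correlation ratio
against the mean contour distance l_i0, unweighted least squares over
all separations i = 1…24 by default (configurable); the prefactor α
absorbs a non-unit intercept. The equilibrium structure is factored
out of the bending correlation (t̂ᵢ·t̂₀ in the denominator), so an
intrinsically bent but fluctuation-free duplex gives ratio ≡ 1 and an
unbounded persistence length (reported as infinity, never as a fake
large number). Non-positive ratio values are excluded from the fit
and reported. Static disorder uses random-sequence equilibrium
structures as virtual snapshots with the sequence-averaged structure
as reference; defaults (400 sequences × 150 bp) are scaled-down,
configurable choices that keep the estimate stable at interactive
cost.

## Threading energies

Template threading constrains a per-step subset (default roll, twist,
slide — the step coordinates conserved among nucleosome structures)
to template values while all other coordinates relax: the effective
stiffness is the Schur complement K_cc − K_cf·K_ff⁻¹·K_fc of the
local window's repaired stiffness, and E = ½ΔᵀK_effΔ with Δ the
template-minus-predicted means. Windows extend two pairs left and
three right of the template's steps so every constrained step has a
full hexameric context.

## Ensemble analysis choices

Snapshot filtering drops a snapshot if any watched Watson–Crick
H-bond heavy-atom distance exceeds 4 Å; the watched range defaults to
all pairs except the outermost pair at each end (the outer caps).
Opening events are maximal runs of broken snapshots; single-snapshot
escapes count. The survival fit of ln S(t) needs a window because the
curve is nonlinear at short times and ill-defined at long times: the
window is user-specified or auto-selected as the longest stretch
whose straight-line fit reaches R² ≥ 0.98 (scanned on a ≤60-point
decimated grid, fit on all support points inside; flagged as
auto-selected in the output). Duplicate hexamers during block
extraction: the first occurrence wins, and the maximum deviation
between duplicates is reported. Half-trajectory convergence errors
follow εa = ½(|x₁−x_full| + |x₂−x_full|), εr = εa/|x_full|.

## Numerical conventions

kB = 1.987204×10⁻³ kcal/mol/K, T = 300 K. Angles are degrees at the
API surface and radians internally where geometry requires; ω is
radians. Gaussian sampling uses the Cholesky factor of K (solve
Lᵀx = z), failing loudly on non-SPD input. Uncovered end positions
are NaN in profiles (never silently filled); the mean-vector builder
fills them from the terminal hexamer windows because frame
reconstruction and energies need complete vectors, and says so in its
docstring. Matrices are re-symmetrized (½(M+Mᵀ)) after transforms
that are symmetric only up to round-off.

## Problem sizes used in tests

Rod Monte-Carlo closed forms use 10⁵ snapshots × 25 steps; end-to-end
parameter recovery 1.5×10⁵ snapshots of an 8 bp duplex; max-entropy
banding identities random SPD systems of 6–10 bp; opening-time
recovery 10⁴ synthetic events. These sizes give Monte-Carlo errors
comfortably below the asserted tolerances (relative errors of a
covariance entry scale as √(2/n)) while keeping the default suite
fast.

## Known limitations

- No context effects beyond the hexamer/heptamer window; banded-
  inverse long-range propagation is deliberately not implemented.
- The synthetic generator's couplings are generic; quantitative
  predictions require an externally fitted parameter set loaded via
  `parameter_io.load_parameter_set`.
- Even-k minimal sequence design is best-effort, not optimal.
- Groove widths are carried as per-context scalars; no atomic P–P
  measurement from structures is performed.
- The survival-fit auto-window is a heuristic; for publication-grade
  lifetimes supply the window explicitly.
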