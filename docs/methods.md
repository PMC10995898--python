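# Methods

## Wrapping energetics

The mechanics module weighs the Helfrich bending cost of completely
engulfing a DNA nanostructure against the adhesion gained from cholesterol
anchors inserting into the bilayer. Assumptions: the membrane is a
tensionless fluid sheet with bending modulus κ (default 25 kBT, a standard
value for cell membranes); spontaneous curvature, membrane tension, line
tension and thermal fluctuations are neglected; only the fully wrapped end
state is priced, not the wrapping pathway. Adhesion is strictly additive,
x kBT per inserted cholesterol (default x = 13).

Closed forms per shape:

* **Sphere** — mean curvature 2/R over area 4πR² gives 8πκ, independent of
  radius.
* **Rod** — modelled as a spherocylinder. `rod_length` is the tip-to-tip
  particle length (the dimension one measures on a micrograph), so the
  cylindrical body contributes πκ(L−2R)/R and the two hemispherical caps
  together contribute 8πκ.
* **Tile** — flat faces bend nothing; the rim is wrapped as a half-cylinder
  of radius t/2 swept along the perimeter P = 2(w+h), giving πκP/t.
  Corner (Gaussian-curvature) terms are ignored: this is the leading-order
  plate-wrapping cost. Default thickness t = 2 nm (a single duplex layer).

Orientation (horizontal/vertical) is carried as metadata on the anchor
model. It changes which anchors can reach the membrane, not the
full-engulfment bending cost; `n_accessible` defaults to `n_anchors` —
the upper bound on adhesion, which makes the infeasibility conclusion
conservative — and configs may restrict it per orientation.

The integer anchor threshold is the ceiling of E_bend/x with an
exact-division guard (a threshold within 1e-9 of an integer is that
integer), and feasibility ties (E_adh = E_bend to 1e-12 relative) count as
feasible, so the threshold anchor count is feasible by construction.

The closed forms are verified in the test suite against an independent
surface-quadrature oracle that rebuilds mean curvature numerically from
finite-difference fundamental forms of each parametrized surface and
integrates (κ/2)(c1+c2)² by trapezoidal quadrature; agreement is required
within 1% (observed: <0.01%).

## Uptake quantification

Pipeline order: background subtraction → channel integration. Background
is a flat per-image value (measured autofluorescence when the experiment
provides it, otherwise estimated as the median of the lowest-decile
pixels — a robust floor estimate); subtraction clips at zero. Subtraction
precedes the top-hat because the opening of a *noisy* flat offset tracks
local minima rather than the offset itself, so an unsubtracted offset
leaks into the punctate sum; the top-hat's exact offset invariance holds
only for noise-free constant offsets.

Surface signal is the plain whole-frame sum (epifluorescence,
population-level; no per-cell segmentation). Internal signal is the sum of
the white top-hat (image minus its morphological opening) with a disk of
radius 5 px by default — large against diffraction-limited puncta
(σ ≈ 1.5 px), small against cells. Internalization efficiency
I_int/(I_int+I_surf) is a consistent cross-condition metric, not a
physical internalized fraction, and the two channels (different
fluorophores) are never summed together; channel roles are enforced by the
API. Fold changes divide group means by a control-group mean and keep
per-replicate normalized values for statistics.

## Intranuclear quantification

Nuclei: Otsu threshold on the counterstain, connected components,
border-touching nuclei removed (truncated denominators bias per-cell
ratios), each component eroded by 2 px by default so ROIs sit slightly
inside the nuclei, components under 50 px dropped. Per-nucleus readout is
DN intensity inside the ROI over ROI area; the image summary is the mean
over nuclei.

Per-cell efficiency divides intranuclear by whole-cell DN intensity. Cell
regions are assigned by a watershed from the nuclear seeds on the distance
transform, restricted to a cell mask. The mask is supplied, or derived
from the surface-ring channel (Otsu, closing, hole filling); a watershed
over the DN-channel foreground itself was rejected because puncta are
sparse and their foreground disconnected. Because each ROI is a subset of
its cell region, the ratio is structurally in [0, 1].

## Gel densitometry

A lane profile is the per-row sum over the lane's column window. The
baseline is a 1-D morphological opening of width 50 px (wider than any
band: a σ = 6 px Gaussian band has ~36 px support, and the opening's
leakage into such a band is <0.1% of its mass), subtracted and clipped at
zero. Band windows are supplied per lane — standard densitometry practice
is to hug each band, about ±4σ — with exactly one `intact` band; the
stability readout is the intact integral over the total band integral,
which cancels loading and concentration differences. SNR for a lane is
quoted at pixel level: band peak pixel amplitude over per-pixel noise sd.

## Synthetic data

The generator emulates the study's imaging conditions: 512×512 px frames
at 200 nm/px; eight well-separated elliptical cells (semi-axes 7×5 µm,
nuclei 3.6×2.8 µm, random orientation); a membrane ring with Gaussian
cross-section (σ 1.5 px, peak 1000 a.u.); 20 unit-mass Gaussian puncta per
cell (σ 1.5 px, 2×10⁴ integrated a.u. each) of which
`round(nuclear_fraction · count)` are placed well inside the nucleus
(≥6 px from its boundary) and the rest in the cytoplasm clear of the
nuclear boundary (≥4 px margins), so the programmed intranuclear fraction
is realized exactly up to rounding; a filled nuclear ellipse at 600 a.u.;
a flat background offset of 4 counts with Poisson noise (Gaussian and
noise-free models available). Ground truth (per-channel integrated
signals, per-cell internal and intranuclear totals) is recorded before
offset and noise. Gels are 1-D Gaussian band mixtures spread across
60 px lanes on a gently tilted baseline, fractions recorded pre-noise.
Group tables use mean-preserving multiplicative lognormal noise
(σ² = ln(1+cv²)).

Every generator is a pure function of (spec, seed) with one local RNG
stream. Not emulated: optics (PSF, bleed-through), flat-field
inhomogeneity, cell-to-cell brightness variation, touching cells, and
autofluorescence texture — so passing recovery tests demonstrates
correctness of the computational pipeline under its stated model, not
robustness to every real-microscope artifact.

With the default conditions, the residual of clipped noise over the empty
frame area bounds recovery accuracy: observed errors are ~4% on integrated
surface/internal signal (10% tolerated), ≤0.01 absolute on intranuclear
fraction (0.03 tolerated), and ≤2% on band fractions at pixel SNR 10
(3% tolerated). Test problem sizes (3 images per group, 1000 ANOVA null
replicates, 5-point efficiency sweeps) keep each stage's check to seconds
while leaving Monte-Carlo error well inside those margins.

## Statistics

One-way ANOVA from sums of squares with the F tail from scipy; degenerate
inputs are flagged with warnings (all-constant data → F = 0, p = 1; zero
within-group variance with differing means → F = ∞, p = 0). Tukey HSD
uses the studentized range (Tukey–Kramer under unbalance) via
`scipy.stats.tukey_hsd`. Significance tiers use inclusive thresholds:
p ≤ 0.05 `*`, ≤ 0.01 `**`, ≤ 0.001 `***`, otherwise `ns`. No correction
beyond Tukey is applied. Replicate tables carry both image and experiment
identifiers so either unit of replication can be analysed.

## Known limitations

* The wrapping model prices only complete engulfment; partial-wrapping
  landscapes, membrane tension and active processes are out of scope.
* The morphological internal-signal extractor is a declared stand-in for
  unpublished pipeline details, validated on synthetic ground truth only.
* Automatic nuclear/cell segmentation replaces manual ROI selection; on
  real confocal data the erosion radius and area floor may need retuning.
* Whole-frame sums assume a flat, single-valued background; structured
  autofluorescence would need a spatially varying background model.
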