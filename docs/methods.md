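# Methods

## The model

A maxilla (upper bill) is idealised as a two-layer solid of length
L = 5 cm aligned with +z (base → tip), x the width axis and y the depth
axis. The cross-section at height z is a superellipse
|x/a(z)|^p + |y/b(z)|^p = 1 with p ≥ 2 (p = 2 is an ellipse; larger p
gives boxier, more convex sections). The half-axes taper by a power law
from their base values to `tip_scale` (default 0.2) of those values at
the tip, so the tip keeps a small loadable face:

    a(z) = (width/2) · [tip_scale + (1 − tip_scale)(1 − z/L)^m_w]

and likewise for b(z) with exponent m_d. The outer layer (rhamphotheca,
keratin) has thickness t at the base; the interface to the inner bony
core is the superellipse with half-axes (a − t, b − t), which makes the
thickness exact on the principal axes and approximately t elsewhere (the
error is second order in the section's eccentricity; a true normal-offset
curve can self-intersect at high p, which this choice avoids). The
thickness tapers in proportion to the local section scale,
t(z) = t·min(a, b)/min(a₀, b₀), keeping the bony core strictly positive
along the whole bill. All geometry is SI metres.

Materials are homogeneous, isotropic, linear elastic: keratin
E = 6.5 GPa, bone E = 12.7 GPa, ν = 0.4 for both; densities (1000 and
50 kg m⁻³) are carried as metadata only — the analysis is static. Three
material assignments are compared on identical meshes: the natural
composite (keratin shell, bone core) and the two homogeneous controls.

**Loading regimes.** Impact: all basal nodes fixed; a net force of 10 N
in −z is distributed over the outer surface within the apical 5% of the
length, weighted by lumped nodal area, summing to the total exactly.
Torsion: the apical 5% surface patch is fixed and the basal nodes receive
the small-rotation displacement field u = (−θ(y−c_y), θ(x−c_x), 0) of a
twist θ = 1.75 mrad about the +z axis through the centroid of the bony
core's base (the small-angle error is O(θ²) ≈ 3·10⁻⁶ relative). The
performance metric for both is the **peak nodal von Mises stress** on the
rhamphotheca surface in a measurement zone at two-thirds of the length
from the base — far from both boundary-condition regions.

**Beam analogue.** The same bill reduced to a solid elliptical cantilever
of half-width a and half-depth b: impact performance is the critical
buckling stress σ_cr = P_cr/(πab) = π²Eb²/(16L²) with Euler's load
P_cr = π²EI_x/(KL)², K = 2 (fixed–free column), I_x = πab³/4; torsion
performance is the maximum surface shear of the twisted elliptical shaft,
τ_max = 2T/(πab²) with T = πGθa³b³/((a²+b²)L), which simplifies to
τ_max = 2Gθa²b/((a²+b²)L) — the π cancels. (A published combined form of
this expression retains a stray factor π that is inconsistent with its
own two ingredients and with the circular-shaft limit Gθr/L; the
self-consistent form is used here. A constant factor is immaterial for
every rank-based statistic downstream.) The formula's maximum-location
condition b < a is not enforced: bills with depth exceeding width are
evaluated with the same expression, a documented caveat. σ_cr is
independent of a, so depth alone protects against buckling, while τ_max
grows with both axes — together these generate the impact/torsion
tradeoff along any morphospace axis where width and depth increase
together.

## Finite elements

4-node linear tetrahedra (Tet4), standard constant-strain assembly, with
per-element isotropic elasticity matrices; the two material regions share
interface nodes (a perfect bond — the desk-scale equivalent of tied
elastic contact, whose high-penalty limit is the bonded solution).
Dirichlet conditions are applied by elimination; the reduced system is
solved by sparse LU with a conjugate-gradient fallback (relative
tolerance 1e-8), and the residual is checked after every solve. Element
stresses are constant per element; nodal von Mises values are
volume-weighted averages over adjacent elements, and the zone peak is
taken over nodes (element peaks are noisier under Tet4). Verified
properties include the patch test (uniform-strain boundary data reproduce
constant stress to solver tolerance), exact work balance, linearity,
frame invariance, a hand-assembled single-element oracle, and analytic
fields: uniaxial prism stress F/A (within 1%), circular-shaft torsion
surface stress √3·Gθr/L (within 5%), cantilever tip deflection vs
PL³/(3EI) (within 8% — Tet4's bending stiffness bias converges slowly,
which is the known cost of linear tetrahedra and the reason production
analyses of this kind use very large meshes).

**Meshing.** The mesher is structured: rings of nodes around the axis
(core rings to the material interface, shell rings to the surface, counts
tied to the circumferential resolution), extruded along z. Wedge and
hexahedral cells are split into tetrahedra by a smallest-global-index
rule that triangulates every shared face identically on both sides, so
the mesh is watertight and conformal across the material interface by
construction, with no randomized (Delaunay) step. Axial levels are laid
out between fixed stations — the measurement-zone centre (2L/3) and the
tip-patch edge (0.95L) are mesh levels at every resolution — with a
torsional-compliance-weighted density (0.6 uniform / 0.4 proportional to
1/J(z), per-segment counts allocated by weight mass so the density is
continuous across stations). This layout is self-similar under
refinement. It matters: without fixed stations the effective clamp extent
and the averaging neighbourhood at the zone jump discontinuously between
refinement levels, and the convergence harness oscillates by ±20% —
the compliant thin tip (J ∝ taper⁴) dominates the torsional response, so
small inconsistencies there are amplified.

**Measurement zone.** The zone centre is at two-thirds of the axial
extent; the default half-width is 0.5% of L, i.e. effectively the node
ring guaranteed at the centre station. A wider band (configurable) spans
a systematic ~19% stress gradient at the default taper and makes the
in-band peak depend on which mesh levels happen to fall inside — a
resolution artefact, not a physical difference.

**Convergence.** The harness refines axially with the cross-sectional
discretization fixed, so the (constant) cross-section error cancels
between levels while the axial profile — the slowly converging direction
for both regimes — is refined; the default ladder is
(n_axial, n_circ) = (10..40, 16), roughly 1.4× elements per level. On the
default bill both regimes fall below the 5% convergence threshold by the third level
and stay there with shrinking steps. The production-scale meshes of
µCT-based studies (hundreds of thousands of elements) are deliberately
out of scope; the coarse tier used throughout is the one verified by this
harness.

## The synthetic clade

A pure-birth (Yule) tree with two monophyletic sister subclades of 7 and
8 tips, joined at the root and scaled to unit height, emulates a
two-family clade of 15 species. Log bill width, log depth and log body
length evolve by correlated Brownian motion: root dimensions 14 × 16 mm
(a mid-sized bill at the 5 cm length convention), rates 0.04 per unit
height for the dimensions (≈ ±40% spread at 2 sd — a morphospace wide
enough to span narrow/shallow to wide/deep), width–depth correlation 0.7
(the axes co-evolve, as they do in real bills), body length 22 cm with
rate 0.03 and correlation 0.6 to both dimensions. Shell thickness is 10%
of the smaller base dimension — a realistic rhamphotheca fraction that
always satisfies the core-positivity invariant. All stochasticity flows
through one seeded generator.

What the generator deliberately does *not* emulate: bill curvature (the
tomial axis is straight, so "length" is the axial extent), scan noise and
segmentation artefacts, trabecular microstructure (the core is a solid
endocast), and real measured covariances between species. Passing tests
therefore demonstrate that the method recovers the geometric tradeoff and
composite advantage when they are present, not that any particular real
clade exhibits particular magnitudes; printed statistics from scan-based
specimens are not reproduction targets here.

## Statistics

- **Spearman:** average ranks for ties; two-sided p by full permutation
  enumeration for n ≤ 10 (the permuted-vector norm is invariant, so the
  enumeration reduces to dot products), t approximation otherwise.
- **PGLS under Pagel's λ:** C is the shared root-to-MRCA path-length
  matrix; C(λ) multiplies off-diagonal entries by λ ∈ [0, 1]. λ̂
  maximizes the profile log-likelihood on a 101-point grid refined by
  bounded scalar optimization (the result is within 1e-3 of the fine-grid
  argmax). The slope test uses the GLS standard error with n − 2 degrees
  of freedom; R² is computed against the GLS intercept-only model at the
  same λ and adjusted with the (n−1)/(n−2) factor — a documented
  convention, since implementations differ. Likelihood-ratio tests of the
  bounds use a χ²₁ reference halved at the boundary; when λ̂ itself sits
  on the tested bound the p-value is 1. λ = 0 reduces exactly to OLS, and
  λ = 1 equals the independent-contrasts regression through the origin —
  both are test oracles.
- **Wilcoxon signed-rank:** zero differences dropped; exact null by
  subset-sum enumeration over (doubled, hence integer) tied average ranks
  for n ≤ 25; normal approximation with continuity and tie corrections
  above.
- **Phylogenetic paired t-test:** differences d are modelled with mean μ
  and covariance σ²C(λ). σ² and λ are estimated by REML; the test
  statistic is μ̂ over a Kackar–Harville-corrected standard error (the
  naive GLS variance understates uncertainty when covariance parameters
  are estimated) with Satterthwaite degrees of freedom capped at n − 1.
  On a star tree this reduces exactly to the ordinary paired t-test.
  Monte-Carlo calibration at n = 15 under a Brownian null puts the
  type-I error at the 5% level between 0.05 and 0.08 across tree shapes;
  the uncorrected plug-in t (λ by ML, naive SE) measured 0.12–0.15 and
  was rejected on those grounds.

## Tunable parameters (defaults)

| parameter | default | meaning |
|---|---|---|
| `length` | 0.05 m | common length all bills are scaled to |
| `base_width`, `base_depth` | 16, 20 mm | default-bill base dimensions |
| `shell_thickness` | 1.5 mm | rhamphotheca thickness at the base |
| `section_exponent` | 2 | superellipse exponent (2 = ellipse) |
| `tip_scale` | 0.2 | tip half-axes as a fraction of base |
| `loads.F` | 10 N | impact tip force (−z) |
| `loads.theta` | 1.75 mrad | prescribed base twist |
| `geometry.n_axial`, `n_circumferential` | 20, 16 | pipeline FE tier |
| `tip_fraction` | 0.05 | loaded/clamped apical surface fraction |
| `zone_center_fraction` | 2/3 | measurement-zone centre |
| `zone_half_width_fraction` | 0.005 | zone half-width (see above) |
| `clade.n_species`, `split` | 15, (7, 8) | clade shape |

## Degenerate inputs and tie-breaks

Shell thickness ≥ half the smaller base dimension, non-positive
dimensions, taper exponents ≤ 0 and superellipse exponents < 2 are
rejected at construction. A zero-width measurement band errors unless a
node ring sits exactly at the centre. Zero twist returns an identically
zero field. In the Wilcoxon test, all-zero differences are an error; in
the paired t-test, (near-)constant differences are. Inverted elements
abort assembly with the element index. Scaling a zero-extent or
zero-area mesh is rejected.

## Known limitations

Linear statics only (no transient impact dynamics, contact, or material
nonlinearity); Tet4 elements are stiff in bending, mitigated by the
convergence harness rather than higher-order elements (Tet10 is the
natural extension point); the PLY ingestion route re-meshes by radial ray
casting and therefore requires surfaces star-shaped about the +z axis
(an external tetrahedralizer can be plugged in for general surfaces);
absolute stress values depend on the tip-force distribution and clamp
extent, which are modelling conventions — only comparative statements
across species and material modes are claimed.
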