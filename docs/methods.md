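# Methods

`ssmrec` virtually reconstructs the intact shape of a fractured hemipelvis
from the surfaces of its fracture fragments, using a statistical shape model
(SSM) learned from intact training anatomy. This note documents the models,
the numerical choices, and what the synthetic test bed does and does not
demonstrate.

## Pipeline

1. **Preprocessing** (`ssmrec.mesh`). Fragment surfaces are remeshed to a
   uniform edge length, closed ("wrapped"), merged into one segmentation,
   and mirrored when needed so that every shape is expressed as a left
   hemipelvis. All coordinates are millimetres.
2. **Correspondence** (`ssmrec.registration`). A template mesh is deformed
   onto each target surface by non-rigid ICP, producing a fixed-topology
   point set: vertex *i* denotes the same anatomical location on every
   shape.
3. **Shape model** (`ssmrec.shape_model`). PCA over corresponded intact
   training shapes yields a mean shape, orthonormal modes and per-mode
   variances; 15 components are retained by default.
4. **Reconstruction** (`ssmrec.reconstruction`). The model is fitted to the
   merged fragments by alternating registration and masked subspace
   projection; missing regions are interpolated by the model.
5. **Evaluation** (`ssmrec.evaluation`). Whole-surface and region RMSE,
   per-vertex distance maps, and six plate-fitting parameters measured on
   66 landmark vertices transferred by correspondence.

## Non-rigid ICP

The template deforms onto the data (template -> target), which is what makes
fitting *partial* shapes possible: template vertices without data support
are carried by regularisation alone and flagged invalid.

Per stiffness level `alpha` the displacement field `d` minimises

    sum_i w_i |d_i - delta_i|^2 + alpha |L d|^2

with `delta_i` the closest-point offset, `L` the degree-normalised graph
Laplacian of the template and `w_i in {0,1}` a correspondence gate. A
correspondence is rejected when it is farther than `max_corr_dist` (default
10 mm — fragments displaced beyond this must not drag the template), when
surface normals disagree by more than `max_normal_angle` (default 60°,
compared against smoothed per-face normals), or when it lands on a face
touching an open boundary of the target (rim correspondences around holes
are spurious). The stiffness anneals over `[100, 50, 20, 10, 5, 2]` with 10
correspondence/solve rounds per level. Rigid pre-alignment uses
point-to-plane ICP (Kabsch warm-up, then Gauss–Newton on the se(3)
increment), which converges orders of magnitude faster than point-to-point
updates on smooth sliding surfaces.

The sparse system is refactorised only when the gate pattern changes
substantially; otherwise the previous factorisation preconditions a few CG
iterations (the matrix difference is a ±1 diagonal of small support). The
pipeline is deterministic: KD-tree queries and linear solves only.

**Identifiability limit.** Surface-to-surface registration observes
geometry, not material points: the tangential component of a deformation is
only pinned down by curvature features, so recovered correspondence drifts
tangentially by roughly 5–15% of the deformation amplitude depending on the
field's spatial gradient. Point-to-plane data terms and warm restarts do
not reduce this (the tangential modes are nearly flat directions of the
regularised objective; we verified both experimentally). In the clinical
workflow both the reconstruction and its contralateral comparator pass
through the same registration, so this drift largely cancels in reported
RMSEs, but synthetic ground-truth comparisons of raw correspondence show it
in full.

## Shape model and reconstruction

PCA uses a thin SVD of the centred `n x 3V` data matrix (the `3V x 3V`
covariance is never formed); variances use divisor `n - 1`. No Procrustes
scale normalisation is applied: plate-fitting needs true millimetre
dimensions, so alignment is rigid only. Masked projection solves the
least-squares problem restricted to observed vertices and clamps each score
to ±3 standard deviations of its mode (configurable; a standard
plausibility constraint).

Fracture reconstruction alternates (registration -> masked projection ->
synthesis) from the mean shape, up to 5 outer passes or until the mean
coordinate change drops below 0.1 mm. The first pass runs the full
stiffness schedule; later passes start from an instance already close to
the data and run only the final three levels. The alternation converges
geometrically (roughly a factor 5 per pass): a single pass underestimates
mode scores by 20–30% because closest-point correspondences from a distant
template are biased toward it, while 3–5 passes recover the scores of
in-subspace shapes to below 1%.

Fragments are used where they lie; no automatic repositioning is attempted.
The correspondence gate makes a fragment displaced beyond `max_corr_dist`
effectively invisible (equivalent to deleting it), but a fragment displaced
*within* the gate injects systematically offset data that the fit follows —
under masked least squares, wrong data perturbs the solution considerably
more than absent data, since the model interpolates missing regions well.
Reconstructions supported by less than 25% of template vertices trigger a
warning: accuracy degrades noticeably beyond that much missing data.

## Clinical parameters

Regions are defined once as vertex indices on the template (12 + 12 + 8 +
4 + 30 = 66 landmarks) and transferred by correspondence, so all
measurements are automatic. The "radius" of a bony line is the curvature
radius of the best-fit circle through its ordered landmarks: points are
projected onto their total-least-squares plane, an algebraic Kåsa fit is
refined by geometric Gauss–Newton. The acetabular diameter is twice the
radius of the circle through its four landmarks. The quadrilateral slope is
the dihedral angle between the landmarks' total-least-squares plane and the
plane orthogonal to the superior–inferior reference axis, folded into
[0°, 90°] (normal parallel to the axis gives 0°). The plate-fitting region
RMSE pools all 66 landmarks into a single number; per-region RMSEs are
available for diagnostics. Group summaries are median with IQR (linear
interpolation between order statistics); two-group comparisons use a
Mann-Whitney U test, exact for tie-free pooled samples of at most 12,
otherwise the normal approximation with tie and continuity corrections.

## Synthetic test bed

No patient data ships with the package; `ssmrec.synthetic` generates the
study conditions.

* **Template**: a deterministic, stylised closed surface (anisotropic
  ellipsoid, semi-axes 40/35/45 mm, with smooth feature lobes, a flared
  upper wing, a lateral cup dent and a flattened medial patch). Landmark
  geometry is *constructed*: cross-sections carrying the line landmarks are
  blended to exact circles of known radius, the quadrilateral patch is
  flattened onto a plane of known 55° tilt placed where the surface normal
  matches the plane normal, and the 66 landmark vertices are snapped
  exactly onto this geometry after a smooth neighbourhood blend (so no
  spiky triangles appear). The six clinical parameters therefore have
  machine-precision ground truth.
* **Population**: each training shape is the template plus a linear
  combination of smooth, band-limited (80 mm wavelength), mutually
  orthogonal deformation fields applied along vertex normals, with mode
  standard deviations 6/3/1.5 mm of RMS vertex displacement by default.
  Scores are drawn once and then centred, orthogonalised and rescaled so
  the cohort's sample covariance over the modes is *exactly* the nominal
  diagonal — the population realises its specification instead of carrying
  O(1/sqrt(n)) sampling error. Each shape additionally receives a 1 mm-RMS
  idiosyncratic smooth field (anatomy outside any finite mode basis);
  without it, model-generated targets are perfectly reconstructable at any
  deletion level and accuracy would not degrade with missing data at all.
  Normal-direction fields are used because surface variation of bone is
  predominantly a normal-direction effect and purely tangential variation
  is unobservable from surface geometry.
* **Fractures**: random planes partition the closed surface into connected
  pieces; pieces totalling approximately the requested fraction of surface
  area are deleted (greedy largest-first selection; the achieved fraction
  is reported), and remaining fragments are optionally displaced rigidly
  within stated bounds. The intact shape is kept as ground truth.

**What passing tests show — and what they do not.** The synthetic anatomy
is stylised: it has no cortical/trabecular structure, no segmentation
noise, no articulating neighbouring bones, and its variation modes are
smooth and low-rank by construction. Passing the suite demonstrates the
correctness and numerical behaviour of every pipeline stage under known
ground truth — not clinical accuracy on real CT segmentations, which
depends on data the package does not ship.

## Problem sizes and defaults

| Quantity | Default | Rationale |
| --- | --- | --- |
| Template resolution | 2562 vertices (`subdivisions=3`) | matches a 1.5 mm-remeshed hemipelvis within ~2x |
| Isotropic remesh target | 1.5 mm | uniform vertex density for PCA |
| Training cohort | 40 shapes, 3 modes (6/3/1.5 mm) | small enough to run everywhere, rich enough to test recovery |
| PCA components | 15 | standard choice for hemipelvis SSMs |
| Stiffness schedule | 100…2, 10 inner rounds | gross-to-fine annealing |
| `max_corr_dist` | 10 mm | displaced fragments beyond this must not attract the template |
| Reconstruction | ≤5 outer passes, tol 0.1 mm | geometric convergence makes more passes pointless |
| Coefficient clamp | ±3σ | plausibility constraint |

Batch experiments (the degradation study, the cohort run and the acceptance
script) use 4 inner rounds per stiffness level and 3 outer passes — at the
default template resolution the extra rounds change reconstructions by less
than the convergence tolerance, and the reduced setting keeps a full
80-reconstruction study in the minutes range on one CPU.

## Known limitations

* Mesh "wrapping" is hole filling + largest-component selection + optional
  Taubin smoothing — an approximation of proprietary shrink-wrap
  operations, not an equivalent.
* Binary STL stores float32 by format definition; PLY is written with
  float64 vertices and round-trips exactly.
* Displaced fragments are used where they lie; repositioning them first
  (fracture reduction) is out of scope.
* Tangential correspondence drift (above) bounds how well raw registration
  output can match material-point ground truth; quantities computed after
  subspace projection are much less affected.
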