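# Methods

`lumbokin` is a reduced-order, quasi-static model of the lumbar column
(L1–sacrum) built for mobility analysis: range of motion of every vertebra
with respect to the sacrum under physiological loading, verification
against radiological cohort statistics, and the mobility consequences of
L5–S1 disc degeneration. This note documents the model, its assumptions,
the numerical machinery, and what the synthetic data do and do not show.

## The mechanical model

**Kinematics.** The sacrum is fixed (wings constrained). Each of the five
motion segments contributes six relative degrees of freedom: translation
(mm) and a rotation vector (rad) of the upper vertebra about the disc
centroid, expressed in the disc-local frame. Vertebrae are rigid — bone is
two to four orders of magnitude stiffer than the discs and ligaments, so
vertebral elasticity (carried in the material card as metadata) is not
resolved. Coordinates: x mediolateral (the sagittal mirror plane is x = 0),
y anteroposterior with anterior at −y, z cranial; flexion is a positive
rotation about x, lateral bending about y, axial rotation about z.

**Segment energy.** Each segment stores energy in five constituents, and
the restoring wrench is the exact negative gradient of that energy:

1. *Annulus ground substance* — a homogenized 6×6 diagonal foundation from
   the elliptical section properties: the confined modulus
   `M = E(1−ν)/((1+ν)(1−2ν))` acts on axial translation and bending
   (the matrix is constrained between the endplates), the shear modulus on
   in-plane shear and torsion. The shear terms carry an interlamellar
   shear-correction factor (default 0.4): annulus lamellae slide on one
   another, so the layered matrix transmits far less shear than a solid
   section would, and torsion restraint is carried mainly by the crossed
   fibres and the facets. Without this knockdown the degenerated matrix
   (E 4.2→6.0 MPa, ν 0.45→0.35, hence *higher* G) would stiffen the
   degenerated segment in torsion, the wrong direction for a degenerated
   disc.
2. *Nucleus pulposus* — a cavity model: axial approach of the endplates
   displaces nucleus volume, which either compresses the nucleus (bulk
   modulus K) or bulges the annulus wall against its cavity stiffness.
   The confinement modulus comes from the thick-walled Lamé solution of
   the ground-substance ring, `c_b = E / (2 (λ + ν))` with
   `λ = (r_o² + r_i²)/(r_o² − r_i²)`; the tension-only fibres are
   near-slack in the compression-dominated states where the cavity model
   matters and therefore do not stiffen the wall. The two stiffnesses act
   in series, so an incompressible nucleus in a compliant wall displaces
   its volume into the bulge — which is what keeps the nucleus volume
   change small (≈0.2%) for the compressible elastic comparison nucleus
   under the full preload. For the healthy, incompressible Mooney–Rivlin nucleus
   (C01 = 0.0343 MPa, C10 = 0.1369 MPa) K is a volumetric penalty, 500×
   the annulus modulus by default: this keeps the converged relative
   volume change below the 1e-4 penalty tolerance under the 400 N preload
   (a 100× penalty leaves ~2.3e-4 of residual compressibility, violating
   the stated tolerance). The Mooney–Rivlin deviatoric response enters the
   foundation through its small-strain shear modulus 2(C10+C01) =
   0.3424 MPa. Degenerated and comparison nuclei are compressible elastic
   and use their physical bulk modulus.
3. *Annulus fibres* — tension-only truss samples spanning endplate to
   endplate on five concentric layers (orientation 35° innermost to 80°
   outermost from the transverse plane; the four inner layers are crossed
   ± pairs, the single outer sheet is sampled at half density split across
   both handedness families to preserve bilateral symmetry). Default fibre
   volume fraction 0.10 of the annulus, 12 samples per family per layer.
   Fibre kinematics are exact truss kinematics, so the helix behaviour in
   torsion (only the family following the twist tensions) emerges rather
   than being imposed.
4. *Ligaments* — eight families (ALL, PLL, LF, ITL, CL, ISL, SSL, and the
   iliolumbar ligament at the lumbosacral junction only) as tension-only
   strands with the bilinear law (E1 up to the transition strain, E2
   beyond; the ISL/SSL second modulus is *lower* than the first and is
   transcribed literally, not "corrected"). Attachment coordinates and
   cross-sections are not printed in any primary source table, so they are
   named config parameters with average-anatomy defaults; rest lengths
   equal the neutral attachment distances (zero pre-strain), with a
   per-strand pre-strain offset available for slackening.
5. *Facets* — one contact point per side per level, posterior and lateral
   to the disc centroid, with a tangential (circumferential) normal and a
   0.5 mm articular clearance. The penalty (200 N/mm) acts in both
   tangential senses (the medial and lateral faces of the articular pair),
   which keeps the system bilaterally symmetric; facets therefore restrain
   axial rotation, and by construction do not carry axial load.

**Loads as potentials.** The 400 N follower preload is realized as
compressive force pairs along the deformed lines joining adjacent body
centroids (sacrum through L1); because such a pair derives from the
potential `P·(current length − neutral length)`, the entire load system is
conservative and equilibrium is the stationary point of one scalar
potential. External moments (15 N·m for flexion/extension/lateral bending,
6 N·m for axial rotation, at L1), per-vertebra muscle moments, and psoas
slip forces (constant-tension potentials `F·ΔL`) are handled the same way.
A fixed-direction ("vertical") preload variant exists for comparison; it
produces far larger coupled sagittal rotations than the follower load, as
expected. Subtracting the neutral lengths keeps the potential near zero
magnitude, which matters for the finite-difference conditioning below.

## Equilibrium solver

Newton iteration on the gradient of the total potential, under ten uniform
load increments (automatic halving of a failing increment), warm-started
between increments. The internal (segment) gradient is assembled by chain
rule: the tension-only force laws are evaluated analytically at the state —
exactly zero at tension onset — and only the smooth geometric sensitivities
(strains, gaps, lengths) are centrally differenced (half-steps 1e-5 mm,
1e-6 rad). This avoids the O(h·k) artifact a plain energy difference
produces at the constitutive kinks. The Hessian is differenced from that
same gradient (block-diagonal over joints) plus a dense finite-difference
Hessian of the cheap external potential; steps are regularized by a
Levenberg shift when needed and accepted under a backtracking line search
on the energy. Convergence: every residual force component < 1e-6 N and
every residual moment component < 1e-3 N·mm. The iteration schedule is
fixed, so identical inputs give bit-identical results.

With the lordotic default geometry the follower preload leaves a small
sagittal coupling (≈0.3° at L5–S1, from the offset between the centroid
chords and the disc centroids); out-of-sagittal rotations vanish to
round-off by symmetry.

## Muscle-force calibration

The calibration finds nonnegative muscle magnitudes whose equilibrium
meets per-segment rotation targets while minimizing the total muscular
energy `W = Σ W_F + Σ W_M`, with `W_F = ∮ F·ds` along the muscle path and
`W_M = ∫ M·dθ` over the achieved rotation. Two stages:

* an outer Newton iteration on per-vertebra driving moments until the
  converged chain meets the segmental targets (stopping at one fifth of
  the per-segment tolerance, so the cumulative L1 angle — a sum of five
  segmentals — stays sharp);
* a linear program (HiGHS) distributing those moments over the muscle set
  at minimum energy, with a squared-magnitude tie-break among
  energy-equal solutions (deterministic split of redundant muscles).

Global muscles act as per-vertebra moment fascicles — consistent with
adjusting "forces and moments on each vertebra" — and carry a per-movement
action sign: rectus abdominis flexes (and opposes extension), erector
spinae extends (and opposes flexion), the bilateral obliques and
multifidus act in both senses for lateral bending and axial rotation. All
magnitudes are nonnegative; antagonist (eccentric) work is counted by
magnitude in the objective, so co-activation costs effort instead of
returning energy — this keeps the program bounded and penalizes redundant
co-activation. The psoas major is the local muscle: one slip per vertebra
from an anterolateral attachment to a fixed pelvic anchor, entering the
moment balance through its geometric arms. The descent history records
the accepted candidates of the distribution stage (feasible least-squares
start, LP optimum, tie-break), nonincreasing by its acceptance rule.

Healthy-model targets distribute the whole-lumbar maxima (34.40° flexion,
35.58° extension, 19.33° lateral bending, 9.96° axial rotation) over the
levels following the radiological per-level pattern, rescaled to the L1
maximum; axial rotation, which has no radiological arm, uses uniform
segmental targets, consistent with the observation that vertebral
rotations in torsion differ little between levels.

## Angle measurement

Every vertebra carries two perpendicular superior-endplate reference
lines (frontal: mediolateral nodes; sagittal: anteroposterior nodes), and
angles with respect to the sacrum come from the direction cosines of
those lines, pairing the components of the measurement plane: (m, n) of
the sagittal lines for flexion-extension, (l, n) of the frontal lines for
lateral bending, (l, m) for axial rotation. The *literal* inner product of
the in-plane cosine pairs equals the in-plane angle only when both lines
lie in the plane; a *projected* variant (normalize the in-plane
projections first) is the default for 3-D states, and both are exposed —
for the planar movements studied here they agree to round-off. Signs
follow the rotation about the movement axis; angles are reported in each
movement's own positive sense and as changes from the neutral (lordotic)
posture. Model states and radiological landmark data flow through this
same code path.

## Synthetic radiological cohort

The generator emulates the verification protocol: 25 healthy young men
(age 27.4 years on 23–33, weight 78.6 kg on 72.1–81.7, truncated normals
with SD = range/4), per-level cumulative angles drawn around the packaged
reference means/SDs for flexion, extension and lateral bending. Torsion
has no radiological arm and is not generated. Within a subject, levels
share a mobility factor (intraclass correlation 0.5 by default) —
independent draws would violate the anatomical ordering too often — and an
isotonic (pool-adjacent-violators) correction enforces L1 ≥ L2 ≥ … ≥ L5.
The correction slightly biases adjacent-level means/SDs (of order 0.1° at
the closely spaced caudal levels), so distributional parameter recovery is
asserted on the raw draws, and the corrected cohort on looser bounds.
Landmark emission rotates the neutral endplate lines by the subject's
angles and adds isotropic Gaussian endpoint noise (default 0.5 mm); with
zero noise the direction-cosine readout reproduces the generated angles
exactly. The cohort emulates between-subject variability only: no
radiographic projection geometry, magnification, or observer error model —
so passing recovery tests validates the sampling machinery, not the
radiographic measurement process.

## Disc degeneration study

The degenerated L5–S1 level swaps in the degenerated material card
(annulus 6.0 MPa/0.35, compressible elastic nucleus 1.3 MPa/0.4, fibre
moduli ÷10) plus the two geometric signatures the card cannot carry:

* *height loss* — the column is rebuilt with the reduced disc height while
  all trans-disc soft tissues keep their healthy rest lengths, which
  slackens every fibre and ligament crossing the level exactly as a
  collapsed disc does;
* *longitudinal-ligament slack* — an extra nonpositive pre-strain offset
  on ALL and PLL (default −2%).

Both arms are loaded identically (400 N follower preload + the pure
normalized moments) and compared by the percent change of the cumulative
L1 angle. The two free parameters are calibrated once, on flexion only —
a regularized Nelder–Mead fit anchored at the defaults (0.2, −0.02),
since a two-parameter fit to one scalar is underdetermined — and then held
fixed, so extension, lateral bending and axial rotation are genuine
predictions. Two properties of the fit are worth knowing: the flexion
response is insensitive to the longitudinal-ligament slack (the PLL is a
weak flexion restraint at these arms, so the slack parameter is fixed by
the regularization, not identified by the data), and the flexion increase
saturates near a height loss of ~0.3 — beyond that the 1/h stiffening of
the matrix foundation "restabilizes" the segment, the known late-stage
behaviour of degenerated discs.

## Problem sizes and runtime

Five segments × 6 DOF = 30 unknowns; 120 fibre trusses and 9–11 ligament
strands per level; batched vectorized energies make one equilibrium solve
take on the order of a second, a four-movement calibration a few minutes,
and the full verification-plus-degeneration pipeline well under ten
minutes on one CPU. These sizes are the package's intended desk scale.

## Known limitations

* Quasi-static only: no viscoelasticity, poroelasticity, creep, or
  load-rate effects; no dynamics.
* No intradiscal or bony stress fields — constituent force magnitudes and
  activation signs only (fibre tension patterns in
  flexion/extension/bending/torsion are asserted, stress maps are not
  reproduced).
* The matrix/fibre load share of the homogenized annulus differs from a
  volumetric finite-element discretization: lateral-bending and torsion
  restraint remain more matrix- and facet-dominated here even after the
  interlamellar shear correction, so the predicted degeneration mobility
  increases in those movements are smaller than a full continuum model
  yields, although their direction (hypermobility at every level, in all
  four movements) is robust.
* Ligament attachments, cross-sections, muscle paths, and disc dimensions
  are literature-informed defaults, exposed as config rather than claimed
  as measurements; forces scale with the cross-sections, which the muscle
  calibration absorbs.
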