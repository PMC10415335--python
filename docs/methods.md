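# Methods

## The model

The foot is three rigid segments — phalanx (toes), forefoot, hindfoot —
joined at the metatarsophalangeal (MTP) and midtarsal joints; the ankle
joins the hindfoot to a shank frame. The plantar aponeurosis (PA) is five
tension-only linear springs (PA1 medial → PA5 lateral), each a polyline
from an origin on the hindfoot (plantar calcaneus) through an intermediate
point under the forefoot to an insertion on the phalanx. Midtarsal
dorsiflexion (arch flattening) and MTP dorsiflexion (windlass engagement)
both lengthen the polylines, which is the geometric mechanism the model is
built to capture.

The original model of this kind was built from CT of an adult foot; that
geometry is not published, so `footspring` ships a **parametric idealized
template**: marker positions, PA path points and joint centers for an
average right foot, expressed in a common neutral (quiet-standing)
configuration in which every segment's local frame coincides with the lab
frame (X anterior, Y left, Z up; mm). All geometry lives in
`TemplateConfig` and is serialized to JSON, so results are always
interpretable relative to a fully stated template. Consequences of the
idealization:

- The 14 standard foot markers are assigned so each segment carries ≥ 3
  non-collinear markers (a rigid pose is otherwise indeterminate). The real
  toe segment carries a single marker; here the first and fifth
  metatarsal-head markers move with the phalanx. Marker #7 is read as the
  fifth metatarsal base (the marker table's literal text duplicates #3, and
  the plate-placement rule needs the lateral forefoot landmark).
- The ankle's proximal frame is built geometrically from the two malleolus
  markers plus a synthetic shank-axis marker (a Procrustes fit does not
  apply because the malleoli ride on the hindfoot). It is exact for
  sagittal-plane motion and a documented proxy otherwise.

### Subject scaling

Each segment gets one uniform similarity scale fitted to the time-averaged
standing markers (three-marker segments under-determine anisotropic
scaling). PA paths and joint centers scale with their host segment.
Per-slip natural length is `L0 = c · L_stand` with `c = 0.98` for every
slip; the PA cross-sectional area scales allometrically,
`A = 69.2 mm² · (m / m_ref)^{2/3}`, split equally across the five slips
(configurable proportional split). A standing trial is flagged non-static
when a marker's positional RMS about its mean exceeds 3 mm — an RMS
criterion rather than a frame-to-frame speed, which would be dominated by
ordinary marker noise.

### Parameters without published values

| parameter | default | rationale |
|---|---|---|
| spring constant `k_i` | 40 N/mm per slip | ≈200 N/mm total PA stiffness, mid-range of cadaver estimates |
| reference mass `m_ref` | 70 kg | conventional adult reference mass |
| per-slip CSA split | equal fifths | no published split; configurable |
| foot mass | 1.37 % body mass | standard anthropometry |
| segment mass split | 60/30/10 % hind/fore/phalanx | mass concentrated in the tarsus |
| segment inertia | solid ellipsoid over the segment markers | order-of-magnitude correct; inertial terms are ≪ the GRF terms |

## Event detection

Stance is the longest episode with net vGRF above 2 % body weight, with
sub-sample threshold crossings by linear interpolation (1000 Hz
quantization is 1 ms, close to the precision of the reported latencies).
The impact peak — the first local vGRF maximum above 1.5 BW in the first
half of stance, a configurable qualifier for a shape that is defined only
pictorially — sets `t = 0`. T2 is the first local minimum after the impact
peak, T3 the maximum after T2, T1 and T4 the contact→impact and T3→toe-off
midpoints. The GRF channels are never filtered.

Trial selection: (i) navicular and fifth-metatarsal-base markers within
±15 mm of the inter-plate edge at heel contact; (ii) the heel marker
descends to within 10 mm of its *standing* height while the posterior
plate is loaded — the heel marker sits ~25 mm above the sole on the
calcaneal tuberosity, so an absolute height bar near the plate surface
would be unreachable by any physically placed marker; (iii) contact time
< 0.3 s.

## Kinematics and dynamics

Markers are filtered with a fourth-order zero-phase Butterworth at 24 Hz
(forward–backward; the two passes square the magnitude response, so the
cutoff sits at −6 dB). Poses come from an orthogonal-Procrustes (Kabsch)
fit per segment and frame, reflections corrected to proper rotations; the
per-coordinate residual RMS is reported (expectation `σ√(1−6/(3n))` under
isotropic noise). Joint angles are intrinsic Euler decompositions of the
distal-relative-to-proximal rotation, sagittal (mediolateral axis) first,
then frontal, then transverse, with standing angles subtracted
component-wise; frames with |frontal| > 85° are gimbal-flagged. Angular
velocity is the central difference of the per-plane Euler angles (matching
how per-plane "angular velocity" is conventionally reported), not the
angular-velocity vector.

Inverse dynamics assigns the anterior-plate wrench to the forefoot and the
posterior-plate wrench to the hindfoot at their COPs, block-averages the
analog channels to the marker rate (anti-alias, then decimate), and runs a
distal-to-proximal Newton–Euler recursion: phalanx → MTP,
phalanx+forefoot → midtarsal, all three → ankle. Moments are taken about
the joint center, resolved in the **proximal-segment frame** (a choice the
source convention leaves open; it is logged in output metadata), with
dorsiflexion positive. Power is the per-plane dot product `M·ω` (radians
internally). Normalizations: GRF by `m g`; foot moments by
`m · foot length`; powers by `m`.

## The synthetic-data generator

The generator is **kinematics-first**: joint-angle waveforms and the net
vGRF are prescribed as C¹ shape-preserving piecewise-cubic Hermite
interpolants (PCHIP slopes where no derivative is given; supplied
derivatives honoured exactly), markers are synthesized by forward
kinematics of the template, and the plate forces are prescribed
independently to match the two-peak drop-jump vGRF shape. Its defaults
*are* the study conditions: the sex presets pass through the published
group means —

- stance 0.26 s (female) / 0.28 s (male); T3 latency 78 / 99 ms; T4
  142 / 165 ms; impact peak 3 BW; vGRF trough 1.6 / 1.4 BW;
- midtarsal dorsiflexion 11.4° / 7.1° at T2 and 12.2° / 8.3° at T3, with
  the Hermite derivative constraint 65.2 / 20.1 deg/s at T2; MTP
  dorsiflexion 17.1° / 7.9° at toe-off; T4 plantarflexion velocities
  −310 / −152 deg/s (midtarsal) and −240 / −372 deg/s (ankle);
- body mass 55.1 / 59.6 kg.

The impact-peak offset from contact (54 ms female, 49 ms male) is the
unique value consistent with the published stance/T3/T4 means under
T4 = (T3 + toe-off)/2. Unpublished keypoints (vGRF second peak 2.8/2.6 BW,
trough timing, contact/toe-off vGRF slopes, angle values at contact and at
the impact peak) are fixed once at realistic values; the angle value at
the impact peak is chosen so the angle's *acceleration* is continuous at
the velocity-constrained T2 knot — a C¹-only Hermite corner there is an
interpolation artifact, not physiology, and would alias into any
finite-difference velocity estimate.

Plate split: the anterior-plate share of the net vGRF ramps monotonically
from ~0.12 at contact to 1 at toe-off (posterior plate carries the heel
impact), with fixed per-plate COPs under the heel and metatarsal heads.
The aerial phases are 0.1 s of free fall before contact and a ballistic
rise after toe-off whose takeoff velocity is derived from the waveform's
own net impulse, so the trial is impulse-consistent by construction; the
test suite asserts that consistency at the 5 % level on the sampled
signals. Marker noise is independent isotropic Gaussian, default σ =
0.5 mm; GRF noise is zero (GRFs are not filtered downstream). Cohort
sampling jitters the preset keypoints with independent Gaussians at the
published between-subject SDs (5 % where none is published), resampling
draws that violate the event-ordering or GRF-shape constraints.

What the generator does **not** emulate: soft-tissue artifact and
marker-occlusion gaps; full dynamic consistency between prescribed
kinematics and prescribed forces (asserted only at the impulse level);
inter-joint coordination variability within a trial; horizontal GRFs.
Passing round trips therefore demonstrate correctness of the estimation
chain — filtering, pose fitting, Euler decomposition, differentiation,
event detection, spring mechanics — under rigid-body conditions, not
robustness to the artifacts of real capture data.

## Numerical choices

- Threshold crossings and event times: linear interpolation between analog
  samples; series are evaluated at event times by cubic interpolation.
- Angular velocity of a rotation series: central rotation increments
  `rotvec(R_{i+1} R_{i-1}ᵀ)/(2Δt)`.
- A measurement-chain caveat, quantified in the tests: at a sharp velocity
  peak (the female midtarsal T2 constraint of 65.2 deg/s) the 100 Hz
  central difference plus the 24 Hz marker filter recover ≈ 63.6 deg/s,
  a ~2.5 % attenuation intrinsic to differentiating filtered, sampled
  angles — the same chain a real capture system applies.
- Tension-only springs: negative elongation stores no energy and produces
  zero force; this slack condition is logged in output metadata.
- The Lilliefors normality table starts at n = 4; n = 3 falls back to the
  naive KS statistic against the fitted normal. Degenerate (zero-variance)
  samples route to the rank-sum branch. The rank-sum test is exact for
  tie-free samples with n ≤ 8 per group, otherwise the tie-corrected
  normal approximation.
- The t-test is Student (equal-variance), two-sided; Welch is available by
  flag. The KS variant and t-test variant are configurable because the
  source procedure names neither.

## Problem sizes

The test suite and the acceptance script run single nominal trials
(~0.46 s, 47 marker frames / 461 analog samples per trial), cohorts of
3–4 subjects per sex for pipeline determinism checks, 1000-draw Monte
Carlo for the pose-residual law, and a 10,000-replicate null simulation
for the empirical size of the routed test procedure — sizes chosen so the
whole suite completes in well under a minute of compute per stage.

## Known limitations

- The PA is purely elastic; viscosity is deliberately out of scope, so
  reported tensions are lower bounds during fast stretch.
- No muscles cross the modelled joints, so joint contact forces are not
  estimable.
- The idealized template is not subject-specific anatomy; absolute strain
  and stress levels inherit its geometry, and only comparisons within the
  same template are meaningful.
- Proximal joints (knee, hip, trunk) are out of scope.
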