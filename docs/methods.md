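# Methods

This note documents the models, conventions and numerical choices behind
`lumbocord`, and what the synthetic-data tests do and do not establish.

## Coordinate and level conventions

All volumes are treated as RAS+ (x → right, y → anterior, z → superior).
In the cord, anterior ≡ ventral and posterior ≡ dorsal; rostral means
larger z. Slice intervals are 0-based and half-open. The lumbosacral cord
comprises seven segmental levels L1–L5, S1, S2 (integer codes 1–7 in label
volumes), flanked by the nine nerve roots T12–S3.

**Level delimitation from REZ.** The boundary between consecutive levels is
the rostrocaudal midpoint of the two flanking root-entry-zone coordinates;
level Lk occupies the half-open mm interval (mid(REZ_{k−1}, REZ_k),
mid(REZ_k, REZ_{k+1})]. Boundaries are invariant to uniform translation of
the annotations. Annotations may arrive in mm or slice units (declared in
the annotation); computation is in mm.

**Hemicord tie rule.** A voxel whose in-plane coordinate equals the
centerline coordinate is assigned to the *right* (left/right split) and to
the *ventral* (dorsal/ventral split) hemicord. The rule is arbitrary but
fixed, so voxel counts and indices are reproducible.

## Synthetic data: the stated world

The simulator emulates a reduced-FOV axial acquisition: 48×48×32 voxels at
1.1 × 1.1 × 3 mm, TR 2.5 s. The cord is a per-slice disk of radius 4 mm
around a straight or smoothly meandering centerline (meander bounded at 2
voxels so the cord plus its 2 mm CSF ring stays in-grid); baseline signal
is 100 in cord, 80 in CSF, 10 outside.

Paradigms: the active/passive task is 12 blocks of 15 s interleaved with 13
rest periods of 15 s (375 s; 150 volumes at TR 2.5 s). The published run
length of 153 volumes does not reconcile with the block structure; the
3-volume difference is exposed as `pad_volumes` rather than guessed at.
The vibration task is 18 blocks of 10 s with strictly alternating
agonist/antagonist labels and rests drawn uniformly from 10–15 s (seeded).

Signal model: planted voxels follow baseline·(1 + a/100 · s(t)) where a is
the % signal change and s(t) the task boxcar convolved with the canonical
double-gamma HRF normalized to a unit plateau; everywhere a polynomial
drift (2nd order by default) and white Gaussian noise are added. The
simulated HRF delay is a parameter, so basis-mismatch scenarios can be
produced; at the default delay the simulator and GLM share the canonical
shape, making amplitude recovery unbiased by construction. Motion spikes
add their magnitude to the x-translation and perturb that volume's
cord/CSF intensity by 5% of baseline per mm, so DVARS scrubbing has a
target. An optional low-rank CSF signal (random spatial loadings times
given time courses) exercises the aCompCor path.

Not emulated: k-space/MR physics, susceptibility artifacts, and realistic
cardiac/respiratory noise waveforms. A green recovery test therefore
establishes correctness of the *analysis logic* under white noise and
drift, not robustness to structured physiological noise.

Probabilistic level maps are across-subject label frequencies: each
synthetic subject jitters the six internal level boundaries independently
by an integer in [−j, j] (monotonicity enforced, outer extents fixed).

## Quality control

- **FD**: per slice and volume pair, the sum of absolute backward
  differences of translations; when rotations (degrees) are present they
  are converted to arc length at a 50 mm radius and added. The series is
  averaged over slices, then over time. Rotation inclusion is a flag
  (`include_rotations`), since slice-wise realignment stages provide
  translations only. Runs are kept iff mean FD < 0.5 mm (strict).
- **DVARS**: RMS over cord voxels of consecutive-volume differences,
  computed on unsmoothed data. Scrubbing flags elements strictly above
  Q3 + 1.5·IQR with quartiles by linear interpolation between order
  statistics (the result on short series depends on the quantile method,
  hence it is pinned). Flagged volumes become one-hot nuisance regressors.
  Series element t−1 maps to volume t.
- **tSNR**: temporal mean over sample SD (ddof = 1); zero-variance voxels
  get +inf and are excluded from the mask mean.

## GLM

- **Basis**: canonical double-gamma (peak 6 s, undershoot 16 s, ratio 1/6)
  plus temporal (0.1 s finite difference) and dispersion (1% dispersion
  change) derivatives; the derivatives are Gram–Schmidt orthogonalized
  against the canonical column after mean-centering. This replaces an
  optimized FSL basis whose waveforms are not recoverable; equivalence
  with FSL outputs is not claimed.
- **Estimation**: per-voxel OLS; no prewhitening (the synthetic noise is
  white by default). Drift is modeled with Legendre polynomials (order 2
  default). The contrast is the canonical-basis coefficient; t → Z by
  matching one-sided tail probabilities, with an asymptotic inversion of
  the normal survival function from log p where the tail underflows, and
  |t| as an upper-bound fallback where even log p is −inf.
- **aCompCor**: principal-component time courses of the mean-centered CSF
  voxel-by-time matrix (SVD), variance-ranked, unit norm; five components
  by default. Motion parameters are added as nuisance regressors for the
  vibration condition (configurable).
- **Fixed effects**: cope and varcope are summed and Z = Σc/√Σv, so k
  identical inputs scale Z by √k. Degrees of freedom are summed;
  associativity holds exactly.
- **Smoothing**: anisotropic Gaussian, FWHM 2 × 2 × 6 mm, applied in
  cord-aligned coordinates: slices are shifted (bilinear) so the
  centerline is straight, the volume is smoothed in-plane and then along
  z, and shifted back.
- **Cluster correction**: the exact Gaussian-random-field correction is
  replaced by sign-flip permutation of the input (run- or subject-level)
  COPEs: each permutation flips whole maps' signs, recombines by fixed
  effects, rethresholds, and records the maximum cluster size;
  p = (1 + #{null ≥ observed}) / (n_perm + 1). Two caveats follow from the
  method itself and are deliberately not hidden: (i) with k input maps
  only 2^k sign patterns exist, so with 2 runs the smallest achievable
  cluster p is 0.25 — cluster correction is meaningful at the group/third
  level, not on a 2-run second level; (ii) a very strong true effect
  contaminates the null (permutations with mostly-positive signs retain
  the cluster), making the correction conservative at high SNR. The test
  suite exercises the regime (12 maps, planted Z ≈ 5) where the correction
  behaves as intended.

## Spatial metrics

- **Laterality**: LR = (n_left − n_right)/(n_left + n_right), DV =
  (n_dorsal − n_ventral)/(n_dorsal + n_ventral), counted over active ∩
  hemicord ∩ region. Empty maps yield *missing* indices (None), never
  zero, to avoid fabricating laterality. Per-level indices restrict the
  counts to each level's mask.
- **Segmental distribution**: raw active-voxel counts per level; a level
  is *active* iff its raw share of all significant voxels exceeds 30% —
  the share-of-voxels reading, applied before size correction. The
  size-correction factor is level volume over the *mean* level volume
  (the normalizing constant cancels after normalization, a tested
  property); corrected counts are normalized to sum to 1. Group
  histograms sum the corrected counts of active levels across
  participants, then renormalize.
- **Level-map binarization**: threshold 0.6 (≥), largest 26-connected
  component, 3D hole filling, then in-plane dilation to the full cord
  cross-section (each level becomes a block of whole cord slices).
  Overlaps and gaps between adjacent levels are split equally along z;
  an odd slice count gives the extra slice to the more rostral level
  (recorded in the output metadata). Non-adjacent overlap is an error;
  an empty level is an error or, per flag, a warn-and-drop whose span is
  absorbed by the gap rule. 26-connectivity in 3D and 8-connectivity
  in-plane are used throughout (the connectivity choice is a convention).

## Projectome decision tree

Map-set priority: analysis level descending, corrected before uncorrected,
Z threshold descending, cluster p ascending; ties keep input order (the
sort supports arbitrary threshold ladders). Components are 26-connected;
the center of gravity is the unweighted voxel centroid by default
(`cog_weighted` enables Z-weighting for sensitivity analysis), and its
level is read at the nearest voxel. A component is kept iff its CoG level
lies in the muscle's expected range; the shipped table (TA L4–S1, Gas
L4–S2, Qd L1–L4, Il L1–L4, BF L5–S2, GMax L5–S2) reflects intraoperative
stimulation literature and is an editable JSON. Within a map the largest
kept component wins; equal sizes go to the more caudal CoG. Pool labels
use the component DV index with a ±0.2 margin (below −0.2 motor, above
+0.2 sensory, else mixed); side is left iff the component LR index is
positive (ties right). Confidence is *high* iff the source map is
third-level corrected; one entry per muscle (a multi-candidate mode can be
built from `extract_components`/`evaluate_candidate` directly). A muscle
with no kept candidate is reported not-estimable — a result, not an error.

## Tolerances and test scaling

Analytic identities (laterality endpoints, fixed-effects √k scaling,
midpoint arithmetic, size-correction neutrality) are tested exactly or at
1e-9–1e-10. Monte-Carlo calibrations use stated bands: the first-level
false-positive fraction at Z > 2.3 on ≥10⁴ white-noise voxels must fall
within ±0.003 of the one-sided normal tail (≈0.0107). The end-to-end
recovery suite uses a scaled-down grid (24×24×21, 3-slice levels) and
cord-masked GLM fits to keep 20 participants × 6 muscles × 2 runs within
seconds; noise SD 5.3 puts planted second-level Z near 5, the regime the
recovery protocol specifies. Jitter-robustness tests use 4-slice levels
(~12 mm), the realistic thickness at 3 mm slices; with 3-slice levels a
±2-slice boundary jitter can legitimately erase a level, which the
binarizer reports rather than hides.

## Known limitations

- Rigid/slice-wise motion-correction registration and template
  (PAM50) normalization are out of scope; motion parameters, masks and
  warped inputs come from external tools or the simulator.
- No mixed-effects group model: fixed effects only, so group inferences
  do not generalize beyond the analyzed cohort.
- The permutation cluster correction is unusable for very few input maps
  and conservative at very high SNR (see above).
- The simulator's noise is white; claims about physiological-noise
  robustness cannot be made from these tests.
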