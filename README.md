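# scapstab

Scapula shape analysis and supraspinatus glenohumeral-stability modelling.

Specific scapula shapes are associated with full-thickness tears (FTTs) of
the supraspinatus tendon. A central role of the supraspinatus is to press
the humeral head into the glenoid (concavity compression); scapular
geometry that tilts the muscle's line-of-action away from the compressive
axis may raise the tendon load needed to keep the joint stable.
`scapstab` implements, as one tested pipeline, the chain of methods needed
to study that link:

1. **Supervised shape discrimination.** 29 named 3D landmarks per scapula
   are aligned by generalized Procrustes analysis (similarity
   superimposition, reflections excluded). Partial least squares
   discriminant analysis (PLS1 regression on a binary tear label, y = 0
   control / y = 1 FTT) extracts shape modes ordered by covariation with
   tear status. The mode count *m* is selected by leave-one-out
   cross-validation over 1..M (M = modes explaining 70% of shape
   variance), scored by balanced accuracy = (sensitivity + specificity)/2,
   with F1 and G-mean (harmonic/geometric means of precision and recall)
   alongside, and the model is benchmarked against 20 label-permuted null
   models (Z-scores, upper-tail p).
2. **Group-associated shapes and metrics.** Control- and FTT-associated
   landmark shapes are the group means projected onto the *m* retained
   modes; a 3D thin-plate spline (biharmonic kernel U(r) = r) warps a
   template mesh onto them, and a panel of discrete metrics is computed:
   critical shoulder angle, glenoid inclination/version, glenoid
   height/width, acromion coverage, lateral acromion ratio.
3. **Kinematics-driven simulation.** Glenohumeral poses use a Y-Z-Y Euler
   sequence (elevation plane, abduction, axial rotation) in ISB-style bone
   frames (x lateral, y superior, z posterior). The base path is 10-100
   degrees of abduction in 5-degree steps, 5 degrees anterior to the
   scapular plane, with 50 degrees of external rotation; perturbed paths
   add constant plane/axial offsets. The humeral head is placed
   congruently on the glenoid-centre normal, and the kinematic neutral
   pose is the centroid of the impingement-free rotational range of
   motion.
4. **Multi-fibre supraspinatus and stability ratios.** The muscle is 50
   fibres (30 deep spanning the full fossa origin perimeter, 20
   superficial on its superior segment), each discretized to 100 nodes
   and wrapped over the humeral head with an exact tangent-arc-tangent
   construction plus a lateral-coherence regularizer. Each fibre's
   line-of-action (effective insertion to effective origin) is resolved in
   the glenoid principal-axes frame into

   SI ratio = f_shear,SI / f_compressive, AP ratio = f_shear,AP / f_compressive

   (SI positive superior, AP positive anterior); higher magnitudes mean a
   greater tendency to translate the humeral head.

Because clinical CT cohorts cannot be redistributed, the package ships a
synthetic-data generator with known ground truth: two-group landmark
cohorts sharing a schematic template with an injected tear-associated
displacement field (narrower supraspinous fossa, anteverted and superiorly
inclined glenoid, more lateral acromion), plus parametric bone geometry
(ellipsoidal glenoid rim, spherical humeral head, fossa origin patch,
tuberosity insertion patch) whose version/inclination/width are exact by
construction. Every stage is therefore testable against analytic or
construction oracles. See `docs/methods.md` for model details and
limitations.

## Worked example

```python
from scapstab.synthgen import SynthConfig, BoneParams, \
    generate_landmark_sample, generate_bone_geometry
from scapstab.procrustes import gpa
from scapstab.plsda import loocv_mode_selection, n_modes_for_variance
from scapstab.kinematics import base_path
from scapstab.pipeline import simulate_stability
from scapstab.stability import summarize, compare_shapes

cohort = generate_landmark_sample(SynthConfig(n_control=40, n_ftt=20, seed=7))
aligned = gpa(cohort)
X, y = aligned.flat(), aligned.groups.astype(float)
m_max = min(n_modes_for_variance(X, y, 0.70), 14)
table, best_m, reports = loocv_mode_selection(X, y, m_max)
print(f"modes for 70% variance: {m_max}, optimal m: {best_m}, "
      f"balanced accuracy: {reports[best_m].balanced_accuracy:.2f}")

control = generate_bone_geometry(BoneParams())
tear = generate_bone_geometry(BoneParams(version_deg=6.0, fossa_width_factor=0.8))
path = base_path()
diff = compare_shapes(
    summarize(simulate_stability(control, path)[0]),
    summarize(simulate_stability(tear, path)[0]),
)
print("AP-ratio mean shift (tear - control): "
      f"{diff.ap_ratio_mean_diff.min():.3f} to {diff.ap_ratio_mean_diff.max():.3f}")
```

Output:

```
modes for 70% variance: 14, optimal m: 3, balanced accuracy: 0.96
AP-ratio mean shift (tear - control): 0.078 to 0.084
```

Fourteen PLS modes are needed to cover 70% of the shape variance in this
cohort; cross-validation keeps three of them and classifies the held-out
specimens with 0.96 balanced accuracy, because the injected group effect
is large relative to the landmark noise. Along the whole abduction path
the tear-like shape's supraspinatus acts 0.078-0.084 more anteriorly per
unit of compression than the control shape's - an anterior shift of the
muscle's stabilizing action driven purely by the glenoid anteversion and
fossa narrowing built into that geometry.

A full run (cohort -> shape model -> warps -> metrics -> simulation ->
comparison report, with every table written to disk plus a manifest) is

```sh
scapstab all --outdir runs/demo --seed 1
```

and the same stages are available individually as `scapstab synth`,
`shape`, `simulate` and `report`.

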