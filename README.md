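# catm — context-aware template matching for crowded cryo-ET

Tools for identifying the positions and orientations of nucleosome-like
particles inside biomolecular condensates imaged by cryo-electron
tomography, where conventional template matching breaks down, plus the
synthetic-tomogram benchmark that quantifies the difference and the
spatial statistics (interface geometry, contact-graph heterogeneity,
clustering) used to characterize condensate organization.

## The problem and the method

A nucleosome is a flattened disc (~11 nm × 5.5 nm).  In a condensate the
discs pack a few nanometers apart, and the tomogram is degraded by the
contrast transfer function (CTF) and the missing wedge of a ±60° tilt
series, which elongates every particle along the beam axis z.  Exhaustive
template matching (TM) — the locally normalized cross-correlation

CCC(x, R) = ⟨ f, T_R ⟩_M / (‖f − f̄‖_M · ‖T_R − T̄_R‖_M) ∈ [−1, 1]

maximized over voxel x and rotation R, followed by a 4 nm center-distance
suppression and a CCC threshold sweep — merges neighbors, undercounts
face-on particles and overcounts side-on views.

Context-aware template matching (CATM) instead starts from one seed
centroid per particle (from segmentation, or the bundled matched-filter
detector), scores all orientations of a wedge- and CTF-degraded template
locally around each seed, retains every orientation with CCC ≥ 0.3 as a
candidate list, and then places particles greedily in descending CCC
order under a hard steric constraint (voxelized mask overlap ≤ 5%).
Conflicts are settled by two-body optimization: the blocked particle and
its nearest placed neighbor are jointly re-optimized over the cross
product of their candidate lists, keeping the sterically compatible
combination with the highest summed CCC.

Downstream, assigned particles feed interface analysis (least-squares
sphere fit of annotated perimeters, signed depth, surface normals, angle
between disc normal and interface normal), a shape-aware contact graph
(edge when disc surfaces approach within 1 nm) with valence distributions,
normalized valence entropy (1 = all valences equally populated, 0 = a
single valence) and attribute assortativity, and DBSCAN clustering with
cluster-size and cluster-fraction-versus-depth profiles.

## Worked example

Simulate a small condensate tomogram, run both matchers, and score them:

```
catm simulate --seed 7 --out demo/            # tomogram_7.mrc + ground truth
catm tm  --tomogram demo/tomogram_7.mrc --step 15 --cutoff-nm 4 --out demo/tm.star
catm evaluate --gt demo/ground_truth_7.csv --pred demo/tm.star --ang-tol 20
```

On a full-size benchmark tomogram (128³ voxels, 150 nucleosomes + 50 DNA
rods, ±60° wedge, CTF, SNR 0.078) the complete comparison runs as

```
catm benchmark --seed 1 --n-tomograms 3 --out report/
```

which prints, per tomogram and summarized (actual output):

```
tomogram seed=1: TM F1 0.854/0.812  CATM F1 0.983/0.943
tomogram seed=2: TM F1 0.803/0.782  CATM F1 0.993/0.946
tomogram seed=3: TM F1 0.803/0.786  CATM F1 0.983/0.936
{"tm_max_f1_position": 0.820, "tm_max_f1_angular": 0.794,
 "catm_f1_position": 0.987, "catm_f1_angular": 0.942, ...}
```

The two numbers per method are the F1 of particle assignment scored on
center positions alone (5.5 nm tolerance) and with orientation agreement
additionally required (20°, symmetry-reduced).  TM's maximum-F1 operating
point still misses or misplaces roughly one particle in five and shows the
characteristic orientation pathology (too few face-on, too many side-on
detections), while CATM recovers nearly all particles with an angle-to-z
distribution statistically indistinguishable from the isotropic sin(θ)
reference (`report/orientation_distribution.png`).

Spatial statistics on an assigned particle table:

```
catm analyze --particles report/catm_particles_1.csv --out report/analysis/
```

writes the contact graph (GraphML + edge list), valence distribution,
normalized valence entropy, DBSCAN cluster sizes, and — when interface
perimeter annotations are supplied — the cluster fraction versus depth
profile.

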