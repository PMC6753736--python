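# linacqa

Simulation-based evaluation of geometric quality-assurance tests for a
radiotherapy linac C-arm.

## The problem

Geometric QA of a medical linear accelerator checks that the machine's real
geometry — isocenter position, gantry and collimator rotation axes, gantry
angle readout, source-to-axis distance (SAD), source-to-imager distance
(SDD), radiation-field size and shape — agrees with its nominal values.  A
modern multi-ball variant of the Winston–Lutz test images a two-module
fiducial phantom on the EPID (the flat-panel MV imager): one module on the
treatment table, one on the collimator head.  From the projected ball
centers the whole machine geometry can be reconstructed automatically.

But EPID image analysis locates each projected ball center only to within a
localization uncertainty sigma (a fraction of the ~0.35 mm pixel).  `linacqa`
answers the question that determines whether such a test is usable: **how
does the dispersion of every reconstructed geometric parameter depend on the
test-plan design (which gantry/collimator angles), the phantom design (how
many balls, how large a module), and sigma?**  It is aimed at medical
physicists designing QA protocols and at developers of automated geometric
test software.

## Model and method

With the isocenter at the origin, `Y` the gantry axis and `Z` vertical, the
source at gantry angle psi sits at `S(psi) = (SAD sin psi, 0, SAD cos psi)`,
and the detector plane lies normal to the beam at SDD beyond the source.
For every pair (theta_i, psi_j) of a test plan `P_T` the phantom markers
`B_k` (table) and `C_l` (head) are centrally projected onto the detector and
perturbed:

    P(B_k), P(C_l)  ~  Normal(nominal projection, sigma^2 I_2)

Reconstruction uses the noisy coordinates alone: camera resection from the
known table-module geometry (source + detector plane, principal point fixed
at the calibrated beam-axis piercing point), perspective-n-point pose of the
head module, Kabsch rotation fitting between collimator angles, extrinsic
(chordal) means of rotation axes on the sphere, and the isocenter as

    I = argmin_P sum_i d(P, R_i)^2

over the per-gantry-angle collimator axes `R_i`.  Field corners are
back-projected into the isocentric plane H normal to the collimator axis.
Repeating simulation + reconstruction many times yields the sampling
distribution `f_Q(x | P_T, B, C, sigma)` of every parameter `Q`, its
standard deviation with chi-square confidence limits, and empirical
action thresholds: the tolerated difference `Delta_TH` with tail
probability `Pr_TH` under the correctly-functioning-device model.

See `docs/methods.md` for the full chain, conventions and caveats.

## Worked example

A baseline test plan — 5 gantry angles over [-180, 180], the 5 collimator
angles (-165, -90, 0, 90, 165), sigma = 0.2 mm, default phantom (6 table
balls / 8 cm cube, 4 head balls / 6 cm cube) — with 200 replicates:

```yaml
# cfg.yaml
plan:
  n_gantry: 5
  n_collimator: 5
  sigma_mm: 0.2
replicates: 200
seed: 42
```

```text
$ linacqa experiment -c cfg.yaml -o out
metric unit       sd  ci95_low  ci95_high  n_samples
 alpha  deg 0.110130  0.105506   0.115181       1000
 theta  deg 0.031158  0.028374   0.034552        200
 omega  deg 0.065962  0.065322   0.066615      20000
     L   cm 0.037081  0.036721   0.037448      20000
     s   cm 0.023343  0.022093   0.024745        600
     l   cm 0.016417  0.014950   0.018205        200
  dsad   cm 5.379082  5.275687   5.486640       5000
  dsdd   cm 9.709098  9.522474   9.903237       5000
outputs in out (config hash 00dc01095c1c62cc)
```

Reading the table: at this noise level the gantry-angle readout check
(`alpha`) is good to ~0.11 deg and the isocenter components (`s`) to
~0.23 mm (1 SD) — comfortably below typical action thresholds — while a
*single-measurement* SAD estimate is only good to ~5 cm; SAD/SDD need
averaging over the many images a plan already contains (the dispersion of
the per-replicate mean falls like 1/sqrt(n_images)).  An action threshold
for, e.g., the isocenter at tail probability 0.05:

```text
$ linacqa threshold --samples out/samples.csv --metric s --pr-th 0.05
Delta_TH(s, Pr_TH=0.05) = 0.0448136
```

i.e. an observed isocenter-component deviation above 0.45 mm would occur
with probability < 5% in a correctly tuned machine under this test plan.

The library API mirrors the CLI (`simulate_plan`, `reconstruct_plan`,
`run_experiment`, `tolerance_threshold`, ...); phantom layouts, plans and
machine constants are plain objects in `linacqa.phantom` / `linacqa.plan`.

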