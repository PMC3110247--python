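# adsorbkit

Analysis toolkit for molecular-dynamics trajectories of polypeptides
adsorbing on flat metal surfaces — gold(111) being the canonical case.  MD
of protein–gold systems produces long coordinate and energy series; the
questions that matter (which residues touch down first? how does an Arg
side chain orient when it lands? does the protein deform or just reorient
its domains?) all reduce to a small set of geometric and statistical
analyses against an ideal surface plane.  `adsorbkit` packages those
analyses, with scripted synthetic trajectories carrying exact ground truth
so every stage is testable without running MD.

It is written for simulators of bio–inorganic interfaces: people who have
GRO/PDB trajectories and XVG energy tables on disk and want reproducible,
scriptable versions of the standard adsorption metrics.

## What it computes

The surface is modelled as one or two ideal planes normal to *z*; every
criterion is a distance Δz along the normal.

* **Contact kinetics** (`adsorbkit.contacts`): per-frame atomic contact
  counts (Δz < 0.35 nm), per-residue minimum-distance maps with the Δz⁻¹
  normalization, first-contact tables (closest-atom Δz < 0.3 nm), residue-
  type aggregation across simulations, and segmentation of the contact
  curve into adsorption phases — *approach*, *gradual increase*, *plateau*,
  *cooperative jump* — by a piecewise-linear changepoint fit.
* **Arg orientation** (`adsorbkit.arginine`): per-frame classification of
  each arginine as `no_contact`, `contact_parallel` or
  `contact_perpendicular`.  An Arg is in contact when any of its atoms is
  within 0.35 nm of the surface; the side chain is parallel when all three
  guanidinium C–N bonds (CZ–NE, CZ–NH1, CZ–NH2) make angles < 30° with the
  surface plane, else perpendicular.  First-contact orientation statistics
  and dwell-time run lengths included.
* **Adsorption energy** (`adsorbkit.energy`): baseline subtraction (each
  component minus its mean over the first nanosecond, before contact),
  1-ns centered-window smoothing with truncated edges, component
  bookkeeping (bonded incl. 1–4 terms, Lennard-Jones, Coulomb; total ≡
  sum), and contact–energy Pearson correlation with a lag profile.
* **Domain reorientation** (`adsorbkit.domains`): per-domain vs whole-
  protein Cα RMSD from independent Kabsch superpositions, the four-point
  binding-site dihedral (site centroid – two anchor residues – site
  centroid), and circular-statistics comparison of dihedral distributions
  (width ratio, mean shift).
* **Diffusion** (`adsorbkit.diffusion`): time-averaged MSD curves (FFT
  algorithm), Einstein-relation fits MSD(τ) = 6Dτ, and the diffusion-limit
  arithmetic L = √(6Dt), t = d²/6D.  Note 10⁻⁵ cm²/s ≡ 1 nm²/ns.
* **Synthetic systems** (`adsorbkit.synthetic`): a rigid anti-parallel
  β-sheet of RAD16II chains (RARADADARARADADA) following a scripted
  adsorption schedule, a two-rigid-domain Cα protein with an injected
  hinge, free Brownian walkers, and contact-coupled energy series — each
  with a ground-truth ledger consistent with the emitted coordinates by
  construction.

I/O (`adsorbkit.io_formats`) reads multi-frame GRO/PDB (via mdtraj), XYZ
with a TSV residue sidecar, and XVG-dialect energy tables; everything
downstream works in nm / ns / kJ·mol⁻¹.

## Worked example

```python
from adsorbkit import contacts, diffusion, synthetic
from adsorbkit.datasets import fn_gold_first_contact_times
from adsorbkit.pipeline import table1_report

# 1. residue-type first-contact aggregation on the bundled reference matrix
#    (fibronectin FNIII(9-10) on Au(111), eight starting orientations)
rep = table1_report(fn_gold_first_contact_times(long_format=True))
print(rep.loc[["ARG", "GLY", "LYS", "PHE"], ["0deg", "60deg", "N-Term", "mean", "min_in"]])

# 2. adsorption phases of a scripted noisy contact series
times, counts, _ = synthetic.scripted_contact_series(seed=0)
seg = contacts.detect_adsorption_phases(counts, times)
for t0, t1, label in seg.segments(times[0], times[-1]):
    print(f"{t0:6.2f} - {t1:6.2f} ns  {label}")

# 3. diffusion constant from ten 100-ns Brownian walkers
_, walkers, _ = synthetic.make_brownian_walkers(D=0.786**2 / 6, seed=1)
lags, msd, per = diffusion.msd_curve(walkers, dt=0.01, max_lag=20.0)
est = diffusion.fit_diffusion(lags, msd, fit_range=(1.0, 20.0), per_walker_msd=per)
print(f"D = {est.D:.4f} +/- {est.uncertainty:.4f} nm^2/ns "
      f"-> L(1 ns) = {diffusion.mean_travel_length(est.D, 1.0):.3f} nm")
```

prints

```
sim_id         0deg   60deg  N-Term   mean        min_in
residue_type
ARG           0.750   0.025   0.025   0.31  60deg,240deg
GLY           2.475   1.225  10.100   3.35
LYS             NaN     NaN     NaN   4.88
PHE           0.875  71.200     NaN  50.12
  0.00 -   4.00 ns  approach
  4.00 -  23.00 ns  gradual_increase
 23.00 -  58.03 ns  plateau
 58.03 -  60.03 ns  cooperative_jump
 60.03 - 100.00 ns  gradual_increase
D = 0.0978 +/- 0.0325 nm^2/ns -> L(1 ns) = 0.766 nm
```

Arginine is the fastest residue type to reach the surface (mean first
contact 0.31 ns across the runs where it appears; `min_in` flags the runs
where it was the overall earliest).  The scripted contact curve is
segmented into the four adsorption phases with the cooperative 58–60 ns
zipping event localized to within a frame or two.  The MSD fit recovers a
diffusion constant statistically compatible with the 0.1030 nm²/ns used to
generate the walkers (the across-walker spread is the quoted uncertainty).

A command-line interface mirrors the library:

```sh
adsorbkit simulate --preset beta-sheet --seed 3 --out sim/
adsorbkit contacts --traj sim/system.gro --surface 0.0 --cutoff 0.35 --out contacts.tsv
adsorbkit run --preset paper-synthetic --seed 7 --out report/
```

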