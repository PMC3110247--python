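# Methods

## Surface model and unit conventions

The adsorbing surface is an ideal plane (or two parallel planes for slab
setups) normal to *z*.  All criteria in this package are pure
distance-to-plane thresholds, so the metal lattice is never read; when
configs are built from real systems, the *z* of the topmost metal atom
layer is the natural plane origin, and `AnalysisConfig.surface_z0` records
whichever convention was chosen, because the literature does not fix one
(topmost nuclei vs. effective surface).  There is no minimum-image
treatment in *z*: in slab geometry the *x,y* periodicity is irrelevant to
every metric computed here.  Units are nm, ns and kJ/mol throughout; the
only conversions (Å→nm for PDB/XYZ, ps→ns for mdtraj times) live in the
readers.  A convenient identity used by the diffusion module:
10⁻⁵ cm²/s = 1 nm²/ns exactly, so diffusion constants quoted in the
customary CGS-derived unit carry the same numeric value internally.

## Contact criteria

An *atomic contact* is Δz < 0.35 nm, strict inequality; hydrogens count by
default ("any atom" semantics), with an `include_hydrogens` switch and an
`atom_subset` argument for heavy-atom-only counting.  A residue's *first
contact* uses the closest atom of the residue and the tighter 0.3 nm
cutoff.  Equality at the cutoff is no contact; both cutoffs are
configurable.  The per-residue distance map is normalized as
v = clip(dz_ref/Δz, 0, 1) with dz_ref the global minimum distance observed
over the whole trajectory and all residues (v = 1 at the closest approach
ever seen, v→0 at infinity); dz_ref is configurable and always reported in
the output, since "1.0 corresponds to the minimum distance" admits
per-residue and global readings and we fix the global one.

When first-contact tables from several simulations are aggregated by
residue type, the (type, sim) cell is the *earliest* first contact among
residues of that type — the aggregation that turns per-residue tables into
one number per type per run — with a per-residue-mean variant behind
`cell_statistic="mean"`.  Absent cells (no residue of the type contacted in
that run) are excluded from the per-type mean; a type absent everywhere has
an absent mean.  This absent-cell handling is forced by consistency: the
bundled reference matrix reproduces its published row averages only when
blanks are excluded rather than zero-filled.

## Adsorption-phase segmentation

The contact-number curve is smoothed with a centered moving average
(window 1 ns, truncated at the edges) and segmented by a piecewise-linear
changepoint fit:

1. The noise scale is estimated robustly as σ² = (1.4826·MAD(Δy))²/2 from
   first differences of the raw series, divided by the window length for
   the smoothed series, floored at 10⁻¹⁰·max(var, 1) so noise-free input
   still segments.
2. Changepoints come from exact optimal partitioning (dynamic programming)
   with per-segment line SSE in O(1) via prefix sums, penalty
   β = 12·log(m) per segment on a half-window-decimated grid (decimation
   keeps the DP cheap and the decimated noise nearly independent; the
   edge-shrunken smoothing region is excluded so truncated windows cannot
   fake changepoints).
3. A slope knot smeared by the smoothing window can be cut twice (the
   smoothed curve is a short quadratic blend there); cuts closer than 1.5
   windows are merged to their midpoint, and each boundary is then
   localized on the *raw* series by sliding it within half a window to
   minimize the two-line SSE.  On noise-free piecewise-linear input this
   recovers the knots exactly.
4. Segments are labeled by slope class: a leading segment whose mean is
   below 5 % of the series maximum is *approach* (a count series' noise is
   clipped at zero, so the pre-contact baseline is small but positive);
   then slope ≥ 50 contacts/ns is *cooperative jump*, |slope| ≤ 5
   contacts/ns is *plateau*, anything else *gradual increase*.  The slope
   thresholds are configuration, not physics: no published algorithm
   exists for these labels, only the described four-phase phenomenology,
   so the defaults are chosen to separate the scripted regimes by an order
   of magnitude on either side.

A constant series yields a single plateau segment.

## Arginine orientation

The guanidinium group is the planar CZ(NE)(NH1)(NH2) moiety.  "All the
C–N bonds" is interpreted as the three CZ–N bonds — they span the
guanidinium plane; the NE–CD bond belongs to the stalk, not the plane.
Bond vectors are taken from CZ toward each N; the bond–plane angle is
arcsin(|v_z|/|v|) ∈ [0°, 90°], indifferent to the vector's sign.  A
contacting Arg (any atom Δz < 0.35 nm — the looser atomic criterion, which
is the one defined for orientation maps, not the 0.3 nm first-contact
criterion) is *parallel* iff all three angles are < 30° (45° as the
standard alternative), else *perpendicular*.  The *first contact event* of
an Arg is its first frame out of `no_contact`; re-contacts after
desorption are not separate events (desorption is not observed in the
regimes of interest, and no published definition of an event's end
exists).  Widening the threshold can only reclassify perpendicular →
parallel, so the perpendicular-at-first-contact fraction is non-increasing
in the threshold — asserted as a property test.

## Energy processing

Raw component energies (sampled every 0.2 ps in production use; the
generator defaults to coarser grids where full scale adds nothing) are
turned into adsorption energies by subtracting, per component, the mean
over [t₀, t₀+1 ns) — the pre-contact baseline.  Whether "the first
nanosecond" starts at t = 0 or after an equilibration offset is a run
convention; the window start is simply the first sample's time, and the
config records it.  Smoothing is a centered moving average with the window
truncated (never padded) at the edges — padding would fabricate data at
t = 0.  The bonded component is opaque and already includes the
intramolecular 1–4 LJ/Coulomb terms; no re-splitting is attempted, no
entropic term is ever estimated, and the total is validated to equal the
component sum to 10⁻⁶ relative.  Contact–energy correlation resamples the
energy onto the contact frames by nearest-time matching (energies are
sampled ~10³× faster than frames) and reports Pearson r plus a ±5 ns lag
profile; constant inputs yield an explicitly absent r.

## Domain metrics

Per-domain and whole-protein Cα RMSD each come from an independent
least-squares rigid superposition (Kabsch, SVD with the determinant
correction excluding reflections, equal weights — no mass weighting) onto
a reference frame, by default frame 0 (the relaxed start).  The
binding-site dihedral takes p1 = Cα centroid of the primary site (e.g. an
RGD loop), p2/p3 = two anchor residues' Cα, p4 = Cα centroid of the
secondary (synergy) site, with the IUPAC sign convention (verified against
mdtraj).  The anchors are not canonical — no published choice exists — so
they are mandatory configuration; the synthetic fixture uses the two
linker residues joining its domains, which makes the dihedral shift under
a hinge rotation equal the hinge angle by construction.  Distribution
comparisons use the circular mean and circular standard deviation
(scipy, period 360°): width_ratio = σ_circ(adsorbed)/σ_circ(free) < 1
means narrowing; the mean shift is the signed minimal difference on the
circle.  A histogram-free width metric was chosen because "narrowing" is
the claim of interest and σ_circ is its minimal sufficient summary.

## Diffusion

MSD(τ) is the time-averaged ⟨|r(t+τ)−r(t)|²⟩ over all valid origins,
computed with the standard FFT autocorrelation algorithm (cross-checked
against the naive double loop in tests).  D is the OLS slope / 6 over a
fit range defaulting to 10–50 % of the maximum lag — long lags are poorly
averaged — and the uncertainty is the standard deviation of per-walker
fits (block averaging over contiguous lag blocks is the fallback for a
single trajectory).  A negative fitted slope clamps D to 0 with a warning
flag.  The factor 6 (3D Einstein relation) is pinned by the published
(D, L) pair: L = √(6Dt) reproduces 0.786 nm from 0.1031 nm²/ns at 1 ns to
the printed precision.  t = d²/6D gives the diffusion-limit expectation a
first-contact time is compared against ("faster/slower than diffusion
expectation").

## SASA

Shrake–Rupley with a deterministic golden-section-spiral point lattice, so
results are bit-exact across runs and platforms; probe radius 0.14 nm
(water), 960 points by default.  Neighbour culling uses a k-d tree.
Validated against the analytic sphere, the two-fused-spheres spherical-cap
closed form, and mdtraj's independent implementation.  The per-residue-
type fraction (e.g. the share of a protein's surface contributed by Arg)
divides the summed per-atom areas of that type by the total.

## The synthetic generators — what they emulate and what they don't

The generators produce *scripted kinematics*, not physics: no force field,
no thermostat, no water.  What they share with real adsorption
trajectories is the *statistical structure* the analyses must detect:

* `make_beta_sheet_system` — a rigid idealized anti-parallel β-sheet
  (0.35 nm Cα spacing along the strand, 0.48 nm between strands,
  alternating strand direction), 16 chains of the 16-residue RAD16II
  sequence RARADADARARADADA with ACE/NAC caps, coarse pseudo-side-chains
  except the explicit Arg guanidinium quartet (the only internal geometry
  any metric needs).  Residue minimum distances are steered exactly:
  contact at 0.15 nm, detached ≥ 0.6 nm, 0.5-ns attach ramps; jitter is a
  per-residue rigid z-shift clipped to preserve the scripted contact
  state, so the ledger (per-frame attachment, first contacts, Arg states,
  phase boundaries) is exact rather than approximate.  The default
  schedule puts the first contact at 3 ns, spreads chain 0 over 3–23 ns
  with arginines leading, holds a plateau, zips chain 1 on cooperatively
  over 58–60 ns and trickles chain 2 on afterwards, over a 100-ns span at
  25-ps frames; 10 % of attaching Args land already flat, the rest arrive
  upright and flatten 2 ns after touchdown.  The initial detachment height
  stands in for the water layer that separates peptide from surface at
  t = 0.  What it does *not* emulate: backbone internal dynamics,
  desorption, competing adsorption geometries, or any energetics of the
  contact itself — so passing tests certify the *analysis*, not any claim
  about real peptides.
* `make_two_domain_protein` — two rigid helical Cα domains joined by a
  2-residue linker, global random-walk tumbling (rotation and translation
  per frame), and an instantaneous hinge: at the hinge time domain 2 snaps
  to an orientation rotated by the hinge angle about the axis through the
  linker Cαs.  Per-domain RMSD is identically ~0 (float noise), the
  whole-protein RMSD steps up at the hinge, and the binding-site dihedral
  shifts by exactly the hinge angle.  Real domain reorientation is
  gradual; the step fixture isolates the metric's contract.
* `make_brownian_walkers` — i.i.d. Gaussian increments, per-axis variance
  2 D dt; the default scale (D ≈ 0.1 nm²/ns, 100 ns of 10-ps steps, ten
  walkers) matches how protein center-of-mass diffusion in water is
  measured.
* `make_energy_series` — LJ and Coulomb drop linearly with the scripted
  contact count, the bonded term drifts upward (internal strain as the
  molecule maximizes surface contact), with an optional pre-jump
  electrostatic dip (Coulomb down, bonded+LJ up, net positive total
  fluctuation) and additive Gaussian noise; the noiseless series is the
  ledger.  With the noise at zero, the processing chain must reproduce the
  ledger exactly (baseline identity everywhere; smoothing exact outside
  half a window of slope knots, where a moving average of a linear
  function is the function itself).

Determinism: all randomness flows through `numpy.random.default_rng(seed)`;
identical seeds give bit-identical outputs, which the pipeline inherits
(byte-identical report bundles under a fixed seed and config).

## Numerical choices and degenerate inputs

* Strict `<` at every contact cutoff (boundary equality is no contact).
* Kabsch requires ≥ 3 non-collinear points; reflections are never
  returned; rank-deficient input raises.
* Dihedrals are undefined for collinear p2–p3 with a flanking point —
  raised as a domain error, never silently NaN.
* Atoms escaping a two-plane slab are flagged, not clipped.
* `expected_diffusion_time` at D = 0 returns an explicit absent value
  (None), not infinity.
* Aggregation means skip absent cells; an all-absent type yields an
  absent mean.
* The LEU-style half-ulp case: a printed 2-dp average can sit exactly
  0.005 from the exact mean (round-half-up), so printed-value comparisons
  carry a 1-ulp epsilon.

## Problem sizes used in the test suite

The validation suite runs the β-sheet generator at 4 chains / 20 ns / 50-ps
frames and the two-domain fixture at 100 ns / 100-ps frames — scales chosen
so each property under test (ledger agreement, threshold monotonicity,
hinge response) is exercised with comfortable statistics while the whole
suite stays interactive.  The phase-detection and diffusion studies run at
the full 100-ns schedule (the changepoint and MSD statistics are the point
there); the diffusion recovery uses the full ten-walker protocol.

## Known limitations

* The surface is geometrically ideal: no curvature, no atomistic
  corrugation, no position-dependent diffusion near the wall.
* Energies are consumed as given; force-field terms are never re-evaluated
  and the image-charge polarization contribution is outside scope.
* Orientation analysis is defined only for arginine's guanidinium; other
  planar side chains (His, Trp, ...) would need their own bond sets.
* Binary trajectory formats (XTC/DCD) are not read; converting to
  multi-frame GRO/PDB upstream is assumed.
* Phase labels depend on slope thresholds; curves whose "gradual" phases
  are slower than 5 contacts/ns will be labeled plateau.
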