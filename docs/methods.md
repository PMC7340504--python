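# Methods

## The quantification problem

smFISH labels each mRNA species with dozens of tandem fluorescent
oligo probes, so a mature transcript images as a diffraction-limited
spot of stereotyped intensity, and a transcribing gene images as a
brighter nuclear spot whose integrated intensity is (approximately)
the number of nascent transcripts times the single-mRNA intensity.
The package turns 3D confocal stacks (or synthetic stand-ins) into
per-cell counts and per-position statistics, and provides a matched
stochastic model so that measured spatial trends in transcription-
site frequency and nascent content can be interpreted in terms of
burst size versus burst frequency.

Default acquisition calibration: 76 nm x-y pixels, 345 nm z-spacing,
12-bit intensities; a 600 nm diffraction-limited spot is therefore
8 pixels across, which fixes the minimum 2D object size.

## Spot segmentation

Detection is deliberately threshold-and-components, with no PSF
fitting:

1. **Plateau threshold selection.** A grid of cutoffs is applied to
   the whole stack; for each, the number of connected 2D components
   with ≥ `min_pixels` (8) above-cutoff pixels is summed over
   sections. True spots produce a range of cutoffs over which this
   count is stable; background produces a steeply falling count.
   The plateau is detected as a run of ≥ 3 consecutive steps with
   relative count change below 2% per step and count ≥ 10 objects,
   and the selected cutoff is the run's midpoint. When bright
   transcription sites are present the count curve has a *second*,
   lower flat regime at high cutoffs where only sites survive; among
   qualifying runs the one with the highest mean count is therefore
   selected (the single-mRNA plateau always dominates in object
   number). A stack with no qualifying run fails QC and is excluded
   rather than defaulted — on real data this corresponds to
   insufficient signal-to-background.
2. **2D objects.** Components use 8-connectivity (configurable);
   centroids are pixel-means (subpixel, 0-based, pixel-centered).
3. **2D → 3D linking.** Objects in adjacent sections link when their
   x-y centroids are within 4 px (the diffraction radius). An object
   is recorded as a spot iff it has ≥ 1 link and is larger than all
   linked partners; ties break deterministically by (z, y, x). This
   counts a spot once even though it appears in 2–3 consecutive
   sections. Non-maximal objects attach to their nearest recorded
   maximum (graph distance, ties to the earlier spot), so member
   sets are disjoint; chains spanning > 3 sections are flagged
   `long_chain` but kept.
4. **Intensity.** The sum over a fixed circle of radius 4 px about
   the centroid, in the representative (largest-object) section
   only — the across-sections alternative is deliberately not used
   because spot z-geometry is variable. The fixed area decouples
   intensity from the cutoff choice. Disks clipped at the x-y border
   are summed over the clipped area and flagged.

## Transcription sites and nascent units

Bright sites are mishandled by mature-spot linking (their largest
section is not always their brightest), so sites are re-segmented
independently at a higher pixel cutoff. The mature "intensity" being
multiplied by the 2.5 factor is interpreted as the median *peak
pixel* brightness of mature spots, measured above background:

    site cutoff = bg + 2.5 × (median mature peak − bg)

with `bg` the stack's median pixel value (spots occupy a negligible
voxel fraction). A literal reading — 2.5 × the radius-4 *integrated*
intensity — would exceed the 12-bit pixel range and can never be a
pixel threshold, so the peak-pixel reading is adopted and documented
here. Candidate sites are linked and measured exactly like mature
spots; each site's **normalized nascent units** are its
background-corrected integrated intensity divided by the median
background-corrected mature intensity, making a site of k× mature
amplitude measure ≈ k units regardless of illumination gain (site
calling is scale-invariant by construction). Sites under 2.0 units
are discarded: the segmentation factor (2.5, a pixel cutoff) and the
detection cutoff (2.0, an integrated-intensity filter) are distinct
on purpose and both configurable.

## Virtual cells

Nuclei are segmented per 2D section by Gaussian smoothing, Otsu
thresholding with a contrast guard, and marker-based watershed with
markers spaced by the expected nuclear radius (default 32 px;
synthetic fixtures use their rendered radius). Sections stack into
3D "pancake" objects by a greedy forward pass: each object passes
its identity to its maximal-overlap partner in the next section;
partners already claimed keep their first claim, so two nuclei that
both maximally overlap one object merge chains there — a documented
behaviour of the greedy pass, not silently repaired. Single-section
objects are disregarded.

Nucleus centroids seed a polytope-bounded 3D Voronoi diagram: each
cell is the halfspace intersection of the bounding box (default: the
image volume) with the bisector planes against every other centroid.
By default the diagram is computed in physical units (z stretched by
345/76 ≈ 4.54) so "nearest" means nearest in real space despite
anisotropic voxels; pixel-unit diagrams are a flag away and tested.
Duplicate centroids merge with a warning. Assignment is a facet test
per cell in index order (a point on a shared facet goes to the
lowest nucleus index); points outside the box are dropped and
counted. Cell volumes provably tile the box, and interior assignment
equals the brute-force nearest-centroid rule — both are tested.
Local assignment errors are expected (RNAs cross bisectors); the
statistics are computed at the per-bin level where trends over
hundreds of cells are robust.

## Spatial statistics

Cells are partitioned by nuclear-centroid distance from a
user-supplied landmark (the DV-midline y or the pouch-border x;
landmark detection from images is out of scope) into half-open bins
[kw, (k+1)w), w = 64 px ≈ one nuclear diameter; the DV axis tracks
dorsal and ventral sides separately. Replicates are registered by
integer bin offsets minimizing the mean squared difference of
overlapping mRNA-sum profiles (an automated surrogate for manual
alignment; squared difference rather than correlation because
monotone gradient profiles correlate highly at every shift); flat
profiles warn and take offset 0; pooling merges cells of overlapping
aligned bins.

Per bin: median mRNAs/cell and median nascent units (medians because
the distributions are long-tailed), the fraction of cells with ≥ 1
site — with the denominator either all cells or only mRNA-containing
cells, both conventions exposed as explicit modes since both appear
in tissue analyses — and the Fano factor (variance/mean; 1 for a
Poisson birth-death process, > 1 for bursty transcription). The
nascent median is suppressed when < 5% of the bin's cells carry a
site. Confidence intervals are 95% bias-corrected-and-accelerated
(BCa) bootstrap intervals, 10,000 resamples by default, seeded;
all-equal samples collapse to a zero-width interval. The fraction of
cells with a site, regressed on per-cell mRNA count bins by
unweighted least squares, yields the slope (with parametric 95% CI)
that discriminates frequency from size modulation. One nuance the
simulator exposes: even within a single constant-rate population a
cell's mRNA count and its site flag are positively coupled, because
the count integrates ~1/k_deg ≈ 25 min of the same promoter
trajectory whose last ~τ_elong determines the site. The correct
null for "site frequency is unrelated to expression" is therefore a
permutation of site flags across cells (slope CI covering 0), not a
constant-rate simulation, and that is how the regression is tested.
No multiple-testing adjustment is applied; intervals, not adjusted
p-values, are reported.

## The telegraph model

States are (N_m, N_g): mRNA count and active gene copies
(N_g ≤ N_g_tot, default 1). Transitions: activation
k_on·(N_g_tot−N_g), inactivation k_off·N_g, initiation k_ini·N_g,
decay k_deg·N_m, with k_deg fixed at 0.04 min⁻¹ (the experimentally
measured *sens* decay rate). Sweep ranges are constrained to
literature-anchored bounds (k_ini 0.2–60, k_on 0.008–38, k_off
0.016–20 min⁻¹). Simulation is the exact SSA: waiting times
exponential in the total propensity, events chosen proportional to
their rates, starting from zero mRNA with the promoter OFF, 10⁴
events per run (doubling the event count changes summary statistics
by less than Monte-Carlo noise, which is tested). An initiated
transcript enters the decaying mature pool immediately — the model
has no elongation delay on N_m — and nascent signal is a post-hoc
relabelling of recent initiations.

**Sampling convention.** The state immediately after the N-th
*event* samples the embedded jump chain, whose stationary law
weights each state by its total propensity; it is measurably biased
against the master equation (≈ +16% in the mean for a typical bursty
triple). The recorded outcome is therefore the state occupied at a
uniformly drawn time in the second half of the trajectory, an
asymptotically exact stationary sample; the end-of-run convention
remains available as `record="end"`. For distribution-level checks,
`occupation_distribution` pools the time-weighted occupancy of the
second half of each trajectory — the natural ergodic estimator,
whose Monte-Carlo floor is far below a per-run endpoint sample's.
The truncated master equation (state space up to mean + 12 sd,
stationary vector by sparse solve) is the independent oracle: the
closed-form mean and Fano factor are verified against it to < 10⁻⁵
relative error before being used as test oracles, and the SSA
occupancy matches it to total-variation distance < 0.02 across slow,
fast and asymmetric switching regimes.

**Nascent weighting.** For each gene, τ_elong (5′-most probe site to
3′ end; tabulated: brk 1.35, dad 2.05, sens 5.15, salm 5.30, omb
3.05 min at 1100 nt/min) and τ_probe (across the probe region)
convert initiation ages a = T − t into probe fluorescence: 0.5 units
for a < τ_probe (probe region partially transcribed — the
deterministic ensemble expectation rather than a per-molecule coin
flip), 1.0 for τ_probe ≤ a < τ_elong, 0 once mature. τ_probe is not
tabulated and defaults to 0.8·τ_elong (probe sets tile most of the
measured region); it is configurable. Independent simulations are
randomly disjointly paired to mimic the two physically paired
alleles; a pair with summed units ≥ 2.0 (boundary inclusive) is a
detected site. Detection fractions and the median nascent units
among detected pairs are reported per parameter value (≥ 1000 pairs
each); sweeps of k_ini versus k_on at fixed complements produce the
size-versus-frequency discrimination signatures, and a (size,
frequency) grid maps the detection phase diagram. Grids map to rate
triples via a fixed k_on/k_off ratio ρ (default 1):
k_off = f(1+ρ)/ρ, k_on = ρ·k_off, k_ini = size·k_off; infeasible
grid points (rates outside the literature bounds) are marked, not
simulated. The k_on sweep range is chosen so detection fractions
span the experimentally observed window (up to ~50% of cells); well
beyond it (k_on ≳ k_off) bursts merge and nascent content rises for
trivial reasons.

## Synthetic scenes

The generator emulates what the pipeline assumes about real stacks:
a large population of near-uniform mature spots (amplitude CV 5%), a
smaller separable population of brighter sites (≥ 2.5× mature,
variable) confined to nuclei, nuclei as non-overlapping disks
stacked through z, constant background (default 100) with additive
Gaussian noise (σ = 4) standing in for shot noise, and 12-bit
clipping. Rendering is bit-deterministic for a fixed spec + seed.
The lateral PSF is Gaussian (σ from the 600 nm FWHM ≈ 3.35 px).
Axially, a pure Gaussian profile would make each spot's side
sections fade *continuously* with the cutoff, and the object-count
curve would have no plateau at all; real 700 nm-thick sections at
345 nm spacing instead capture an axially confined emitter almost
completely or almost not at all. The axial profile is therefore a
flat-topped "section capture" weight: full amplitude (with a 7%
roll-off) within 1.25 sections of the spot center, zero beyond,
placing each spot in 2–3 consecutive sections with a clean count
plateau. Spots keep a minimum lateral separation (16 px by default;
closer pairs would merge at plateau cutoffs) unless separated by
≥ 4 sections in z; requests that cannot be placed raise an
infeasibility error rather than silently overlapping. With an
expression profile (expected mRNAs per cell as a function of nucleus
position), per-cell counts are Poisson draws scattered around the
nucleus, still respecting separation (unplaceable RNAs are dropped
and the truth records what rendered), and site-hosting nuclei are
sampled with probability proportional to the local profile —
frequency modulation, matching the biology the pipeline is meant to
detect.

What the generator does *not* emulate: probe-hybridization
chemistry, bleaching, stage drift (drifted samples fail QC in real
workflows), pseudostratified cell geometry, overlapping/clumped
RNAs at biological densities, or realistic background texture.
Passing tests therefore demonstrate the correctness of the
algorithms under the stated optical model, not detection performance
on real tissue; background level and noise variance are not
documented for real stacks and fixture defaults are chosen for clean
separability.

## Problem sizes and numerics

The test suite and the acceptance script run on one CPU in a few
minutes: distribution checks use 10⁴ trajectories of 10⁴ events
(numba-compiled SSA core, per-run seeds derived from one root seed
so any batch slice is reproducible); sweeps use 1000 pairs per value
on 8-value grids; the dense segmentation benchmark renders 4066
mature RNAs and 103 sites in a 20 × 1024 × 1024 stack; nucleus
recovery uses a 50-nucleus field. Halfspace intersections get an
interior point nudged 10⁻⁷ of the box extent inward so centroids on
box faces remain strictly interior; Voronoi facet tests use a 10⁻⁹
tolerance; bootstrap statistics use the vectorized path when the
statistic accepts an `axis` argument. Pipeline outputs embed the
config hash (scientific parameters only, output path excluded) and
root seed, and identical config + seed reproduce byte-identical
CSVs.

## Known limitations

- The greedy nucleus-stacking pass can merge two nuclei through a
  shared maximal-overlap partner; first claim wins deterministically
  and the behaviour is documented rather than repaired.
- Site intensity is measured in one section; extremely elongated
  sites spanning many sections would be underestimated.
- Registration assumes replicate profiles are translates; profiles
  whose shape genuinely differs (e.g. a peak folded at the image
  edge) register approximately.
- The nascent-weighting 0.5 is an ensemble expectation; per-molecule
  stochastic weighting would widen the nascent-unit distribution
  slightly without moving its mean.
- No rate inference from data is attempted; the model is compared to
  measurements at the level of qualitative signatures, which is how
  the burst-frequency conclusion is drawn.
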