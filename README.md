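# burstfish

Quantification of single-molecule FISH (smFISH) image stacks of
developing tissue, and stochastic modelling of the transcriptional
bursting that underlies them.

smFISH renders every mature mRNA as a diffraction-limited fluorescent
spot and every active transcription site as a brighter nuclear spot
whose intensity counts the nascent transcripts on the gene. In a
tissue patterned by morphogen gradients (the *Drosophila* wing
imaginal disc is the motivating system), quantifying both per cell
and per position lets one ask *how* graded expression is produced: by
bigger transcriptional bursts, or by more frequent ones. `burstfish`
implements both halves of that analysis:

**Image quantification.** Spots are detected as thresholded connected
components: an intensity cutoff is chosen automatically inside the
*plateau* of the 2D-object-count curve (the regime where detected
object number is insensitive to the cutoff), 2D objects of ≥ 8 pixels
(the 600 nm diffraction limit at 76 nm pixels) are linked across
adjacent z-sections (centroids within 4 px; a genuine spot spans 2–3
consecutive 345 nm sections; only the largest member object is
recorded), and intensity is integrated over a fixed radius-4 circle.
Transcription sites are re-segmented at 2.5× the median mature-spot
brightness and expressed in *normalized nascent units* (multiples of
the median single-mRNA intensity); sites under 2.0 units are not
reported. Nuclei are segmented per section, stacked into 3D by
maximal overlap, and their centroids seed a polytope-bounded 3D
Voronoi tessellation that assigns every RNA to its nearest nucleus —
a virtual cell. Cells are binned at 64 px (≈ one nuclear diameter)
along a developmental axis; replicates are registered by their mRNA
profiles and pooled; bins report median mRNAs/cell, fraction of cells
with a site, median nascent units, and the Fano factor, with 95% BCa
bootstrap intervals.

**Bursting model.** The two-state (telegraph) model: a promoter
switches OFF→ON at rate $k_{on}$ and ON→OFF at $k_{off}$ (min⁻¹);
while ON, transcripts initiate at $k_{ini}$; mRNA decays at
$k_{deg}$ = 0.04 min⁻¹. Burst size is $k_{ini}/k_{off}$ transcripts,
burst frequency $(k_{on}^{-1}+k_{off}^{-1})^{-1}$ min⁻¹. Exact
Gillespie simulation (10⁴ events per run) yields mature mRNA counts
and — from initiation timestamps and gene-specific elongation times
at 1100 nt/min — weighted nascent signal per allele: an initiation
younger than $\tau_{probe}$ contributes 0.5 probe-fluorescence units,
one younger than $\tau_{elong}$ contributes 1.0. Pairs of simulations
mimic the two physically paired alleles of a nucleus; a pair with
≥ 2.0 summed units is a detected transcription site, the same cutoff
the imaging side applies. Parameter sweeps separate the two control
modes: varying $k_{ini}$ (burst size) drags nascent content up with
detection frequency, varying $k_{on}$ (burst frequency) moves
detection frequency while nascent content stays flat — the signature
by which graded expression can be attributed to burst-frequency
modulation.

A synthetic-scene generator (`burstfish.synthetic`) renders
ground-truthed two-channel stacks — uniform-intensity mature spots,
brighter variable sites inside nuclei, "pancake" nuclei, 12-bit
noise — so the entire pipeline is testable without any download, and
a truncated master-equation solver provides an independent oracle for
the simulator.

## Worked example

```sh
python examples/05_telegraph_model.py
```

prints (abridged):

```
burst size 4.0 transcripts, frequency 0.167/min
mean mRNA 16.93 (closed form 16.67); Fano 3.72 (closed form 3.69)
SSA vs master equation: TV distance 0.0017

burst-size modulation (k_ini swept, frequency fixed):
  k_ini   2.89: detected 0.28  median nascent   3.0
  k_ini  16.65: detected 0.60  median nascent  10.0
  k_ini  40.00: detected 0.62  median nascent  22.0
burst-frequency modulation (k_on swept, size fixed at 4):
  k_on  0.010: detected 0.02  median nascent   2.5
  k_on  0.131: detected 0.27  median nascent   3.5
  k_on  0.250: detected 0.45  median nascent   3.5
```

The simulated stationary mean and Fano factor match the closed forms
$\bar N = \frac{k_{on}}{k_{on}+k_{off}}\frac{k_{ini}}{k_{deg}}$ and
$1 + \frac{k_{ini}k_{off}}{(k_{on}+k_{off})(k_{deg}+k_{on}+k_{off})}$,
and the empirical stationary distribution agrees with the master
equation to a total-variation distance of 0.002. In the sweeps, only
burst-*size* modulation couples the nascent-RNA content of detected
sites to the detection frequency (3.0 → 22.0 units); under
burst-*frequency* modulation the content holds at ≈ 3.5 units while
detection rises twenty-fold — so flat nascent content across a
spatial expression gradient implicates frequency control.

The other examples exercise the imaging half; e.g.
`python examples/01_render_and_segment.py` prints

```
plateau: cutoffs 120..330 (selected 220)
detected 301 spots, rendered 300 (0.3% off)
```

and `examples/03_virtual_cells.py` shows the Voronoi tessellation
tiling the imaged volume exactly and assigning 98% of RNAs to their
true cell. The `burstfish` command exposes the same stages as
subcommands (`synth`, `segment`, `cells`, `stats`, `simulate`,
`run`).

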