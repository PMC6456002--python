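# Methods

## Scope

`atpfret` quantifies dual-channel (CFP/YFP) recordings of genetically
encoded FRET ATP sensors targeted to the cytosol, the mitochondrial matrix
and the ER lumen, and condenses each cell's recording into the scalar
features used to phenotype metabolic settings: basal ratio, transient peak
after hexose withdrawal, onset of decrease, depletion minimum, maximal
signed changes in protocol windows, and peak width. A two-axis fingerprint
(maximal mitochondrial change on glucose removal vs on oligomycin)
classifies cells as glycolytic, oxidative or intermediate. Because no public
recordings accompany this problem class, the package ships its own
synthetic-data generator — a compartmental bioenergetics model plus a
fluorescence forward model — so every part of the chain is testable end to
end against known ground truth.

## Bioenergetics model

Seven state variables per cell: intracellular free hexose split into a
metabolizable (glucose) and a non-metabolizable (mannose / 2-deoxyglucose)
pool, the corresponding hexose-6-phosphate (H6P) pools, and ATP in cytosol,
matrix and ER (mM). The perfusion protocol drives piecewise-constant
external conditions (hexose identity and concentration, oligomycin,
antimycin A).

Fluxes:

* hexose transport `v_glut * (hexose_ext - hexose_in)` (facilitated
  diffusion, first order);
* reversible hexokinase `v_HK = k_hk_f*hexose*ATP_m - k_hk_r*H6P*ADP_m`,
  mass action on both sides. The enzyme is coupled to the *matrix* ATP pool
  (the outer-membrane/VDAC coupling hypothesis); a `hk_atp_source='cyto'`
  switch reroutes it to the cytosol for sensitivity analysis. H6P pools are
  tagged by the hexose that produced them: only the glucose-derived pool
  feeds glycolysis, and a mannose-derived pool left behind after a buffer
  switch remains available to the reverse reaction — this reservoir is what
  fuels the transient matrix-ATP peak on hexose withdrawal;
* glycolysis `v_glyc = k_gly * H6P_glc`, yielding `y_atp` cytosolic ATP per
  H6P. `y_atp` is an *effective* yield: it lumps all production downstream
  of H6P, including mitochondrial oxidation of glycolytic pyruvate, into one
  term, which is why its calibrated value is larger than the textbook
  stoichiometry. 2-DG in the bath sets `k_gly = 0` (glycolysis poisoned);
* ANT exchange down the adenine-occupancy gradient,
  `k_ant * a_tot_m * (ATP_c/a_tot_c - ATP_m/a_tot_m)`;
* ATP synthase `s_oligo * (v_ox * s_anti * ADP_m/a_tot_m - k_hyd * ATP_m)`:
  forward OXPHOS production vs reverse-mode hydrolysis. Oligomycin blocks
  both directions (`s_oligo = 0`); antimycin A abolishes only the
  respiratory production (`s_anti = 0`);
* linear compartment consumption (`k_cons_c`, `k_cons_m`), linear ER
  import/consumption (`k_er_in`, `k_er_cons`), and a small hexose-independent
  cytosolic production `v_base_c * ADP_c/a_tot_c` standing in for the
  energy-stress response (AMPK-activated fallback substrates) that keeps
  cytosolic ATP from collapsing outright during starvation.

ADP is implicit via conservation (`ADP_x = a_tot_x - ATP_x`, floored at
zero). Every phosphorylating flux carries the free-adenine factor
`ADP_x/a_tot_x`; without it the linear model admits runaway solutions and
cannot honor the pool caps. With it, `0 <= ATP_x <= a_tot_x` is an exact
dynamical invariant and the basal state is unique and attracting. Membrane
potential and pH are not modeled.

### Archetypes and calibration

No rate constants for this system are published; the five named archetypes
(`hela_like`, `beta_like`, `mef_young_like`, `mef_old_like`,
`mfn2_ko_like`) are **calibrated, not measured**. Calibration targets were
qualitative: basal ATP around 4.5 / 2 / 0.9 mM (cytosol / matrix / ER) for
the glycolytic archetype; a transient matrix-ATP peak on hexose withdrawal
that shrinks superlinearly with hexokinase activity and fades over repeated
depletions; depletion depth ordering 2-DG < mannose < plain removal;
reverse-mode synthase in glycolytic cells (oligomycin raises matrix ATP)
and forward mode in oxidative ones (oligomycin depletes it). Two structural
facts shaped the calibration and are worth recording:

* At quasi-steady state the matrix pool tracks the cytosolic pool, so the
  *relative* depletion of the two compartments is similar at the ATP level.
  The much larger mitochondrial *ratio* response seen in recordings is
  produced jointly by deeper matrix depletion and the sensor operating
  points (below).
* The transient withdrawal peak has two additive sources in this model:
  release of the hexokinase's standing demand on matrix ATP, and net
  reverse flux from the H6P reservoir. Both vanish when hexokinase rates
  are scaled to zero.

Cell-to-cell variability multiplies every rate parameter by an independent
log-normal factor with median 1 and CV 0.3 (pool sizes and the yield stay
fixed), matching the strong heterogeneity of single-cell responses.

## Fluorescence forward model

Sensor occupancy follows a Hill curve `f = ATP^h / (Kd^h + ATP^h)` with
`h = 2`. Channel means per frame:

    CFP = g_c * E * (1 - kappa*f) * exp(-k_d t) + bg_c
    YFP = g_y * E * (gamma + f)  * exp(-k_a t) + bg_y

with expression level `E`, donor-quench depth `kappa = 0.7`, acceptor
baseline `gamma = 0.2`, per-channel bleach rates and additive Gaussian read
noise (default 5 counts on ~1000-count signals, about 1% ratio noise per
frame; Gaussian rather than Poisson keeps closed-form SEM checks exact).
The YFP/CFP ratio is independent of `E` — the ratiometric property the
sensors are built for — and the pipeline inherits that invariance end to
end.

Apparent affinities are deliberate design choices, not measurements: the
cytosolic sensor (`Kd = 1.3 mM`) sits near saturation at basal cytosolic
ATP, compressing cytosolic changes; the mitochondrial sensor (`Kd = 2 mM`)
sits mid-dynamic-range where protocol responses are largest; the ER sensor
(`Kd = 1 mM`) reports the low-ATP lumen. This placement, together with the
deeper matrix depletion, reproduces the compartment ordering of maximal
normalized changes (mito > cyto >= ER).

Synthetic image stacks draw each cell as a uniform ellipse (axes TCYX in
TIFF exports, channel 0 = CFP) with per-pixel noise; ground-truth masks and
traces ride along for segmentation and extraction tests. Colocalization
fixtures place uniform-intensity signal supports with a known shared pixel
fraction.

## Quantification chain

Fixed order, enforced through provenance tags: per-channel background
subtraction -> YFP/CFP ratio -> optional photobleach correction ->
normalization to the mean over the final 60 s before the first stimulus.
Frames with non-positive corrected intensity are flagged invalid and ignored
downstream, never interpolated. ROI traces from stacks use Otsu thresholding
of the temporal-mean image, connected components, per-ROI per-frame means,
and the median of non-ROI pixels as the background estimate.

Bleach correction fits `A*exp(-k t)` (k >= 0; rates below 1e-6/s are
treated as zero) to the ratio on stimulus-free windows and divides it out,
preserving the t = 0 amplitude; a per-channel variant exists as a config
option. A practical identifiability note: a ~1e-5/s rate cannot be
estimated from a 60-s baseline at 1% noise, and the k >= 0 bound then
biases corrections upward. The default pipeline configuration therefore
leaves correction off and the validation recordings bleach-free; the
correction is validated on constant-condition recordings with trace-wide
quiescent windows, where it recovers the rate to well under 5%.

### Feature rules (package conventions)

The onset of decrease is the first time after the stimulus at which the
normalized trace is at or below `1 - max(3*sigma, 0.01)` and stays there
for 3 consecutive valid frames (threshold multiplier and persistence are
config keys). "Maximal change" is the signed excursion of largest magnitude
relative to the pre-window baseline mean. Peak width is the full width at
half maximum with linear interpolation between frames (the fraction is
configurable). The peak search ends at the onset of decrease so that a deep
late minimum cannot stand in for a missing early transient. A cell with
more than 20% invalid frames in any analysis window fails QC and is
excluded.

### Fingerprint and classification

Axes are always in normalized ratio units. `delta_glc` is the maximal
change during the hexose-free phase before any drug; `delta_oligo` the
maximal change after oligomycin relative to the 60 s preceding it. The
default rule labels a cell glycolytic when `|delta_glc| > |delta_oligo|`
and `delta_glc < -tau` (tau = 0.1), oxidative with the axes swapped, else
intermediate; a deterministic 2-means partition on standardized coordinates
is available as an alternative. The numeric rule and tau are this package's
operationalization of a distinction usually drawn by eye.

### Statistics

Two groups: unpaired Student's t test (equal variance; Welch by flag).
Three or more: one-way ANOVA followed by Tukey's HSD with p-values from the
studentized-range distribution. No further multiplicity correction.

### Colocalization

Pearson on unthresholded masked pixels. Costes thresholds: orthogonal
(total least squares) regression `ch2 = a*ch1 + b`, then `t1` scanned
downward from the channel-1 maximum (step 1 for integer images, range/1000
for float) with `t2 = a*t1 + b`, stopping at the first threshold whose
below-both pixel set has Pearson <= 0; exhausting the range returns the
minimum with a warning flag. Manders M1/M2 use the above-threshold-in-both
numerator (the common Costes-style dialect; the classic dialect is a flag).
On images with strictly two intensity levels the scan degenerates (it stops
at the foreground intensity, where nothing remains above threshold) — the
automatic threshold needs graded intensities, which the tests respect.

## Protocols and problem sizes

Named protocols begin with 300 s of 10 mM glucose. Defaults: removal
recordings 2100 s total; substitution recordings 1200 s; mannose-switch
3000 s (1800 s mannose, 900 s sugar-free); repeated depletion three 450-s
removals separated by 100-s readditions (short against the H6P refill
time); the two-phase fingerprint protocol 4800 s (3600 s glucose-free, then
900 s oligomycin). Imaging cadence is 1 s by default; population-scale
validation runs use 2-s cadence and 10-50 cells per group — sizes chosen so
a full validation cycle completes in minutes on a laptop while keeping
group statistics stable.

## What the generator does and does not emulate

Emulated: compartment-specific basal levels and kinetics; instantaneous,
uniform intracellular glucose depletion; the hexokinase-dependent transient
matrix-ATP peak with strong cell-to-cell variability; deeper depletion
under 2-DG than mannose than plain removal; fading peaks over repeated
depletions; the oligomycin dichotomy between glycolytic and oxidative
settings; expression-level variation, photobleaching, background and read
noise.

Not emulated: sub-mitochondrial ATP gradients and organelle morphology;
motion, focus drift and photochromism; membrane potential and pH (and hence
any crosstalk of those onto the sensors); Poisson photon statistics
(optional Gaussian only); competing mechanistic explanations of the
withdrawal peak other than reverse hexokinase flux (the model implements
that one mechanism and cannot exclude alternatives such as release of
pre-bound ATP); respirometry-style population measurements. Passing tests
therefore demonstrate that the pipeline correctly recovers what this model
generates — they do not certify the model as a quantitative description of
any real cell line, and none of the calibrated constants should be quoted
as measurements.

## Numerical choices

LSODA (stiff-safe) integration segment by segment with rtol 1e-8 /
atol 1e-10; output sampled on the imaging grid; states clipped to the
invariant box only within solver tolerance (violations beyond it raise).
The basal state is obtained by integrating the first segment's condition
for 40 000 s from a generic interior state — equilibration by relaxation,
mirroring the pre-incubation of a perfusion experiment, and independent of
the root-finding used to verify steady states in tests. Exponential fits
use bounded least squares with a slope-based initial rate. Random numbers
come exclusively from seeded `numpy` generators; every stochastic API takes
a seed and all pipeline seeds derive from the single `RunConfig.seed`.
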