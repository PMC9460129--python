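# Methods

## Threshold model

Each mechanoreceptor's vibrotactile detection threshold is a piecewise
straight line in (log10 frequency, dB) coordinates, `L(f) = a·log10 f + b`,
with per-receptor frequency domains: FA I [0.5, 67] Hz, FA II (20, 800] Hz
(the lower endpoint is exclusive), SA I [0.5, 120] Hz, SA II [0.5, 400] Hz.
All logarithms are base 10; the resulting Pacinian (FA II) minimum of about
−27 dB near 240 Hz matches the neurophysiological picture of Pacinian
sensitivity peaking in the low hundreds of hertz. Threshold units are taken
as dB re 1 µm peak displacement; every comparison with measured spectra
happens in that dB space, so the choice of reference amplitude only shifts
both sides equally. Outside its domain a receptor is treated as never
firing (threshold +∞, reported as NaN). The model ships as a YAML document
(`vibrotact/data/thresholds.yaml`) and is fully serialisable, so alternative
threshold sets can be swapped in.

The published coefficients are rounded to four significant digits, which
has two numerical consequences handled explicitly:

* adjacent segments of one receptor agree at their shared breakpoint only
  to within 0.05 dB; model validation enforces that bound rather than exact
  continuity;
* two *different* receptors' curves can run closer than that rounding noise
  (the FA I and SA II pieces differ by 0.01 dB below 10.13 Hz and cross
  near 14.7 Hz). Band construction therefore treats thresholds within
  0.05 dB at a frequency as tied: tied values are snapped to the group's
  lowest value, ordered by the fixed receptor order SA I, SA II, FA I,
  FA II, and kept as zero-height slabs. Without this policy a sliver-thin
  spurious firing combination ({SA I, FA I}) appears on fine frequency
  grids; with it, the model yields exactly eight combinations at every grid
  resolution, and the area reassigned by snapping is bounded by
  0.05 dB × the sliver width in decades — orders of magnitude below the 1%
  integration tolerance.

## Signal pipeline

The sensor calibration `d = −1409.4·V + 710.35` (µm per volt) is applied
elementwise; the 710.35 µm offset is a static preload, which is why the
trace mean is removed before spectral analysis and bin 0 is excluded from
all feature integration. Spectra are single-sided amplitude spectra of the
Hamming-windowed, mean-removed trace with default `n_fft = 32768` (2^15; a
3 s trace at 10 kHz gives 30 000 samples and is zero-padded). Scaling is
2/Σw — division by the window's coherent gain — so a sinusoid centred on a
bin reports its time-domain amplitude (verified to 1% in tests); DC and
Nyquist bins are not doubled. Traces longer than `n_fft` are reduced to the
central block by default (steady-state tracing), configurable. The dB view
is `20·log10(A/1 µm)` with zero amplitudes clamped to a −120 dB floor.

## Subarea features

Features are areas in (log10 f, dB) coordinates, the chart on which the
thresholds are straight lines; linear-frequency integration is available as
an option. For each spectrum bin inside [0.5, 800] Hz, the vertical column
from the lowest defined threshold up to the spectrum level is cut by the
sorted thresholds into slabs; each slab contributes height × bin width (in
decades, bin edges clipped to the band) to the area of its firing
combination. The slab (horizontal-band) decomposition is what produces all
eight labels — intermediate combinations such as SAISAII and SAIFAII arise
only as interior slabs; assigning whole columns to one combination cannot
produce them. Quadrature is per-bin rectangle evaluation at the bin centre;
at the default FFT resolution (0.305 Hz bins) this agrees with an
independent fine cell-counting oracle to well under 0.1%, so trapezoid
refinement is unnecessary. The eight features sum exactly to the total
area between spectrum and lowest threshold (conservation is a tested
invariant), and all features are zero when the spectrum never exceeds the
lowest threshold.

The earlier three-feature baseline — pool the whole column into the
receptor holding the lowest threshold at that frequency — is reconstructed
as the "legacy" method, its original formulas not being available. Worth
noting: with the packaged thresholds the lowest curve belongs to SA I on
[0.5, 20] Hz and to FA II everywhere above, so only two of the pooled bands
can be nonzero; the implementation reports all four receptor keys and the
pooled totals still equal the subarea totals exactly.

Feature screening is a one-way ANOVA per feature across samples
(repetitions as replicates, α = 0.05 by default) with Tukey HSD pairwise
comparisons as the post-hoc companion; constant features are excluded with
a warning.

## Panel analysis

Subjects are clustered by Ward linkage on Euclidean distances between their
flattened sample × word score vectors, cut at k groups (default k = 2,
mirroring the two response populations typically found in such panels).
PCA is computed per cluster on the correlation matrix of (subject, sample)
observations × words, with no rotation; components with eigenvalue > 1 are
retained (at least one always), loadings are eigenvector × √eigenvalue,
and each component's sign is fixed so its largest-|loading| word is
positive (PCA signs are otherwise arbitrary). Contribution percentages are
eigenvalue / word count × 100. The (subject, sample) observation unit is
what makes per-sample averaging of row scores well defined; those per-sample
means are the regression targets. A zero-variance word column is an error
naming the word, since the correlation matrix is undefined there.

## Regression and selection

All families are fitted by ordinary least squares with intercept.
Logarithms are base 10 throughout (the base only rescales coefficients).
The interaction family carries an independent coefficient on the product
term. Defaults: up to `p_max = 5` variables in the linear/logarithmic
subsets (leaving at least one residual degree of freedom when fitting on
seven samples) and polynomial degree up to `a_max = 3`, both configurable.
Logarithmic specs touching a non-positive feature value, rank-deficient
designs, and under-determined fits are infeasible: skipped and logged, not
errors. Reported diagnostics per fit: R², adjusted R², F-test p, per-
coefficient t-test p, and standardized coefficients
β′_j = β_j·sd(x_j)/sd(y) (computed on the design column, i.e. on log10 x
for logarithmic terms).

Selection: for every target and every (feature-method, family) cell, the
minimum leave-one-sample-out error over the cell's specs; the per-target
winner is the lowest-error spec with ties broken by fewer parameters, then
lexicographic variable names, making selection fully deterministic. The
error metric is mean squared error by default ("rmse" available and
labelled in output). The five published best-fit equations are stored with
their printed coefficients verbatim and evaluated directly by
`evaluate_frozen`; they are the only bridge to the original fitted results,
whose underlying measured data are not deposited.

## Synthetic data

The trace generator is spectral phenomenology, not contact mechanics: a
surface with spatial period λ traced at speed v excites a fundamental at
f₀ = v/λ with geometrically decaying harmonics (default rolloff 0.5 per
harmonic, 5 harmonics, random phases) over white Gaussian noise; defaults
follow the measurement conditions of 10 mm/s tracing, 3 s duration and
10 kHz sampling, with an aliasing guard on f₀ × harmonic count. Friction
coefficients default to uniform [0.2, 1.2], a plausible range for textured
plastics. The panel generator plants a low-rank word–factor model: score =
round-and-clip to 1..7 of 4 + L·g + noise, where the loading matrix L is
cluster-specific (default 35 subjects split 10/25, two clusters with
sign-flipped loadings, noise SD 0.5). What the generators do *not* emulate:
nonstationary stick-slip bursts, sensor resonances, subject response styles
(skew, end-aversion), or correlated word usage beyond the planted factors —
so passing recovery tests demonstrates the pipeline's correctness under its
own assumptions, not performance on real measurements.

Recovery studies: the planted-regression study draws per-sample feature
values log-spaced over two decades with multiplicative jitter, builds
y = β₀ + β₁ log10 D + N(0, σ) with σ = 0.01 over 8 samples, and checks that
leave-one-sample-out selection prefers the logarithmic family over the
linear one and recovers the coefficients; it operates directly on feature
tables so that 100 replicates run in seconds, while `end_to_end_recovery`
exercises the full trace → spectrum → feature → selection chain for a
single seed (8192-point FFT for the simulated 10–150 Hz fundamentals). At
small feature dynamic range a planted *linear* model can legitimately be
won by the logarithmic family (log is near-affine over a narrow range);
two decades of range separate them reliably.

## Degenerate inputs and tie-breaks, collected

* constant or zero traces → all-zero spectra → all-zero features (no error);
* spectrum below every threshold → all features zero;
* equal thresholds at a frequency → zero-height slab, receptor-order tie-break;
* k = 1 clustering → single cluster; k > number of subjects → error;
* repeated PCA eigenvalues make component directions non-identifiable
  (documented; the planted tests use unequal factor strengths for this
  reason);
* model-selection ties → fewer parameters, then variable-name order.

## Limitations

The regression operates on eight samples — one point per material — so the
search is deliberately shallow (p_max, a_max caps) and the selection metric
is a leave-one-out error rather than a held-out set. The published fitted
coefficients cannot be re-derived without the original measured traces and
panel; this package reproduces the *method* end to end and the published
constants exactly, and validates the statistical machinery on planted
synthetic ground truth.
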