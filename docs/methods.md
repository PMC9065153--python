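# Methods

This note documents the models behind `screptime`, the defaults and why
they are set where they are, what the synthetic-data generator does and
does not emulate, and the numerical choices a maintainer would otherwise
have to reverse-engineer.

## Read counting and windows

Alignments contribute to window counts only if primary, non-duplicate,
and MAPQ ≥ 30. Mates mapped on the same chromosome within 20 kb of each
other are two observations of one fragment and carry weight 0.5 each at
their own positions; otherwise each read carries weight 1. The 20-kb
mate-distance rule is keyed on start-position distance (the fragment's
outer span is not reconstructed). A read belongs to the window containing
its leftmost aligned base. Coordinates are 0-based half-open everywhere,
including BED output.

Cell barcodes (16 bp) are filtered by abundance: high-count barcodes are
those with at least 1/10 of the top barcode's count, and the acceptance
floor is 1/10 of the 95th percentile of high-count abundances (linear
interpolation between order statistics). A barcode absent from the
whitelist is corrected only when at most one base has quality < 24 and
exactly one whitelisted barcode lies at Hamming distance 1.

Windows with < 75% uniquely mappable positions are masked, with a strict
`<` comparison at the boundary.

## In silico sorting

For each cell, unmasked 20-kb windows are aggregated in runs of 50 (runs
never span chromosomes; trailing partial runs are dropped). MAPD is the
median of |adjacent aggregate differences|, again within chromosomes, and
scaled MAPD divides by √(mean aggregate count). For Poisson counts the
adjacent difference has variance 2λ, so scaled MAPD → Φ⁻¹(0.75)·√2 ≈
0.954 regardless of coverage; replication adds between-window rate
variance and raises it. An alternative reading of the statistic — the
median absolute deviation of the differences around their median — is
available via `form="mad_of_diffs"`; the default is the plain median of
absolute differences.

The (coverage, scaled MAPD) plane is fit with an EM mixture of two linear
regressions with Gaussian residuals. Initialization splits cells at the
within-coverage-bin median of scaled MAPD; nine further randomized
restarts guard against local optima and the best log-likelihood fit wins
(seeded, so deterministic). The G1/G2 component is the line predicting
the smaller scaled MAPD at the maximum observed coverage. Cells with
|residual| ≤ 0.05 from that line are labeled G1/G2 — absolute value,
because cells far *below* the line are artifacts, not S-phase cells. Two
components whose mean separation over the observed coverage range is
under 3 residual sd are flagged degenerate (single population).

The sampling noise of a median over ~3,000 aggregates (a human-genome's
worth of 20-kb windows) gives scaled MAPD a per-cell sd of ≈ 0.03, so the
0.05 residual band deliberately captures only the core of the G1/G2
cloud: the label is conservative (high purity, ~85–90% recall), and any
replicating cell that slips through is identified downstream when its
aggregate counts fit two Poisson rates at ~2:1. On genomes much smaller
than ~150,000 windows the residual rule is under-calibrated and the
downstream ratio screen does the sorting; the sort tests therefore run at
genome scale.

## G1 reference, fixed-coverage windows, CNA masking

The G1 reference aggregates G1/G2 cells in descending coverage order
until the expected mean window size, genome span ÷ (total reads / 200),
reaches 20 kb. The same 200-read windows serve per-cell counting and the
aggregate profiles. Window boundaries are emitted where the running
reference count crosses the 200-read quota, snapped to the 20-kb bin edge
where the crossing happens, and the quota resets there — so every window
carries at least 200 reference reads and less than 200 + (max bin count).
Masked fine bins contribute nothing and are spanned silently; each
chromosome's trailing remainder is dropped.

Cell-specific CNAs are masked per cell by an iterative screen on 15-window
(~300-kb) aggregates. A two-rate Poisson mixture is fit by EM, with
mixing weights floored at 0.05 so neither component can specialize to a
small aberrant region. Each aggregate is scored by its probability under
the better-fitting rate. The candidate region grows greedily from the
worst-scoring aggregate, adding one or two neighbors at a time whenever
that lowers the region's pooled tail probability (the two-step lookahead
rides over diluted aggregates at a misaligned CNA edge). Because a
legitimate region can mix replicated and unreplicated aggregates, the
pooled total is scored against every composition k·λ_low + (n−k)·λ_high
and only counts extreme under *all* compositions count as outliers. The
region is masked when that tail probability is below 10⁻⁶ and its median
aggregate score is below the genome-wide median; the procedure repeats on
the unmasked remainder until no region qualifies. Individual 20-kb
windows carry 1–5 reads at typical single-cell coverage and have no
discriminating power on their own, which is why all evidence is pooled at
aggregate scale. The screen presumes the two rates describe the cell's
2N/4N structure; a small CNA in a purely uniform (G1-like) genome can be
absorbed by the otherwise-idle second component and missed — such cells
do not enter replication inference, and residual structure is caught by
the autocorrelation gate: cells whose unmasked counts have lag-1 Pearson
autocorrelation > 0.15 (pairs never span masked gaps or chromosome ends)
are excluded. Constant counts have undefined correlation and are reported
as 0 (pass).

## Two-state Poisson HMM

Initialization fits the same two-rate mixture to 15-window aggregates. A
cell is excluded when EM fails to converge or the rate ratio is outside
[1.5, 2.5] (closed interval) — this is also what rescues mis-sorted
G1/G2 cells, whose ratio is ≈ 1. Windows start at the nearer of the two
per-window means.

The HMM has two states (unreplicated, replicated) with Poisson emissions
initialized at the aggregate rates / 15, sticky transitions (self
probability 0.99), and uniform start. Baum–Welch updates emissions,
transitions, and the start distribution (fixed-transition training is
available) with relative log-likelihood tolerance 10⁻⁶ and at most 200
iterations; the rate order λ_replicated > λ_unreplicated is enforced by
relabeling after each M step. Masked windows are missing observations:
their emission likelihood is 1 for both states, so the chain passes
through them. Decoding is by the most probable path (Viterbi); posterior
decoding is available behind a flag. If training fails to converge, the
path is decoded under the initial parameters and the cell flagged. The
recursions are written directly (scaled forward–backward, log-space
Viterbi) because off-the-shelf HMM implementations do not support
missing observations with this exact semantics; an exhaustive-enumeration
oracle in the test suite verifies optimality of decoded paths on all
instances up to 12 windows.

Post-decoding QC follows three rules: the realized mean-depth ratio of
replicated over unreplicated windows must lie in [1.5, 2.5]; the sd over
chromosomes of the mean copy state (mean of {2,4} over unmasked windows)
must not exceed 0.4; and a cell may not contain both an entirely
replicated and an entirely unreplicated chromosome ("entirely" = 100% of
unmasked windows). Across cells, a per-chromosome screen excludes a
(cell, chromosome) pair when the cell's mean state correlation with all
other cells on that chromosome is negative, or when its correlation with
one of its 10 genome-wide nearest neighbors falls below Q1 − 3·IQR of the
chromosome's pooled neighbor-correlation distribution (the outlier rule
is a package choice; it is isolated in one parameter).

States are carried to the fixed 20-kb grid by overlap-length-weighted
averaging of copy numbers; only windows whose weighted mean is exactly 2
or 4 (tolerance 10⁻⁹) keep a state, boundary-straddling and
low-mappability windows are masked. A cell's fraction replicated is the
share of unmasked windows in the replicated state.

## Aggregate profiles and fractions

The S/G1 profile is the per-window ratio of summed S-cell counts to the
200-read reference counts, smoothed per chromosome with a cubic smoothing
spline and z-normalized. The smoothing parameter follows the csaps
convention (p·Σresidual² + (1−p)·∫f″², base-pair abscissa) with
p = 10⁻¹⁶, mapped onto `scipy.interpolate.make_smoothing_spline` via
λ = (1−p)/p. With base-pair units this attenuates structure below
~100–200 kb while leaving megabase timing domains intact; p → 1
reproduces the raw ratios (verified in tests). The spline is fit only
over windows with data, so masked spans receive no fitted value.

Sub-S-phase fraction matrices partition retained S cells into
equal-population bins by fraction replicated (ties broken by cell id),
sum counts per bin, and rescale all (fraction, window) values jointly so
the 1st percentile maps to copy number 2 and the 99.9th to 4. Peaks of
the normalized profile are local maxima with prominence ≥ 0.1 sd. Bulk
profiles for benchmarking are mapped onto the profile windows by
overlap-weighted averaging before computing Pearson r.

## IR calling and firing analyses

Tracks are maximal replicated runs bridging at most 5 consecutive masked
windows; 6 or more split the track, and track edges are always replicated
windows. Each track carries three candidate midpoints: observed, and the
midpoints under an outward misplacement of one boundary by 2.5 windows
(mid ± 1.25 windows; the inward variant is a config switch). Clustering
processes tracks shortest first, with ties broken by position then cell
id so the outcome is independent of input order; the provisional IR
interval is the span of member candidate midpoints. Tracks under 1 Mb
left unattributed (they overlapped several IRs) are rescued to the
same-chromosome IR with the nearest current center, ties toward the IR
with more members, then leftmost; tracks of 1 Mb or more stay
unattributed. Final IR centers and bounds are the 50th and 25th/75th
percentiles (linear interpolation) of attributed midpoints; IRs with
fewer than 5 tracks are flagged low-support and skipped in width
summaries. A track of exactly 1 Mb is excluded from rescue (strict <).

An IR counts as replicated in a cell when any of the cell's tracks
intersects the IR's [start, end] span (center-window rule available).
Under the fixed-order null, a cell with n replicated IRs is expected to
hold exactly the n earliest by aggregate timing; premature and delayed
calls per IR give a mismatch fraction, regressed on timing with a
quadratic (refused below 3 distinct timing values; IRs observed in fewer
than 5 cells are excluded from the fit). Firing ranges use % genome
replicated as the S-phase clock: earliest firing cell with an attributed
track, latest cell whose IR-center window is unreplicated after dropping
cells in which neither flanking IR (nearest per side) has replicated;
each extreme is corroborated when a second cell sits within 10 percentage
points. IRs firing in under half of cells are classified with
constitutive-late taking precedence (no firing cell below 50%
replicated), then throughout (more than 5 firing cells above 50%), else
rare-early; more frequently firing IRs are labeled early.

The PCA embedding imputes masked windows to the per-window mean state,
restricts to autosomes by default, and reports |r| between PC1 and
fraction replicated.

## Synthetic data

The generator is first-class, tested code and defines the study
conditions for every benchmark in the package.

*Timing profiles* are Gaussian-filtered white noise (σ = scale/2,
wraparound), z-normalized; the default domain scale of 75 windows gives
1.5-Mb timing domains. *Deterministic cells* draw one of 1,000 equally
spaced time slices; windows with earlier (higher) timing than the slice
level are replicated. Slices can instead be chosen so the replicated
fraction is uniform over a prescribed span, for populations stated in
terms of S-phase progression. *Stochastic cells* draw an observation time
uniform on (0,1); each origin fires with its efficiency at a truncated
normal time, and tracks grow symmetrically at constant equal fork speed,
merging on collision and clipping at chromosome ends. *G1 cells* are
uniform 2N. Counts are Poisson with the replicated rate exactly twice the
unreplicated rate, scaled so the expected mean count matches the cell's
target coverage, drawn uniformly from 50–250 reads/Mb — the coverage
span the method is designed for; the empirical coverage distribution of
any particular platform is not modeled. CNAs are injected by re-drawing a
region's counts with the rate multiplied by a fold factor.

`make_class_program` lays out one chromosome with an early domain
(efficient early origins interleaved with inefficient rare-early ones),
a domain of origins firing throughout S phase, and a late domain, with
origin-free spacers holding mid-late filler origins so the genome
finishes replicating and % replicated tracks elapsed S-phase time — the
structural features that make the three late firing classes
distinguishable in real genomes (rare-early tracks merge into their
neighborhood by mid-S; late domains are not reached passively).

What the generator does not emulate: amplification bias and
overdispersion beyond Poisson, GC bias, mappability structure beyond a
per-window fraction, allele-specific signals, variable fork speeds, and
inter-origin correlations. Passing tests therefore demonstrate the
inference logic under the stated noise model, not robustness to
platform-specific artifacts.

## Benchmark scales

Test and benchmark sizes were chosen as the smallest that exercise each
property at the scale it is defined for: the HMM accuracy benchmark uses
200 cells × 5,000 windows (100 Mb); sorting tests use ~150,000 windows
(full genome, where the 0.05 residual rule is calibrated) with cells
generated in batches; IR recovery uses 30 origins × 300 cells; firing
class recovery 250 cells. The acceptance script reports the HMM benchmark
at 200 cells and rounds to two decimals.

## Known limitations

- Only two copy states are modeled; aneuploid genomes with 3+ underlying
  copy numbers need the CNA mask to carry the difference.
- G2 cells are indistinguishable from G1 cells by design.
- The firing-order null uses ensemble timing ranks; IRs with nearly tied
  timing can swap ranks under profile noise, so exact-zero mismatch is
  guaranteed only with a nesting-consistent ranking (e.g. replication
  frequency), which the analyses use for deterministic data.
- CNA detection pools ~300-kb aggregates and cannot see sub-300-kb
  events; events mimicking the replicated rate (e.g. a clean 2× gain of
  unreplicated sequence) are indistinguishable from replication at the
  rate level and are left to the chromosome-level QC.
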