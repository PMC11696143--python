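# Methods

## Element definitions and scanning

Four degenerate FBE classes are matched exactly (no mismatches), on the
sense strand only, since CLIP peak sequences are already sense-oriented:
canonical `UGURnnAUn`, compact `UGURnAUn`, and the two FBEa*-like patterns
`UGUYRnAUn` and `UGUnRnnAUn` (R = A/G, Y = C/U, n = any base). Some
literature describes the compact element with a more specific consensus
(`UGUGAA(A/U)n`); the scanner deliberately uses the broader `UGURnAUn`
form, which is the definition used for the adjacent-site search this
package reimplements. An upstream cytosine is known to enhance affinity for
several FBEs but is not part of the search patterns; the scanner therefore
does not require it.

Every class is scanned independently at every position; overlapping matches
and multiple classes matching at one start are all reported, because the
pair-calling stage, not the scanner, decides what counts. Internally
coordinates are 0-based half-open; all written tables are 1-based inclusive
and say so in a header comment.

DNA-alphabet FASTA (T instead of U, any case) is accepted and normalized,
since peak sequences are usually exported from genomic coordinates.

## Adjacent-pair calling

The spacing between two elements is the count of bases strictly between
them: `start_3p − start_5p − length_5p`. A pair qualifies when this
distance is within 1–20 nt (both bounds configurable) and at least one
member is canonical; the canonical anchor may be 5' or 3' of the second
element, and two canonical elements may pair with each other. Overlapping
or abutting elements (distance ≤ 0) never qualify under the default
`min_gap = 1`.

When one start position matches several classes, one pair is reported per
(peak, start_5p, start_3p), keeping the class combination with a canonical
anchor (5'-anchored preferred, then alphabetical class order as a
deterministic tie-break). Rationale: the headline statistic counts *peaks*
with adjacent elements, so class-combination multiplicity at identical
coordinates would only inflate the pair table. Peaks are deduplicated by
peak id for the headline count; unique genes are counted over peaks with at
least one pair.

## Occupancy statistics

The occupancy comparison contrasts mean wild-type peak height (FPKM) of the
adjacent-FBE subset against **all** peaks — the subset is included in the
"all peaks" group, not complemented out — with a two-sided unpaired
equal-variance t-test and no multiple-testing correction. When the pooled
variance is exactly zero the test is degenerate; with equal means we report
t = 0, p = 1, and with unequal means the smallest representable positive
p-value, with a warning, rather than NaN.

No canonical numeric criterion exists for calling a peak's occupancy
"lower", "higher" or "unchanged" under the Y479A substitution. The
partition therefore takes an explicit fold-change threshold (default 1.5×),
logs it, and stamps it on the result object, so the choice is always
visible in output.

## EMSA Hill fit

Fraction bound is `bound/(bound+unbound)` band intensity. Titrations are
fit to `f(c) = Bmax·c^h/(K_D^h + c^h)` by bounded least squares
(`K_D > 0`, `h ∈ (0.2, 5)`, `Bmax ∈ (0, 1.2)`), initialized at the
half-maximum crossing interpolated in log-concentration. The bounds keep
the fit stable on noisy gel quantitations while admitting the
super-unitary Hill slopes seen for RNAs with adjacent elements. The default
concentration grid is the experimental one: 12 two-fold dilutions from
5 µM. Since `h` is a free parameter the fitted constant is an *apparent*
K_D; a mechanistic two-site model is intentionally not offered (see below).

## One-set-of-sites ITC

The instrument software that analyzes such titrations does not publish its
equations in the primary literature, so this package fixes one convention —
the Origin/MicroCal one-set-of-sites model for a perfusion cell — as its
single supported dialect. After injection *i* of volume *v* into a cell of
volume *V₀* (macromolecule at *M₀*, syringe titrant at *Xs*):

    M_i = M₀(1 − iv/2V₀)/(1 + iv/2V₀)
    X_i = Xs(iv/V₀)/(1 + iv/2V₀)
    [MX]_i = ((N·M_i + X_i + K_D) − √((N·M_i + X_i + K_D)² − 4N·M_i·X_i))/2
    Q_i = [MX]_i · ΔH · V₀
    ΔQ_i = Q_i − Q_{i−1} + (v/V₀)(Q_i + Q_{i−1})/2

Per-injection heats are normalized per mole of injectant (kJ/mol); whether
to normalize per mole or report raw heats is itself a convention, fixed
here as per-mole and applied consistently by simulator and fitter. Default
geometry is the standard 200-µL cell with 19 × 2-µL injections at 293.15 K
(20 °C), which is also the temperature used for ΔG = RT·ln K_D (K_D in
molar) and −TΔS = ΔG − ΔH.

The fit estimates (N, K_D, ΔH) by bounded least squares, initialized with
ΔH from the first injection and N from the molar ratio at the
half-enthalpy crossing; it warns when the Wiseman c-value (N·M₀/K_D) is
below ~1, where the isotherm is too shallow to pin N. Fitting a two-site
model is deliberately not attempted: a uniphasic isotherm cannot constrain
two independent sets of thermodynamic parameters.

Note on heat conservation: because each injection displaces liquid into the
overflow, the sum of measured per-injection heats equals the final
cumulative heat `[MX]·ΔH·V₀` plus a displacement term `(1/V₀)∫Q dV` that
does not vanish with smaller injections at a fixed total titrant volume.
The conservation test therefore uses a geometry in which total injected
volume is negligible against the cell volume (concentrated syringe, small
injections), where the displacement term is provably small.

## Expression profiles

Line profiles arrive on instrument-dependent pixel grids and are resampled
to a fixed 1-µm grid over 0–100 µm by linear interpolation. All genotypes
are scaled by a single factor — the maximum of the wild-type *mean* profile
within the distal 100 µm — so the wild-type normalized maximum is exactly 1
(the mean is divided directly rather than recomputed from scaled per-gonad
values, avoiding a one-ulp discrepancy). Confidence bands are 95%
t-intervals across gonads at each position; the gonad, not the pixel, is
the replicate unit. Regional tests average within each gonad over the
window first (avoiding pseudo-replication), then compare genotypes with the
same equal-variance t-test used for peak heights. The standard windows are
0–10 µm (stem-cell pool), 70–80 µm and 90–100 µm (differentiation zone).

## Synthetic data: what it emulates, and what it does not

- **Peaks**: background drawn i.i.d. from an AU-rich composition
  (U 0.35 / A 0.30 / G 0.18 / C 0.17) mimicking nematode 3'UTRs; planted
  pairs replace bases in place at a recorded offset with a recorded gap,
  with the canonical anchor placed 5' or 3' at random. Peak lengths are
  uniform on 60–120 nt, comparable to CLIP peak widths. FPKM heights are
  lognormal with log-sd 1 and log-mean 6.1 (arithmetic mean ≈ 740 FPKM),
  and the planted group's log-mean is raised by log(2825/736) ≈ log 3.84 so
  the group contrast matches the observed adjacent-vs-all occupancy gap.
  Because the background is AU-rich, chance FBE matches arise at a nonzero
  rate by construction; recovery checks compare to the planted-pair truth
  table rather than to exact hit counts.
- **EMSA**: Hill-model values plus i.i.d. Gaussian noise (default
  σ = 0.02, a typical gel-quantitation scatter), truncated to [0, 1]. The
  truncation introduces a small bias only near saturation and zero.
- **ITC**: the forward model above plus optional Gaussian heat noise.
- **Profiles**: a rising sigmoid (baseline 0.2, amplitude 1.0, midpoint
  50 µm, width 12 µm) emulating the wild-type pattern — low in the distal
  stem-cell pool, rising steadily toward differentiation — with additive
  per-gonad offsets (sd 0.05) and per-position noise (sd 0.05). The
  baseline sits far enough above zero that clipping at 0 is a negligible
  tail event, keeping the null distribution of the regional t-test
  effectively normal.

None of the generators emulate read-level CLIP signal, crosslink biases,
peak calling, gel imaging artifacts, or image segmentation; passing tests
demonstrate correctness of the analysis conditional on those upstream
steps, not robustness to their failure modes.

## Problem sizes and numerics

Test and acceptance runs use 500 synthetic peaks for recovery checks, 50
replicate titrations for noisy-refit medians, and 1000 null simulations for
t-test calibration — sizes at which the binomial error of the calibration
check (±1.4 percentage points at α = 0.05) is small against the tolerance.
Least-squares fits run with tight (1e-14) convergence tolerances so that
noiseless round-trips recover generating parameters to relative 1e-6.

## Known limitations

- Exact matching only; no mismatch tolerance or PWM scoring.
- Pair calling is within-peak; elements split across two peaks, or chains
  of three or more elements, are reported only as their constituent pairs.
- The Hill fit reports apparent constants; it is descriptive, not a
  two-site mechanistic model.
- The ITC dialect is the one convention documented above; heats produced by
  other integration pipelines must be normalized per mole of injectant
  before fitting.
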