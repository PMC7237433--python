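# Methods

## Scattering model and conventions

Elastic intensity in the Gaussian approximation is modelled as
`I(Q, T) ≈ I₀(T) · exp(−⟨u²⟩(T) Q²/6)`. The **/6 convention** is used
everywhere; it is the convention under which the resilience formula

    ⟨k⟩ = 0.00276 / (d⟨u²⟩/dT)        [N/m, ⟨u²⟩ in Å², T in K]

holds, with 0.00276 N·Å²·m⁻¹·K⁻¹ ≈ 2 k_B (2 × 1.380649·10⁻²³ J/K =
2.76·10⁻²³ J/K = 0.00276 N·Å²/K). Code that imports the package with the
/3 convention in mind would mis-scale every MSD by a factor two; the
constant is stored once, in `sporedyn.constants.FORCE_CONSTANT_COEFF`.

MSDs are extracted per temperature by weighted least squares of ln I on Q²
with weights `(I/σ_I)²` — the delta-method inverse variance of ln I under
counting statistics. The intercept ln I₀ is free. Weighting is a choice, not
a given: an unweighted option (`weighted=False`) exists for sensitivity
checks. Non-positive intensities are dropped pointwise before the log; a
temperature record is emitted only when ≥ 3 points survive inside the
window. No Q⁴ (non-Gaussian) correction term is fitted; the two printed Q
windows stay within or only slightly beyond the Gaussian regime, and the
term is a documented extension point rather than a default.

Window membership is closed-interval on the printed bounds, low Q =
[0.5, 1.67] Å⁻¹ and high Q = [1.4, 2.02] Å⁻¹; their overlap is intentional.
Q = 0.3 Å⁻¹ (length scale 2π/Q ≈ 21 Å) is excluded by default because that
point carries large-scale motions outside this analysis.

## Reduction chain

**Geometry.** Flat-slab sample in a flat container whose two windows
(thickness d_c/2 each) sandwich the sample; the slab normal is tilted 45°
to the beam (slab plane at 135°). Annular cells are out of scope. Scattering
angles whose exit ray lies within 1° of the slab plane are rejected rather
than approximated — path lengths diverge there.

**Transmission** is `exp(−(μ_s d_s + μ_c d_c)/cos(tilt))`; the default
geometry (μ_s = 2 cm⁻¹, d_s = 0.02 cm, μ_c = 0.1 cm⁻¹, d_c = 0.1 cm,
tilt 45°) transmits 93 %, above the 90 % acceptance threshold used to keep
multiple scattering negligible. No multiple-scattering correction is
computed (experimentally minimized, not modelled).

**Paalman–Pings coefficients** (A_ss, A_ssc, A_csc, A_cc) are averages of
`exp(−μ·path_in − μ′·path_out)` over the scattering depth, evaluated by
adaptive quadrature (absolute tolerance 10⁻¹⁰, well under the 10⁻⁶
contract). Q is mapped to scattering angle elastically at λ = 2.23 Å. The
empty-cell subtraction is
`I_corr = I_sample/A_ssc − (A_csc/(A_cc·A_ssc))·I_empty` with errors in
quadrature. Negative corrected intensities are *kept* and counted in the
metadata — dropping them would bias the summed-intensity thermograms — and
only discarded at the log-transform stage of the MSD fits.

**Vanadium normalization** divides by the temperature-averaged per-Q
vanadium profile to cancel detector efficiencies. When the vanadium scan's
metadata states the standard's own mean square displacement
(`vanadium_msd`, Å²), its Debye–Waller factor is divided out first so that
the normalization cancels efficiency only and does not shift every
extracted MSD by the standard's ⟨u²⟩. Vanadium counting errors are
propagated into the result by default; a switch disables this for
comparison. Q points with non-positive vanadium signal are auto-masked.

**Thermograms.** Intensities are summed over all usable Q at each
temperature, divided by the lowest-temperature sum, and quoted in percent;
the anchor point is exactly 100 % with zero error. Q exclusions apply after
reduction and before fitting, so reduced scans remain complete on disk.

## Thermal analysis

**Force constants** come from an error-weighted linear fit of ⟨u²⟩ vs T
over an explicitly configured temperature range; ranges are never chosen
silently. `k = 0.00276/slope`, `σ_k = 0.00276·σ_slope/slope²`. A slope not
exceeding its own 1σ error flags the result *meaningless* (the footnote
travels into the report); a non-positive slope reports k as undefined. The
1σ rule is this package's operational criterion for "statistics not
sufficient", chosen here because no quantitative criterion is standard.

**Breakpoints.** A continuous two-segment (hinge) model
`y = β₀ + β₁T + β₂·max(T−T_b, 0)` is fitted by weighted least squares for
every candidate T_b among the interior data temperatures leaving ≥ 3 points
per side (the breakpoint belongs to both segments); minimum weighted SSE
wins. Significance compares against the single-line fit with an F-style
statistic on 2 extra parameters and n−4 degrees of freedom,
**Bonferroni-corrected for the number of candidates searched** (default
α = 0.05). The correction is deliberately conservative: with the searched
breakpoint the naive F test is anticonservative, and a false germination
call is worse than a missed marginal one. Independent per-range fits — the
literal split-table procedure — are available by configuring explicit
temperature ranges.

**Ratios.** Mutant/wild-type MSD ratios are computed per shared temperature
(quadrature errors) and averaged unweighted; the quoted ± is the
across-temperature standard deviation, with the propagated measurement
error reported side by side since the two can differ substantially.

## Synthetic data: what it emulates, what it does not

The generator produces triplets (sample, vanadium, empty) on a default grid
of 24 Q points uniform in [0.3, 4.9] Å⁻¹ (0.2 Å⁻¹ spacing, so the high-Q
window holds 3 detectors and the low-Q window 6) and 8 temperatures in
[280, 315] K — desk-scale stand-ins for the instrument's detector bank, not
claims about it.

Sample dynamics are a two-population Gaussian mixture: a "small" population
(local macromolecular motions, default ⟨u²⟩ = 0.30 Å² at 280 K, slope
0.00276/0.21 Å²/K so that a pure-population analysis recovers a resilience
of 0.21 N/m) and a "large" population (diffusive/large-amplitude motions,
default 3.0 Å², slope 0.003 Å²/K, weight 0.35). Germination is a breakpoint
at 305 K in the **large population only**, steepening its slope to
0.3 Å²/K — its MSD doubles over the last 10 K, a drastic change of the kind
a spontaneously germinating preparation shows. Because that population's
elastic weight at Q ≥ 1.4 Å⁻¹ is small and shrinks further as its MSD
grows, the transition appears in the low-Q window and is largely invisible
at high Q: the mechanism, not an ad-hoc rule, produces the window
dissociation. The mutant fixtures scale one population's law: ×1.8 on the
large population (CaDPA-less-like) and ×0.6 on the small one
(coatless-like), the published ratio values doubling as simulation ground
truths.

Counting statistics: amplitudes are normalized so the mean sample count at
Q → 0 and the lowest temperature is `counts_scale` (default 5·10⁴, the
order of magnitude of a few-hour-per-point elastic scan); observed counts
are Poisson draws, errors `max(√N, 1)`. Per-detector efficiencies are drawn
log-normally (default 10 % relative spread) **once per triplet** and shared
by the three scans, so vanadium division cancels them exactly — a testable
contract. The container term is a nearly flat Gaussian (⟨u²⟩ = 0.1 Å²) at
5 % of the sample amplitude; a flat sample-background term (2 % by default)
models the Q-independent floor. The vanadium standard is simulated with a
fixed ⟨u²⟩ = 0.05 Å², recorded in the scan metadata and in the fixture
manifest.

Not emulated: quasielastic lineshapes, multiple scattering, H/D exchange
bookkeeping, per-detector masking patterns of any real instrument, and
detector-to-detector solid-angle variations beyond the efficiency factors.
Passing recovery tests therefore demonstrates correctness of the estimators
under Poisson counting noise and the stated forward model — not robustness
to every instrumental artefact of real scans.

Parameter-recovery studies are run with the flat background set to zero, so
the estimator is tested under the model it assumes. With the default 2 %
background the extracted MSDs acquire a small downward bias (≈ 2–3 % on the
temperature slope at these settings): a known, documented model-mismatch
sensitivity, not an estimator defect.

## Determinism and problem sizes

All randomness flows from integer seeds through `numpy.random.default_rng`;
identical seeds give bit-identical scans, and identical configs give
byte-identical report tables. The simulation studies in the test suite use
200 replicates for force-constant recovery and breakpoint localization and
100 for ratio recovery and window dissociation — sizes at which Monte-Carlo
standard errors are a few tenths of a percent of the recovered values while
the whole suite stays fast.

## Known limitations

- Slab geometry only; cylindrical/annular absorption is not implemented.
- The hinge detector assumes at most one breakpoint in the scanned range.
- The F-style significance threshold is approximate for searched
  breakpoints even after the Bonferroni correction; its observed
  false-positive rate is checked by simulation rather than derived.
- Errors are treated as independent across Q and T; the vanadium
  normalization in fact correlates temperatures at fixed Q, which slightly
  overstates the error bars of fitted slopes.
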