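# Methods

This note documents the quantitative model implemented by `afmbone`,
its parameters and defaults, the numerical choices, and the points
where the implementation had to resolve ambiguity.

## 1. Force-spectroscopy pull metrics

### Signal chain

Raw acquisitions are (time, piezo position z, photodiode deflection in
volts) triples, optionally segment-labelled. Conventions: SI units
internally; z increases toward the surface, so the point of closest
approach is the global maximum of z; adhesion force is negative.

1. **Split** into approach / dwell / retraction. Labelled cycles split
   by label; unlabelled cycles split at the global maximum of z.
   Retraction-only acquisitions (all labels `retract`) are used whole.
2. **Calibrate**: force = k · InvOLS · deflection_raw; tip–sample
   separation = (max z − z) + InvOLS · deflection_raw (piezo coordinate
   flipped to grow away from the surface, plus the cantilever-bending
   correction).
3. **Contact alignment**: the contact point is the last zero crossing
   of force before adhesion onset. It is found by anchoring on the last
   sample whose force exceeds a robust noise floor (5 σ̂, below) ahead
   of the deepest adhesion, then extrapolating the zero crossing from
   the slope of the last two samples of the repulsive unloading ramp.
   The ramp slope (hundreds of pN per sample for the protocol
   stiffness) dwarfs the baseline noise, so the crossing lands within a
   small fraction of a sample; walking sample-by-sample to the first
   negative force instead would drift several samples through the flat
   adhesion onset at realistic noise. Both axes are shifted so the
   crossing is (0, 0). Traces with no negative force are rejected
   (`all_repulsive`), or returned as zero-metric pulls when
   `flat_curve_policy: zero`.
4. **Metrics**:
   - maximum adhesion force: |min force| over separation ≥ 0;
   - pulling length: separation of the last sample whose adhesion
     exceeds max(1% of the maximum force, 5 σ̂);
   - energy: trapezoid integral of the adhesive force magnitude
     (positive excursions clipped to zero) over separation in
     [0, pulling length].

σ̂ is the baseline-noise SD estimated as 1.4826·MAD(diff(force))/√2 —
differencing removes slow model trends and the median absolute
deviation makes the sparse rupture jumps irrelevant. The 5 σ̂ floor
under the 1% rule is the operational reading of "adhesion exceeding 1%
of the maximum force": on noisy traces an isolated baseline fluctuation
past the last rupture would otherwise set the pulling length. With the
floor the pulling length is recovered within one sampling interval at
the default noise (measured: ≤ 0.3 nm at 1 nm sampling).

### Calibration

- **InvOLS**: per stiff-surface curve, an OLS line is fitted to the
  loading region (terminal contiguous run of samples above 10% of the
  maximum deflection, ≥ 5 samples); the slope (V/m) is inverted and the
  per-curve values averaged (protocol: 10 curves). Noise-free curves
  are recovered exactly.
- **Spring constant**: equipartition on a free-cantilever deflection
  series (metres), k = β·k_B·T/Var(d), requiring ≥ 10⁴ samples. β
  defaults to 1.0; the standard first-mode correction 0.971 can be set
  in the run configuration. No spectral fitting is attempted — the
  variance form is the estimator the synthetic thermal series honors
  exactly.
- Calibrations with k outside (0.001, 10) N/m are flagged, not refused.

### Condition aggregation

Pull energies per environment (substrate × solution × pH × protein
state) are reported as mean ± SE over accepted pulls. For display the
means and SEs are divided by the substrate's reference-condition mean
(mica → EDTA, hydroxyapatite → water); normalization is idempotent,
preserves input ordering, and never feeds statistics — tests always run
on raw energies. Two-condition comparisons use a KS normality check per
group (parameters estimated from the sample; the asymptotic p is
conservative and flagged as such) and a two-sided Student's t-test,
α = 0.05. Zero-variance groups are refused.

## 2. Bone cohort

### Fracture toughness

Single-valued Kc at maximum load for a circumferentially through-wall
notched femur in three-point bending:

    I  = π/4 (Ro⁴ − Ri⁴)
    σ  = P_max · S/4 · c / I          (c = Ro by default, Rm optional)
    a  = θ_rad · Rm,  Rm = (Ro + Ri)/2,  t = Ro − Ri
    Kc = F(θ, Rm/t) · σ · sqrt(π a)   (reported in MPa·√m)

F(θ, Rm/t) is bilinear interpolation on the versioned CSV
`afmbone/data/geometry_factor.csv` (half crack angle 0–110° × Rm/t
1.5–20). The table is generated from the closed-form thin-wall
circumferential-crack bending solution F = 1 + A·[4.5967(θ/π)^1.5 +
2.6422(θ/π)^4.24] with A = [0.125·(Rm/t) − 0.25]^0.25 for Rm/t ≤ 10 and
A = [0.4·(Rm/t) − 3.0]^0.25 above, extended below the published Rm/t
range by flooring the bracket at 0 (provenance notes in the CSV
header). Queries outside the grid are errors, not extrapolations.

Validity sieve (each rejection carries its reason): `angle_range`
(θ outside 0–110°), `deep_notch` (notch past 1/3 of the cortex),
`off_center`, `angle_outlier` (|θ − cohort mean| > 2 SD, ddof = 1).

### Phosphorylation and the paired design

Global matrix phosphorylation = mean assay absorbance over replicates
per ng protein; the replicate CV is reported and single-replicate
samples flagged. The paired analysis takes per-limb values keyed by
animal, genotype and treatment: per genotype a paired t-test of treated
vs contralateral control (the pairing cancels between-animal
variation), then an independent-samples t-test on the
treated-minus-control deltas between the two genotypes. Animals without
exactly one treated and one control value are refused.

### Statistical kernel

`paired_t`, `unpaired_t` (pooled Student form by default, Welch
optional) and `ks_normality` all return a `TestReport` (statistic, df,
p, group summaries, α = 0.05). Zero-variance inputs yield flagged
degenerate reports (t = 0, p = 1 for zero mean difference; ±∞, p = 0
otherwise) instead of NaNs — reachable for n = 7 cohorts.

## 3. Synthetic generator

### Pull model

A pull is a train of rupture events, each a rising adhesion limb
|F| = peak·(x/span)^p from the previous rupture (or contact) to its
contour length, dropping to baseline instantaneously at rupture. The
exponent p = clip(span / persistence_scale, 1, 8) gives short events a
triangular limb and long events a concave worm-like-chain-style limb
(`shape: "triangle"` forces p = 1). Each event's enclosed area is
analytic: peak·span/(p+1); the pull's truth is the sum, the true
maximum force the largest peak, the true pulling length the last
contour length.

Defaults: events (150 nm, 0.8 nN), (400 nm, 1.2 nN), (800 nm, 0.6 nN);
persistence scale 200 nm; baseline noise 20 pN (white Gaussian on
force); sampling 1 nm; max separation 3 µm; repulsive contact slope
0.5 N/m. Protocol constants: approach 2.0 µm/s to a 15 nN trigger,
dwell 10 s, retract 5.0 µm/s.

### Numerical choices

- Samples are generated on a uniform grid of *true* separation; the
  recorded z is back-computed as z = z_contact − (s − deflection) so
  the downstream separation correction recovers s exactly. A real
  instrument ramps the piezo uniformly instead; the difference
  (snap-in/out multivaluedness for soft levers) is deliberately not
  modelled — only the enclosed area matters to the pipeline.
- Each rupture carries a duplicate-separation sample pair (left limit
  at the peak, right limit at baseline) so the sampled polyline drops
  vertically, exactly like the instantaneous-rupture model; without it
  the trapezoid rule would add peak·h/2 of spurious area per event.
- The retraction clock is index-based (duplicate samples share a
  separation); the full-cycle clock follows the commanded (noise-free)
  piezo path at the segment velocities, so force noise does not inflate
  the apparent piezo travel.
- Events with peaks below 3× the noise SD trigger a ground-truth
  warning (they are physically present but undetectable).

### Other generators

Stiff-surface curves are lines of slope 1/InvOLS (V/m) in the contact
half of the ramp; thermal series are white Gaussian at the
equipartition variance; paired cohorts draw a between-animal baseline,
apply the multiplicative treatment effect plus a limb-level residual,
randomize the treated limb, and back-compute each specimen's maximum
load through the installed geometry-factor table so that Kc round-trips
through the toughness engine (section radii are redrawn when a draw
would leave the table's Rm/t domain). Truth columns are not written to
the cohort CSVs.

Cohort defaults (documented assumptions, set once): 7 pairs per
genotype; control Kc 4.5 ± 0.4 MPa·√m between animals with 0.25 limb
residual; phospho level 5·10⁻⁴ ± 10% AU/ng with 3% replicate CV,
triplicates, 1000 ng protein.

## 4. Known limitations

- The pull model has no snap-to-contact, no hydrodynamic drag, no
  baseline drift or tilt; contact alignment therefore needs no baseline
  regression, which real data would.
- The thermal series is white, not a damped-oscillator spectrum; the
  variance estimator is exact for it by construction.
- The KS normality p-value is the plain asymptotic one with estimated
  parameters (conservative; flagged in the report) rather than a
  Lilliefors-corrected value.
- The geometry-factor table extends the published thin-wall coefficient
  below its stated Rm/t validity by flooring, which is an extrapolation
  choice, not literature data (noted in the CSV header).
- Energies integrate the sampled polyline with the trapezoid rule only;
  no other quadrature is offered (`integration_rule` exists to make the
  choice explicit and rejects anything else).
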