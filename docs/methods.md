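# Methods

## Competitive PCR under limited dNTPs

The endpoint model is a deterministic cycle recursion over the 2–3
co-amplified products of a reaction.  Working in dimensionless reaction
units, amplicon *i* (length *Lᵢ* bp, per-primer pool *pᵢ* μM) starts at
`copies × 5·10⁻¹¹` units of template and each cycle attempts

    demandᵢ = efficiency × completionᵢ × xᵢ,   capped at the remaining pᵢ

new strands.  Nucleotide need is `demandᵢ × Lᵢ` against a shared budget of
`dntp_conc × 2.0` units; when total need exceeds the remainder, all
demands are scaled by the common factor `remaining/need`, so molar ratios
are untouched by exhaustion.  The completion factor

    completionᵢ = min(1, κ · dntp_conc / Lᵢ),   κ = 36 nt/μM

models the polymerase failing to finish long templates within a cycle
when the formulated nucleotide concentration is low.  It is evaluated at
the formulated (not instantaneous) concentration: depletion under
exponential growth is abrupt — the pool goes from ample to empty within
one cycle — so the kinetic regime is a property of the reaction setup,
and this choice keeps the limited regime exactly ratio-preserving.

With the default 35 cycles and 0.95 efficiency these constants put the
three classic regimes at their expected concentration landmarks for the
bundled assays: shortest-amplicon takeover below ≈ 1.56 μM (κ chosen so
the 50 bp product completes there while the 68 bp reference does not),
quantitative dNTP limitation around 6.25 μM (exhaustion near cycle 31),
and the primer-limitation plateau above ≈ 25 μM (all primer pools cap).
Both resources obey exact conservation, which the suite property-tests.

Parameters that matter: `dntp_conc` (μM, default 6.25), `cycles` (35),
`efficiency` (0.95/cycle, shared by all amplicons), per-amplicon
`primer_conc` (μM, from the published assay recipes), and an optional
*SMN2* mis-priming leak (fraction of two *SMN2* copies added to the
*SMN1* template, default 0 — the allele-specific primer is treated as
fully specific; silent-carrier genotypes are out of scope).

## Forward melt model

Each amplicon melts as a symmetric two-state transition,
`amount × L × σ((Tm − T)/w)` with logistic σ and width `w = 0.7 °C`
(single-domain products by design), so signal is proportional to duplex
base pairs as with a saturating dye.  A raw curve is

    F(T) = gain · [ B·e^(−d·(T−65)) + Σ transitions ] + ε,

sampled 65–95 °C at 0.05 °C.  Cohort wells draw background amplitude
`B ~ U(0.3, 0.7) × plateau`, decay `d ~ U(0.05, 0.15) /°C`, gain
`U(0.7, 1.3)`, and a coherent well temperature offset `U(−0.3, 0.3) °C`
from one seeded stream (identical seeds give bit-identical cohorts).
Noise ε is white Gaussian with sd = `noise_sd` × the reference
transition's analytic −dF/dT peak height (`amount·L/(4w)`); the default
`noise_sd = 0.01` corresponds to ≈ 0.4% of the fluorescence plateau.

Default cohort class mixes mirror the clinical validation cohorts: for
SMA (36 affected : 43 carrier : 23 normal : 1 duplication)/103; for
22q11.2DS a 43/99 carrier fraction split 87% A–D, 8% A–B and the
remaining 5% evenly between A–C and B–D.  Mandated controls (2/1/0-copy
*SMN1*; normal + A–D deletion) occupy the first wells deterministically.

What the generator does **not** emulate: multi-domain or heteroduplex
melting, salt/ionic-strength effects on relative peak heights,
single-molecule amplification stochasticity, probe or instrument drift
within a run, and *SMN2* dosage beyond the leak parameter.  Passing tests
therefore demonstrate that the analysis chain correctly inverts this
forward model at realistic noise, not that it is robust to every
instrument artifact.

## Signal chain

1. **Exponential background subtraction.**  Cursors default to the
   extreme expected Tms ± (5 melt-widths + 1.5 °C), clipped to keep half
   a slope window inside the 65–95 °C range.  (A 3-width margin was
   tried first and rejected: logistic tails leak enough slope into the
   cursors to miss the 1%-accuracy target on synthetic oracles.)  The
   decay rate comes from the ratio of Savitzky–Golay slopes at the two
   cursors, `a = ln(s_R/s_L)/(T_R − T_L)`; because an SG slope of an
   exponential is biased by the filter response ρ(a) = Σcᵢe^{a·i·h}
   *identically at both cursors*, `a` is exact and dividing the anchor
   slope by ρ(a) makes the subtraction machine-exact on pure-exponential
   input.  Remaining transition-tail contamination is removed by a
   fixed-point loop: model the corrected curve's transitions as
   logistics (Tm and height from the −dF/dT peaks, width from peak
   curvature via w = √(h/(2|g″|))), subtract the *filtered* model slope
   from the measured cursor slopes, refit (3 iterations; relative RMS on
   the duplex oracle ≈ 0.6%).  Slopes within numerical dust of zero are
   tolerated (re-processing an already-flat curve is a no-op); genuinely
   rising fluorescence at a cursor rejects the sample.
2. **Helicity normalization** rescales to 100 at the left cursor window
   and 0 at the right (1 °C window means).
3. **Temperature shifting** translates each curve by the δ (|δ| ≤ 1 °C,
   0.01 °C search grid, cubic interpolation) minimizing the sup distance
   to the batch's first curve over the 5–10% helicity band — the
   high-temperature tail, shared by all genotypes through the last
   common melt.  The first curve (a control, by batch ordering) is the
   reference rather than an iterative mean, for determinism.
4. **Savitzky–Golay differentiation**, degree 2, window 1.0 °C (21
   points), linear phase, half-window trimmed at each end.  The window
   attenuates a width-0.7 °C logistic peak by ≈ 2.7%; the attenuation is
   identical for equal-width peaks so every ratio-based quantity is
   unaffected, and the wide window buys ≈ 2.6× noise suppression over an
   0.5 °C window.

## Quantification and calling

Peaks are the highest local maximum per expected-Tm window (± 1.5 °C),
quadratically refined; target maxima with topographic prominence below
5% of the sample's reference peak are *absent* (noise wiggles riding a
neighbour's flank are not melting transitions).  A reference peak below
10% of the batch median marks the sample `failed_reference`.  Batch peak
normalization is vertical first (each curve scaled to the geometric-mean
reference amplitude), then horizontal (per-sample affine map of detected
peak temperatures onto batch means — exact for two anchors, least squares
for three; scale outside [0.95, 1.05] is warned).  Vertical-then-
horizontal order is fixed and documented since the reverse is equally
defensible.  Dosage is the target/reference height ratio relative to the
2-copy control.

Calling clusters the normalized −dF/dT curves per target window in the
uniform (sup) metric — restricted to the window so reference-region noise
cannot drive the partition — with average linkage (robust to single noisy
curves; complete/single configurable).  The cut is the largest relative
gap in merge heights, refined toward more clusters until controls of
different copy number separate; indistinguishable controls fail the
batch.  Clusters inherit copies from their control; control-free
clusters get `floor(2·median(dosage) + 0.5)` (half-up rounding, capped
at 4) — this is how a 3-copy duplication is separated without a 3-copy
control.  A member whose dosage sits > 0.35 from its cluster's expected
ratio (half the 1-copy spacing, minus margin) is flagged Atypical.
Triplex copy vectors are assembled per-gene from independent window
clusterings, then decoded by the total, mutually exclusive lookup tables
(SMA: 0/1/2/≥3; 22q11.2: the five hemizygosity patterns, else Atypical).

## Numerical and design notes

* Quadratic peak refinement clamps the sub-grid offset to ±1 step;
  non-concave triples keep the grid point.
* Merge-height gap ratios use an epsilon floor so batches of identical
  curves (zero merge heights) cut cleanly.
* Cubic interpolation is used for all sub-grid resampling (shift,
  horizontal normalization), with arguments clamped to the grid.
* The melt CSV writer emits 17 significant digits so reader/writer
  round-trips are bit-identical (`float_precision="round_trip"`).
* Samples whose raw signal is unusable (e.g. no fluorescence decay at a
  cursor under heavy noise) are excluded and reported, not fatal —
  unless they are mandated controls, which fails the batch.
* Test and acceptance problem sizes: 200-sample cohorts per assay for
  concordance runs, 5 seeds × 4 noise levels for the robustness sweep,
  ~100 parameter points for oracle equivalence.  One cohort analyzes in
  a few seconds on one core.

## Known limitations

Silent (2+0) SMA carriers, intragenic *SMN1* point mutations and *SMN2*
copy quantification are outside what endpoint dosage can see.  The
concentration-to-molecule scaling is qualitative: the 1.56/6.25/25 μM
landmarks are honoured as regimes, not fitted to molecule counts.  The
background model is single-exponential; strongly non-exponential
backgrounds (e.g. probe-release artifacts) would need different cursors
or a different model.  Whether the upstream tooling this mirrors aligns
curves on the high- or low-helicity tail, and whether it clusters whole
curves or windows, is not documented; the choices here (low-helicity
band; window-restricted clustering) are stated as such.
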