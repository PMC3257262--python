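# Methods

## The experimental logic being modelled

A self-assembling helical domain is dissolved to monomers in 100% DMSO and
re-associated stepwise by dilution with water (100 → 90 → 85 → 80 → 70 → 50%
vol/vol in the default ladder). At each equilibrium rung three classes of
observable are recorded for the assigned residues: chemical shifts (Cα for
structure, amide H/N for bookkeeping, proline Cβ/Cγ for isomer state),
³J(HN–Hα) couplings from high-resolution HSQC doublet splittings, and CPMG
intensity decays for R₂. Residues that fold and enter the megadalton
assembly broaden beyond detection, so *absence from the spectrum* is the
assembly readout. The pipeline's stages formalise, in order: where transient
structure forms, where µs–ms exchange is concentrated, and in what order
segments leave the visible pool.

## Secondary Cα shifts with a blended baseline

ΔCα(i) = Cα_obs(i) − (p1·Cα_rc,dmso(aa_i) + p2·Cα_rc,aq(aa_i)), p1 + p2 = 1.

The weights represent the chain's relative exposure to the two solvents.
There is no direct measurement of that exposure, so the default policy sets
p1 to the DMSO volume fraction; the policy is a plain callable argument and
can be replaced wholesale. At p1 ∈ {0, 1} the formula collapses exactly to
the single-solvent baseline (tested).

Significance: a residue counts toward a propensity segment only when
|ΔCα| strictly exceeds the threshold (default 0.7 ppm, the typical spread of
Cα shifts). The inequality is strict because the line is drawn *at* the
uncertainty level: a deviation equal to the uncertainty is not evidence.
Segments are maximal contiguous runs of same-sign significant residues of
length ≥ `min_len` (default 3 — the smallest stretch that is more than a
point; configurable). Missing residues break runs: an unassigned residue is
unknown, not insignificant.

Packaged random-coil tables: the aqueous Cα values are a standard
random-coil compilation; the DMSO table is a synthetic default (aqueous
values with a uniform −1.5 ppm solvent correction) standing in for
peptide-calibrated DMSO references, and is labelled as such in its filename.
Replace both with calibrated tables for real data; no pipeline logic depends
on the packaged numbers, and the tests use synthetic tables throughout.

## ³J(HN–Hα) couplings

J = (δ_high − δ_low) × ν₀, linear in the proton frequency ν₀ (MHz), so a
0.01 ppm splitting at 800 MHz is 8 Hz. Band assignment: helix [3, 5] Hz,
coil [6, 8] Hz, sheet (8, 11] Hz. The coil and sheet bands share the value
8 Hz; it is assigned to coil so the classification is total and
deterministic, and the rule is configurable. Values in the gaps are
`unresolved`.

Random-coil reference couplings are per-residue base values corrected when
the *preceding* residue is aromatic (F/Y/W/H). The correction magnitude is
not a settled constant; it defaults to −0.5 Hz and is an explicit parameter.
The packaged base table is a synthetic default near 7 Hz (editable data, to
be replaced by peptide-calibrated values for real work). The first residue
of a chain has no predecessor and is flagged unresolved rather than guessed.

A doublet whose splitting cannot be measured is an *unresolved state*, never
J = 0: in a titration toward the folded state, vanishing splittings are
themselves evidence of helix formation, and conflating them with zero would
corrupt every downstream deviation statistic.

## CPMG R₂ fitting and exchange segments

Model: I(t) = I₀·exp(−R₂·t) per residue over the delay schedule (default
10–190 ms in 20 ms steps, stored once in seconds to avoid unit bugs). The
fit is nonlinear least squares initialised from a log-linear regression;
when per-point intensity errors are available they weight the fit
(`absolute_sigma`), which matters because multiplicative noise is strongly
heteroscedastic across a decay — unweighted fits underestimate the standard
error at high R₂. The reported uncertainty is the covariance standard error.
Verified behaviour (test suite): noiseless decays are recovered to machine
precision and match the log-ratio closed form; at 2% intensity noise on the
default schedule, bias is below 2% and the 1-SE interval covers the truth at
≈68% over R₂ ∈ {2, 5, 10, 20} s⁻¹. Non-decaying or non-positive data yield
a recorded fit failure, never an aborted batch.

Exchange-segment detection operationalises the visual "trend of the spread"
reading of an R₂ profile as a robust rule: flag residues with
R₂ > median + k·1.4826·MAD (k default 1.0) and keep maximal contiguous
flagged runs of ≥ 3 residues. The median/MAD centre is insensitive to the
exchange residues themselves. Both k and the minimum length are exposed;
the defaults are this package's operationalisation, not a community
standard.

## Proline isomer calls

Δβγ = δ(Cβ) − δ(Cγ). Around 5 ppm indicates a trans X-Pro bond, around
9–10 ppm cis. Only the trans side is tightly anchored empirically, so the
classifier uses a configurable boundary of 7 ppm with a ±1 ppm closed
ambiguity band: trans below 6, cis above 8, ambiguous inside. The zones are
disjoint and monotone in Δβγ.

## Presence, disappearance and nucleation

Presence is defined by assignment records — a residue is present at a
condition iff it has a major-state amide (H or N) record there — because
assigned peak tables are the curated product of the experiment; raw
intensity thresholds are out of scope. Slow-exchange duplicates (minor-state
amide records) mark a residue `minor_duplicate`, which counts as present.

Prolines have no amide proton: they are never present, and they *bridge*
rather than break absent runs (a proline inside a vanished segment carries
no disappearance information). The N-terminal residue's amide exchanges too
fast to observe; the generator models it as never present, and the terminus
exclusion below keeps it out of nucleation calls.

Disappearance events: for each adjacent ladder pair, the maximal contiguous
runs (proline-bridged) of residues present at the higher DMSO fraction and
absent at the lower one. Non-monotone presence — a residue that reappears
after vanishing — is *flagged* in a consistency report, never silently
repaired: real titration tables contain such inconsistencies and they are
information.

Nucleation: at the highest-denaturant condition, every maximal absent run
with a detected exchange segment within `flank_window` residues (default 3,
allowing small unassigned gaps; directly adjacent flanks have gap 1) on
*both* sides is a nucleation candidate. Runs touching a chain terminus are
excluded because one flank is geometrically impossible there.

## The synthetic study generator

The generator plants a ground truth and emits all observables from it, so it
is the oracle for every stage:

- **Geometry (defaults):** 137 residues, prolines at 12/38/67, nucleation
  [109, 116] (stage 0: absent at every rung), incorporation stages radiating
  outward in both directions — [97, 108] and [117, 121] at stage 1,
  [69, 96] and [122, 125] at stage 2, [126, 137] at 3, [39, 68] at 4,
  [33, 38] at 5 — and a flexible tail [2, 32] that never vanishes. The
  stage map is checked to be non-decreasing with distance from the
  nucleation segment along each arm; custom geometries get a generic
  radiating map. The sequence itself is random (seeded): only the landmarks
  matter, and the amino-acid identities exercise the per-residue baselines.
- **Emission model:** Cα = blended random-coil baseline + 2.8 ppm (a typical
  full-helix secondary shift) × propensity × fold fraction + N(0, 0.2 ppm);
  couplings shrink linearly from 7 Hz (coil) toward 4 Hz (helix) with fold
  fraction, ± 0.2 Hz, and are omitted as unresolved below a 3 Hz resolution
  floor; CPMG decays from R₂ = 3 s⁻¹ baseline plus a 12 s⁻¹ exchange boost
  for residues within one rung of their incorporation stage (the
  about-to-vanish residues are the broadened ones), with 2% multiplicative
  intensity noise and matching per-point errors; trans-proline Cβ/Cγ pairs
  with Δβγ = 5 ppm, emitted noiselessly — the isomer bands are ppm-scale
  apart, so carbon-shift uncertainty is immaterial to the call; a fixed set
  of residues carries minor-state duplicate peaks. The fold fraction of a
  residue with stage s at condition index c is min(1, (c+1)/s): each
  residue reaches full folding exactly at its last visible rung, monotone
  down the ladder.
- **Determinism:** one `numpy` generator seeded from the study seed drives
  everything; identical seed and configuration produce byte-identical
  written tables.

What the generator does *not* emulate: peak overlap and accidental
degeneracy, solvent-exchange attenuation, temperature drifts, assignment
errors, field-dependent exchange broadening, and any real relationship
between sequence composition and propensity. Passing tests therefore
demonstrate that the inference machinery is correct under the stated
observation model, not that real spectra meet that model.

## Problem sizes and test design

The statistical suites use sizes that make the checks sharp but quick: 100
Monte-Carlo replicates per R₂ grid point (enough to resolve a 2% bias bound
with 2% noise), 25–60 random profiles against each brute-force oracle, and
50 seeded end-to-end studies for nucleation/order recovery (≥ 95% required;
observed 50/50). The full suite runs in well under a minute.

## Known limitations

- The solvent-weight policy is a declared default, not an estimate of true
  solvent exposure; quantitative ΔCα magnitudes inherit that approximation.
- Only Cα is used for shift propensities (no multi-nucleus consensus score);
  couplings and shifts are interpreted independently, with couplings the
  more reliable indicator when they disagree.
- R₂ is a single-delay-train CPMG rate: exchange contributions are detected,
  not decomposed (no dispersion analysis, no model-free parameters).
- Assignment itself (triple-resonance walks) and raw spectral processing are
  out of scope; the pipeline starts from assigned tables.
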