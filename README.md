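# nmrtitrate

Residue-level analysis of protein folding and self-association from
denaturant-titration NMR data.

Large helical self-assemblies (megadalton coiled-coil oligomers such as the
dynamin GTPase effector domain) are invisible to solution NMR: the assembled
species tumbles far too slowly to give sharp amide peaks. A productive
strategy is to dissolve the assembly in a strong aprotic denaturant (DMSO)
and then walk back down a dilution ladder — e.g. 100%, 90%, 85%, 80%, 70%,
50% DMSO (vol/vol) — recording spectra at each equilibrium rung. As segments
of the chain fold and join the assembly they *disappear* from the HSQC, so
the order of disappearance is the hierarchy of incorporation, and the segment
already missing at the highest denaturant concentration — when flanked on
both sides by stretches of exchange-broadened residues — is the candidate
nucleation site of folding and association.

`nmrtitrate` implements every quantitative stage of that analysis:

- **Secondary Cα shifts in mixed solvent.** The random-coil baseline itself
  moves with solvent composition, so deviations are computed as
  ΔCα(i) = Cα_obs(i) − (p1·Cα_rc,DMSO + p2·Cα_rc,aq) with p1 + p2 = 1
  (default: the DMSO volume fraction). Contiguous runs with |ΔCα| above an
  uncertainty threshold (default 0.7 ppm; positive = helix, negative = sheet)
  become propensity segment calls.
- **³J(HN–Hα) couplings** from high-resolution HSQC doublet splittings
  (J = Δδ_H × spectrometer frequency), random-coil references corrected for
  aromatic preceding residues, band classification (3–5 Hz helix, 6–8 Hz
  coil, 8–11 Hz sheet), and deviation profiles where an *unresolved*
  splitting is an explicit state — evidence of helix, never conflated with
  J = 0.
- **CPMG R₂ relaxation.** Per-residue mono-exponential fits
  I(t) = I₀·exp(−R₂t) (nonlinear least squares, log-linear initialisation,
  covariance standard errors) and robust detection of conformational-exchange
  segments (R₂ > median + k·1.4826·MAD over contiguous runs).
- **Proline cis/trans isomerisation** from the Cβ−Cγ shift difference
  (~5 ppm trans, ~9–10 ppm cis; configurable 7 ± 1 ppm decision band).
- **Titration hierarchy.** A residue × condition presence matrix built from
  assignment records, disappearance events per ladder rung, non-monotone
  presence audits, nucleation-site inference from exchange-flanked absent
  runs, and a structured JSON report.
- **A synthetic study generator** that plants a full ground-truth model
  (nucleation segment, radiating incorporation stages, flexible tail, noise
  levels) and emits every observable above, so each stage — and the whole
  pipeline — is testable against a known truth.

## Worked example

Generate a synthetic study (137 residues, prolines at 12/38/67, planted
nucleation at [109, 116], flexible tail [2, 32], six-rung DMSO ladder) and
run the whole pipeline on it:

```text
$ nmrtitrate simulate --seed 7 --out demo/
wrote synthetic study (seed=7) to demo

$ nmrtitrate run-all --in demo/ --out demo/report.json
nucleation: [[109, 116]]
report written to demo/report.json
```

The pipeline has recovered the planted nucleation segment [109, 116] purely
from the emitted observables: the segment is absent from the 100%-DMSO
spectrum and the R₂ fits flag its two neighbours ([97, 108] and [117, 121])
as exchange-broadened flanks. Individual stages can be run alone:

```text
$ nmrtitrate proline --shifts demo/shifts.tsv --seq demo/sequence.fasta
dmso100: Pro12 (major) dBG=5.00 ppm -> trans
dmso100: Pro38 (major) dBG=5.00 ppm -> trans
dmso100: Pro67 (major) dBG=5.00 ppm -> trans
...
```

Every X-Pro bond shows a Cβ−Cγ difference of 5.00 ppm, squarely in the trans
zone of the classifier.

```text
$ nmrtitrate relax --relaxation demo/relaxation.tsv
dmso100: R2 2.71-15.21 (mean 4.63, n=125); exchange=[(97, 108), (117, 121)]
dmso50: R2 2.59-3.18 (mean 3.00, n=30); exchange=[]
...
```

At 100% DMSO, 125 residues fit cleanly; baseline rates sit near 3 s⁻¹ while
the two exchange-broadened stretches reach ~15 s⁻¹ — these are precisely the
residues planted to vanish at the next dilution rung. The JSON report
collects the per-condition presence, propensity, exchange and packing
summaries plus the global nucleation call and incorporation order.

## Data formats

Sequences are single-record FASTA. Everything else is plain tab-separated
text with documented headers (see `nmrtitrate/io.py`): shift tables
(`condition_label, position, aa, nucleus, shift_ppm, state`), doublet lists,
CPMG series, presence matrices and random-coil reference tables. All writers
are deterministic and round-trip byte-stable. NMR-STAR import is a documented
extension point, not core.
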