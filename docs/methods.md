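# Methods

## Model and assumptions

`ionlink` links two GC-HRMS datasets of the same sample: a fragment-rich run
(EI) and a molecular-ion run (CI/APCI). Three assumptions carry the whole
method:

1. **Chromatographic identity.** A compound elutes at (nearly) the same
   corrected retention time in both runs, so pseudospectra can be paired by an
   RT window after standards-based correction.
2. **Reagent-gas signature.** A genuine (quasi-)molecular ion displays
   predictable satellite ions at fixed m/z offsets (for methane CI:
   +28.03130, +40.03130 and −16.03130 Da relative to [M+H]⁺). Ions without
   enough of these offsets are not molecular-ion candidates.
3. **Subformula consistency.** Every fragment of a molecular ion is composed
   of a subset of that ion's atoms. Given correct fragment formulas, the true
   candidate's composition should contain (almost) all of them; we test
   fragments against the candidate's [M+H]⁺ composition, which grants exactly
   one hydrogen of slack and deliberately no more — adduct rearrangements
   beyond that are treated as edge cases, not modelled.

The chain resolver exploits the fact that ppm mass accuracy is *relative*:
below ~100 m/z one formula usually survives, so fragments are processed in
ascending m/z and each ambiguous ion is resolved toward the formula best
supported (by summed weight) among previously resolved smaller fragments. If
no candidate formula contains any resolved fragment, all formulas are retained
and the ion contributes no evidence — this absorbs noise peaks and
element-introducing fragments without corrupting the chain.

The probability score of a candidate is
`100 × Σ w(supporting resolved fragments) / Σ w(all resolved fragments)` with
`w = m/z · ln(Int_rel·100 + 1)`, `Int_rel` relative to the pseudospectrum's
base peak. The log damps dominant peaks; the m/z factor encodes that heavy
fragments constrain the precursor more than light ones. Unresolved fragments
appear in neither numerator nor denominator, keeping the score a well-defined
fraction in [0, 100].

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `ppm` | 3 | mass tolerance, applied to the ion's absolute m/z everywhere (satellite search, enumeration, isotope checks) |
| `min_features_ei/ci` | 20 | minimum features per pseudospectrum; counted before isotope flagging |
| `deltas` | +28.03130, +40.03130, −16.03130 Da | expected adduct / neutral-loss offsets (methane CI) |
| `min_found` | 2 | distinct offsets required for candidacy |
| `top_x`, `top_x_mode` | 10, by m/z | candidate shortlist per EI pseudospectrum; ties at the cutoff all survive; `by_intensity` suits APCI, `off` disables |
| `rt_tolerance` | 0.05 min | pairing window and raw-search window |
| `elements` | C,H,N,O,S,Si,P 0–50 | enumeration bounds (Si for TMS-derivatized metabolomes; swap Si→Cl for e.g. organophosphorus work) |
| `noise_floor` | 0 | raw-search intensity threshold; zero because satellite ions can be extremely weak |

Element-ratio defaults: H/C ∈ [0.1, 6], N/C ≤ 4, O/C ≤ 3, P/C ≤ 2, S/C ≤ 3,
Si/C ≤ 1, Cl/C ≤ 2 (checked only when C > 0), plus
RDBE = C + Si − (H+Cl+Br)/2 + (N+P)/2 + 1 ≥ −0.5 so both odd- and
even-electron ions pass. Bromine joins the halogen term of the RDBE since it
is monovalent like chlorine. All bounds are configurable.

## Conventions and numerical choices

* **Ion mass conventions.** EI fragments are generic cations (composition
  mass − electron mass); molecular-ion candidates are [M+H]⁺ (neutral + H −
  electron), and the *neutral* formula is reported. The electron mass
  (0.00054857991 Da) is the same order as a 3 ppm window at m/z 180, so the
  convention is applied consistently on both the enumeration and scoring
  sides.
* **Enumeration** is an exact bounded DFS, heaviest element outermost, pruned
  by the residual-mass range achievable with the remaining elements; the
  lightest element's count range is solved in closed form. A visit cap
  (10⁷ combinations) guards pathological constraint windows. Output is sorted
  by |Δppm|, then Hill string, for determinism.
* **RT correction** models the inter-run shift as piecewise linear between
  standard pairs and holds the boundary shift constant outside them; mapping a
  molecular-ion-run time back to the fragment axis is then exactly linear
  interpolation through the (molion, fragment) standard pairs. With one pair,
  a constant shift. The native time axis is kept alongside (`rt_raw`) so raw
  files are always searched on their own axis.
* **Isotope flagging** marks a feature M+1 (M+2) when a strictly more intense
  group member sits 0.9970–1.0100 (1.9940–2.0100) Da below it — windows wide
  enough for ¹³C, ¹⁵N, ¹⁸O, ³⁴S and ³⁷Cl spacings. Flagged features are
  excluded from formula work but remain isotope-check evidence.
* **Isotope veto** is presence-only: an S/Cl/Br-containing formula requires
  its A+2 companion (Δ = 1.99580 / 1.99705 / 1.99796 Da) within ppm, in raw
  data when available, else among the pseudospectrum's features. No abundance
  fit is attempted — a ratio test would wrongly veto formulas whenever
  deconvolution underestimates companion intensities.
* **Tie-breaks** are all explicit: ambiguous-fragment resolution prefers
  better mass agreement, then Hill order; candidate ranking prefers higher
  score, then higher m/z, then better mass agreement; candidates with no
  surviving formula rank last at score 0. Inclusive (≤) boundaries everywhere
  so printed settings behave predictably.
* Duplicate candidates found in several paired CI pseudospectra (same m/z
  within ppm, corrected RT within tolerance) collapse to the most intense
  instance.

## What the synthetic generator emulates — and what it does not

`generate_compound_set` draws CHNO(S) neutrals (C 8–22, O 1–6, N 0–2, ring
counts 1–6, H set by valence), places them 3–37 min apart, and derives
fragments as successive common neutral losses (H₂O, CO, C₂H₄, CH₂O, C₂H₂,
CO₂, CH₃, NH₃, C₃H₆) from the [M+H]⁺ composition, so every fragment is a
strict subformula and fragments form nested chains, as real fragmentation
cascades do. Fragment-mass uniqueness at the working tolerance is *verified at
build time* by enumeration; a configurable fraction of compounds instead keeps
exactly one multi-formula fragment to exercise the chain resolver. Rendering
adds ¹³C isotopologue peaks, exact A+2 companions for S/Cl-bearing species,
residual CI fragmentation, Poisson noise features, an affine (or constant) RT
distortion with matching standards, and centroid raw scans consistent with the
peak lists.

Sulfur-bearing compounds rarely pass the uniqueness screen — at 3 ppm their
mid-mass fragments almost always collide with multi-S/Si/P alternatives — so
the generated sets are predominantly CHNO; S/Cl behaviour is covered by
dedicated constructed fixtures rather than the random generator.

Passing tests on these fixtures demonstrate the machinery (matching,
candidate logic, enumeration, chain scoring) under controlled truth; they do
not demonstrate robustness to real-world deconvolution artifacts: co-eluting
isomers, chimeric pseudospectra, mass-calibration drift, detector saturation
and electron-capture chemistry are all absent from the generator.

Study sizes used by the test suite and the acceptance script — 50 compounds
for recovery statistics, 8 for the co-elution stress, 200 random instances for
enumeration-oracle equivalence — keep a full run in the low minutes on one
core while leaving the statistics stable across seeds.

## Known limitations

* A heavier co-eluting compound whose composition contains the target's
  fragments scores at least as well as the true ion and wins the high-m/z
  tie-break; the true ion then lands at rank 2–4. This is inherent to the
  scoring model; the top few comparable-score candidates should be treated as
  a shortlist.
* If the soft-ionization chemistry yields no adduct pattern (or no molecular
  ion), the candidate list is empty — correctly reported, but not recoverable
  algorithmically.
* mzML reading supports the common encodings (32/64-bit floats, zlib or no
  compression) via the built-in reader; exotic encodings (numpress) are not
  handled. mzXML goes through pyteomics.
* Negative-mode ionization and adduct chemistry beyond user-declared m/z
  differences are out of scope.
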