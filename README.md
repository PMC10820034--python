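# ionlink

Assigning molecular ions to fragment-rich GC-HRMS spectra across two
ionization techniques.

## The problem

Electron ionization (EI) at 70 eV produces reproducible, library-searchable
fragment spectra — but frequently destroys the molecular ion, so the molecular
mass of an unknown cannot be read off the spectrum. Soft techniques such as
chemical ionization (CI, e.g. with methane reagent gas) or APCI preserve a
(quasi-)molecular ion, typically [M+H]⁺, but deliver it in a *separate run*
with its own retention-time axis and its own deconvoluted peak list. Connecting
"this EI fragment spectrum" with "that CI molecular ion" is normally manual,
per-compound expert work.

`ionlink` automates that connection for high-resolution data. Given two
deconvoluted peak lists (features with m/z, retention time, intensity and
pseudospectrum group), it:

1. drops undersized pseudospectra and flags M+1/M+2 isotopologue peaks;
2. maps the molecular-ion run's retention times onto the fragment run's axis
   through co-injected RT standards (piecewise-linear shift);
3. pairs pseudospectra co-eluting within a tolerance window (default 0.05 min);
4. searches each paired CI pseudospectrum for ions displaying the expected
   adduct/neutral-loss m/z differences — for methane CI: +28.03130
   ([M+C₂H₅]⁺), +40.03130 ([M+C₃H₅]⁺), −16.03130 ([M+H−CH₄]⁺) — optionally
   falling back to the raw file (mzML/mzXML) for satellites too weak to
   deconvolute, and keeps the top-x candidates by m/z;
5. enumerates elemental formulas for every fragment and candidate under
   user-set element bounds and ppm tolerance, prunes them with element-ratio
   heuristics and ring-double-bond equivalents, and vetoes S/Cl/Br formulas
   whose diagnostic A+2 isotope peak is absent;
6. resolves each fragment to one formula by a bottom-up chain (small ions are
   unambiguous; larger ambiguous ions are scored by the already-resolved
   smaller fragments their formulas contain), with each resolved fragment
   carrying the weight

   *w = m/z · ln(Int_rel · 100 + 1)*

   where Int_rel is intensity relative to the base peak;
7. ranks the molecular-ion candidates of each EI pseudospectrum by the
   percentage of total resolved-fragment weight whose formulas fit inside the
   candidate's [M+H]⁺ composition — the reported **probability score** — and
   writes one ranked CSV block per fragment pseudospectrum.

The output is a short, scored candidate list per chromatographic peak, ready
for downstream identification tools that need a molecular mass as input.

## Worked example

Everything below is generated — no instrument data needed. The synthetic
generator builds compounds with known formulas, renders paired EI/CI peak
lists, raw runs and RT standards, and remembers the truth:

```python
import ionlink as il

compounds = il.generate_compound_set(10, seed=1)          # known ground truth
ds = il.render_datasets(compounds, seed=1)                # affine RT distortion

il.write_peaklist(ds.ei_table, "ei.csv")
il.write_peaklist(ds.ci_table, "ci.csv")
il.write_mzml(ds.ei_raw, "ei.mzML")
il.write_mzml(ds.ci_raw, "ci.mzML")
il.write_rt_standards_csv(ds.rt_standards, "standards.csv")
```

```sh
ionlink run --ei-peaks ei.csv --ci-peaks ci.csv \
            --ei-raw ei.mzML --ci-raw ci.mzML \
            --rt-standards standards.csv --out results.csv
```

`results.csv` then begins:

```
ei_group_id,rank,candidate_mz,candidate_rt,assigned_formula,probability_score,n_supporting_fragments,adduct_evidence
E1,1,158.11756,2.9644,C8H15NO2,100.00,8,+28.03130;+40.03130;-16.03130
E10,1,275.21179,37.0038,C17H26N2O,100.00,7,+28.03130;+40.03130;-16.03130
E2,1,281.14958,6.8226,C14H20N2O4,100.00,8,+28.03130;+40.03130;-16.03130
...
```

Read: for fragment pseudospectrum `E1` the best (rank 1) molecular-ion
candidate is the ion at m/z 158.11756 whose neutral formula is C₈H₁₅NO₂; 100%
of the weighted, formula-resolved fragment evidence (8 fragments) is
consistent with that composition, and all three methane-CI m/z differences
were observed. A score well below 100 means part of the fragment evidence does
not fit — either noise, or a wrong candidate.

Known limitation (by design of the score): when a *heavier* compound co-elutes
within the RT tolerance, its larger composition tends to contain the true
compound's fragments too and wins the higher-m/z tie-break, pushing the true
ion to rank 2–4. Treat the top few candidates with comparable scores as a
shortlist, not a verdict.

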