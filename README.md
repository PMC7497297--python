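# mzannotate

Putative metabolite annotation for direct-infusion mass spectrometry
(DI-MS), for metabolomics analysts who need to go from a peak table of
unidentified m/z values to ranked compound identities without a network
connection or a fixed vendor database.

DI-MS detects tens of thousands of m/z features at part-per-million
accuracy with no chromatographic separation, so annotation rests entirely
on mass matching. `mzannotate` covers the whole minimal workflow:

1. **Database build** — a user-supplied compound table (identifier, name,
   molecular formula, optional SMILES) is expanded into the ionic m/z of
   every adduct and low-order isotopologue and stored in an indexed
   single-file SQLite database. The adduct m/z is

   ```
   m/z = (x·M + m(added) − m(removed) − q·mₑ) / z
   ```

   with `M` the neutral monoisotopic mass, `x` the molecular multiplier
   (2 for dimers), `z` the charge magnitude, `q = ±z` by polarity, and
   `mₑ` the electron mass. The shipped rule set has 20 adducts over both
   polarities ([M+H]+, [M+Na]+, [2M+H]+, [M−H]−, [M+Cl]−, ...) plus
   13C/2H/15N/18O/34S/37Cl isotopologues with per-element binomial
   relative abundances.
2. **Search** — a measured m/z matches every stored theoretical m/z inside
   the closed relative window `mz·(1 ± ppm·10⁻⁶)` (default 2 ppm); hits
   are ranked by |ppm error| = |10⁶·(observed − theoretical)/theoretical|
   and can be re-prioritized by isotope status (main peak first) and
   adduct status (plain (de)protonation first).
3. **Formula prediction** — for m/z values with no database hit,
   candidate formulas are enumerated by branch-and-bound over CHNOPS
   counts and filtered by valence (RDBE ≥ 0 and integral for neutral
   even-electron molecules) and element-ratio plausibility bounds
   (H/C ∈ [0.2, 3.1], N/C ≤ 1.3, O/C ≤ 1.2, P/C ≤ 0.3, S/C ≤ 0.8).
4. **Statistics** — sample normalization, missing-value imputation,
   per-feature Welch/paired t-tests with Benjamini–Hochberg FDR control,
   fold changes for volcano plots, and a hypergeometric test for the
   significance of overlap between two hit lists.
5. **Simulation** — seeded generators for compound tables, query pools
   and two-group case/control peak experiments with planted effects, so
   every stage is testable offline.

## Worked example

The best-known DI-MS annotation story is the urinary lung-cancer marker
at nominal 264 m/z, later identified as creatine riboside (C9H17N3O6).
Build the bundled demo database and search the measured value:

```python
import mzannotate as mz

db, report = mz.build_extended(mz.demo_compounds(), store_path="demo.db")
hits = mz.search(db, mz.SearchQuery(mz=264.1190, ppm=2.0, polarity="+"))
for h in hits:
    print(h.name, h.adduct, h.isotope, round(h.theoretical_mz, 6),
          round(h.ppm_error, 3))
```

prints

```
Creatine riboside [M+H]+ M0 264.119012 -0.044
```

i.e. the single 2-ppm hit is the protonated main peak of creatine
riboside, 0.044 ppm below the query; rounding 264.119012 to nominal mass
gives the 264 m/z feature. The same answer comes out of formula
prediction with no database at all:

```sh
$ mzannotate predict-formula --mz 264.1190117 --adduct "[M+H]+" --ppm 3
formula     mass       ppm_error  rdbe  element_counts  rdbe_ok  ratios
C9H17N3O6   263.111735  -0.000     3     True            True     True
C11H24NP3   263.112160  -1.613     2     True            True     True
```

The true formula ranks first at essentially zero ppm error; the lone
competitor inside 3 ppm is an implausible triphosphine that a P-count
prior would remove.

The equivalent shell workflow is `mzannotate build-db`, `search`,
`stats` and `simulate`; each subcommand documents itself with `--help`.

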