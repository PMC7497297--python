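# Methods

## Mass arithmetic

All theoretical masses derive from a pinned element table
(`mzannotate._elements`, version string `CIAAW-2013/mzannotate-1`,
recorded in every database build's metadata): monoisotopic masses and
isotopic abundances at the 1e-8 u level, electron mass
0.000548579909 u. The monoisotopic mass of a formula is the sum of
most-abundant-isotope masses; the proton m/z (monoisotopic H minus one
electron) is 1.0072765 u.

Formula strings are a flat dialect — element symbols with optional
positive counts, any order, no parentheses, hydrates, charges or
isotope labels — matching the expanded formulas of HMDB-style exports.
Formatting uses Hill order and round-trips through the parser.

Ring-plus-double-bond equivalents use fixed common valences,

    RDBE = C + Si − (H + F + Cl + Br + I)/2 + (N + P)/2 + 1,

ignoring hypervalent states (S(VI), P(V)); a neutral even-electron
molecule must have integral, non-negative RDBE.

## Adduct and isotopologue expansion

An adduct rule is a symbolic transformation (name, polarity, multiplier
x, charge magnitude z, atoms added/removed). The ionic m/z is
`(x·M + m(added) − m(removed) − q·mₑ)/z` with `q = ±z`; the electron
mass is always applied because ppm-level matching is sensitive to half
a millidalton at low mass. The shipped default set contains 20 rules
over both polarities, following the de-facto standard adduct tables of
ESI practice, with |z| ≤ 2; custom rule files (CSV/TSV) are accepted.

Isotopologues are generated per element channel (13C up to 3
substitutions; 2H, 15N, 18O, 34S, 37Cl up to 1), with m/z shifted by
`k·Δm/z` and relative abundance from the per-element binomial ratio
`C(n, k)·(p/(1−p))^k`, where `n = x·count(element)` (a dimer doubles
the substitutable atoms). Cross-element doubly-heavy species are not
generated — variant labels stay single-channel ("13C2"), which matches
how annotation tables are usually reported and keeps row counts linear.
Variants below a relative-abundance floor (default 1e-4) are dropped;
variants whose m/z would be non-positive (removal rules on very small
molecules) are discarded with a warning.

## Database build and deduplication

Compound tables are CSV/TSV with identifier, name and formula columns
(SMILES, description, synonyms optional). Records with an identical
SMILES string are collapsed into one row — first-seen name wins, the
synonym list is the case-insensitive union of the other names,
descriptions concatenate deduplicated — while records with the same
formula but different structures stay separate, and records without a
SMILES are never merged. SMILES are compared as exact strings by
default (deterministic, no cheminformatics dependency); RDKit
canonicalization is available behind a flag.

The store is one SQLite file with `compounds` and `variants` tables, an
index on (polarity, m/z), and build metadata (element-table version,
rule-set hash, row counts). m/z values are stored as 8-byte floats and
the ppm window is computed at query time, so one build serves any
tolerance. Builds are idempotent (rebuild replaces); a table in which
more than half the formulas fail to parse aborts the build, since that
indicates a malformed input rather than a few bad rows. Deleting a
compound cascades to its variant rows.

## Search semantics

The ppm window is closed on both ends (a theoretical m/z exactly on the
boundary is a hit) — the common convention, chosen because the
alternative is untestable at floating precision. Hits are sorted by
absolute signed ppm error with lexicographic (source, compound,
adduct) tie-breaking so output order is total and reproducible. The
default tolerance is 2 ppm, appropriate to DI-MS mass accuracy, and
always overridable. Polarity "both" unions the two polarities' rows.
Ranking is joint across source databases, with the source recorded per
hit. Batch search distributes queries over threads; results are
guaranteed identical to serial execution regardless of worker count.
Post-annotation prioritization is a stable re-sort: main-peak (M0)
records first, then plain protonation/deprotonation adducts before
salts, dimers and losses, then |ppm error|.

## Formula prediction

The neutral mass is recovered by the exact algebraic inverse of the
adduct equation. Enumeration is depth-first over elements in decreasing
mass order with residual-mass pruning (and a closed-form count range
for the lightest element), which is complete within the per-element
bounds; a candidate cap (default 10,000) turns uselessly wide windows
into an explicit error. Default bounds scale with mass
(`floor(mass/element mass) + 1`) with fixed caps P ≤ 6 and S ≤ 8.

Of the classical heuristic filters for formula generation from accurate
mass, three are implemented: mass-scaled element-count ranges, RDBE
validity (non-negative; integral under the default even-electron
neutral assumption, toggleable for radicals), and element-ratio bounds
H/C ∈ [0.2, 3.1], N/C ≤ 1.3, O/C ≤ 1.2, P/C ≤ 0.3, S/C ≤ 0.8
(configurable). Ratio checks apply only when carbon is present, so
carbon-free inorganics such as H2O are not spuriously rejected while a
bare C atom still fails the H/C lower bound. Filters that need
measured isotope-pattern intensities or MS/MS are out of scope.

## Statistics

Normalization order is sample method (total-sum to unit row sum, or
per-sample median), then log10(x+1) transform, then feature scaling
(auto or pareto). Imputation strategies: half-minimum per feature (fast
default), KNN, and iterative random-forest regression capped at 3
rounds and seeded; observed values are never altered, and features with
no observed value are dropped with a warning.

The two-group test is Welch's unequal-variance t by default (the safer
choice when group variances differ), or a paired t; features constant
across all samples are flagged and excluded from testing and from the
Benjamini–Hochberg step-up adjustment (Bonferroni selectable). Fold
changes are log2 ratios of group means on the raw intensity scale even
when testing is done on the log scale, mirroring standard volcano-plot
convention; zero denominators yield flagged infinities that volcano
output excludes. Overlap significance between two hit lists is the
exact hypergeometric upper tail P(X ≥ overlap); the universe defaults
to the tested feature set and is overridable.

## Synthetic data

The generators define the study conditions under which the package is
validated. Compound tables are drawn by rejection sampling over CHNOPS
counts so every formula passes the plausibility rules, with neutral
masses in 60–600 u (the span of small-molecule metabolomes and of the
query pools used for performance characterization); duplicate-SMILES
and duplicate-formula records can be injected to stress both
deduplication paths. Structure keys on synthetic compounds are random
SMILES-alphabet strings, not chemistry — they exist to exercise
exact-string merging.

Query pools are stratified-uniform over 60–600 m/z: one draw per
equal-width bin, so coverage is even but not gridded.

Peak experiments are two-group log-normal: per-feature log10 means
uniform on [4, 6] (typical ion-count magnitudes) and log10 standard
deviations uniform on [0.2, 0.6]; planted features shift the case-group
log-mean by `effect`·sd (default effect 2, 10 planted of 200 features,
20 samples per group); missing values are injected completely at
random. This emulates the variance structure and dynamic range of
DI-MS intensities but not peak-shape artifacts, correlated features,
batch effects, or intensity-dependent (MNAR) missingness — so passing
tests demonstrate statistical correctness of the pipeline, not
robustness to those real-data pathologies; in particular the advantage
of model-based imputation under MNAR is out of scope.

The scaling harness builds nested databases of increasing size and
reports per-query latency and match counts; timings are hardware-bound
and are reported, never asserted.

## Problem sizes and numerical choices

The validation suite uses a 500-compound synthetic database (~65k
variant rows) for round-trip and search-oracle checks, 20 random masses
in 60–400 u for the enumeration oracle, universes up to 20 for exact
hypergeometric comparison, and 200 pure-noise replicates (200 features,
20 samples per group) for null calibration — sizes at which the
independent oracles (full linear scan, nested-loop enumeration,
rational-arithmetic tail sums) remain exactly computable. Determinism
contracts: all generators are pure functions of their seed; database
builds of identical inputs produce identical row multisets; search
results are independent of worker count. Floating tolerances: stored
m/z reproduces recomputation to 1e-9 u; mass constants are pinned to
1e-6 u.

## Known limitations

Exact-string SMILES comparison treats tautomer/kekulization variants as
distinct unless canonicalization is enabled. Isotope fine structure,
retention-time and MS/MS evidence, probabilistic annotation scoring,
charge states beyond |z| = 2, and multivariate statistics (PCA, PLS-DA,
machine-learning classifiers) are deliberately outside the package;
annotations are putative (MSI level 2) and require confirmation with
authentic standards.
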