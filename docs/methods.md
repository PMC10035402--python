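# Methods

This note documents the models, parameters, and design choices behind
`mrith`, in the spirit of a statistical-software methods appendix.  Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Clonality model

A patient's somatic variants are merged across tumor biopsies on the
normalized identity key `(chrom, pos, ref, alt)` (variants 1-based, VCF
convention; indels are classified identically to SNVs).  With `k` present
biopsies of `n`:

| condition            | label     |
|----------------------|-----------|
| `k = n`, `n >= 2`    | CLONAL    |
| `1 < k < n`          | SUBCLONAL |
| `k = 1`, `n >= 2`    | PRIVATE   |
| `k = 0` or `n = 1`   | NONE      |

NONE covers the two ways a variant can be aberrant in this data model: no
presence survives merging, or the patient has a single tumor biopsy so
clonality is unassessable.

### Forced-call rescue

Low tumor purity, allele-specific imbalance, or heterogeneous amplification
can push a truly clonal variant's allele fraction below the caller's
detection limit in one biopsy, making a clonal mutation look subclonal
(*pseudoheterogeneity*).  When a sister biopsy carries the call, each absent
biopsy with depth `d >= min_depth` is re-examined on its raw counts and
marked present-and-rescued iff all of:

* `alt_reads >= min_alt_reads` (default 3),
* `alt_reads / d >= min_vaf` (default 0.01),
* the upper-tail binomial probability of `>= alt_reads` error reads in `d`
  trials at `error_rate` (default 1e-3) is `<= max_binomial_p` (default 0.01).

Biopsies with `d < min_depth` (default 20) are flagged unevaluable and left
absent.  The thresholds are deliberately conservative against sequencing
error at ~336× panel depth and are all exposed in `RescueParams`.  Rescue
runs before classification and is monotone: stricter thresholds never add
presences, and rescue never removes a called presence.  At default
simulation error rates the binomial gate admits roughly one spurious rescue
per ~2,000 non-carrier biopsy-sites (four error reads at 336×); with
`error_rate = 0` in simulation no private variant is ever promoted.

## Subtype cascade

Evidence is aggregated per patient — maximum EBV on-target read fraction
across biopsies, one patient-level MSI score, mean per-biopsy CNV-altered
fraction — then passed through EBV → MSI → CIN → GS:

* **EBV**: read fraction `>= 1e-4` (separates true viral presence from
  index bleed-through).
* **MSI**: score `>= 3.5` percent unstable loci, the conventional cutoff of
  microsatellite-instability callers.  The score is a simplified per-locus
  test: tumor vs normal repeat-length histograms compared by a chi-square
  homogeneity test with adjacent length bins pooled until every expected
  cell is at least 1, Benjamini–Hochberg adjustment across loci within the
  tumor/normal pair, instability at adjusted p < 0.05, and at least 20
  assessable loci (>= 20 reads in both histograms) required.
* **CIN**: fraction of panel bases inside segments with `|log2 ratio| >=
  0.3` reaching `>= 0.20` (interval-union, no double counting).  This is
  the weakest link for real-data concordance: the CIN/GS boundary is not a
  published rule, so both numbers are exposed parameters.
* **GS**: the fall-through.

## Phylogeny construction

Each distinct presence bitmask is a candidate edge weighted by its mutation
count.  A set of masks that is pairwise nested-or-disjoint (laminar) defines
a perfect phylogeny; conflicts are resolved greedily — visit patterns by
descending count (ties: smaller bitmask first), accept iff compatible with
everything accepted.  The greedy choice is transparent and near-optimal at
<= 6 biopsies; the test suite compares it against exhaustive maximum-weight
search on small instances and prints any instance where it falls below 90%
of the optimum (the mean ratio across seeded random instances is asserted;
adversarial instances below 90% exist and are reported, not hidden).
Dropped patterns are written to a conflict report, never silently discarded.

The tree is the Hasse diagram of bitmask containment rooted at the
full-biopsy trunk (inserted with length 0 when absent); every biopsy ends in
a leaf edge (length 0 when it has no private mutations).  Branch lengths are
raw mutation counts — no rate scaling — so the trunk length is the clonal
burden.  Serialization is Newick with the trunk as root edge length.

## Signature refitting

SNVs with reference-strand trinucleotide contexts are collapsed onto the
pyrimidine strand and binned into the 96 COSMIC-style classes
(lexicographic label order).  Refitting is single-sample forward selection:
starting from all-zero weights, each iteration tunes one signature's weight
on [0, 1] by golden-section search (absolute tolerance 1e-5) to minimize
the sum of squared errors between the renormalized weighted reconstruction
and the observed frequency vector, adopts the best-improving signature
(catalog order breaks ties), and stops when the best SSE decrease falls
below `tol` (default 1e-3).  After each adoption weights are renormalized
to sum to 1, which leaves the reconstruction unchanged but keeps the
single-weight search scale meaningful.  Final weights below `cutoff`
(default 0.06) are zeroed and survivors renormalized; the 6% cutoff and
error tolerance follow the published defaults of the forward-selection
refitting approach.  With the default `tol` the stopping rule can leave
multi-component weights ~0.02–0.03 from their optimum; validation tests
that probe asymptotic consistency pass a tighter `tol`.

Stratified fits pool mutations across patients within each (group,
clonality-stratum) cell — clonal vs nonclonal (subclonal + private), NONE
excluded — because stratum-level statements are the analysis target;
per-spectrum fits remain available.  Cells under the 20-mutation floor are
reported `insufficient`, not fitted.  No opportunity-space renormalization
(exome vs genome context abundance) is applied; contexts are treated as
directly comparable to the catalog, a documented limitation.

### Synthetic catalog

COSMIC v3.2 probability values are not redistributable here, so the default
catalog is an explicitly synthetic stand-in
(`signatures.synthetic_catalog`, written to
`signature_catalog.synthetic.tsv` by the simulator): 11 signatures under
the COSMIC SBS names relevant to gastric tumors (SBS1, 3, 4, 5, 6, 10b, 15,
18, 21, 24, 26), each concentrating 85% of its mass on eight exclusive peak
contexts over a 15% uniform background, from a fixed pseudorandom partition.
The disjoint peaks make the recovery tests sharp; they also make separation
easier than with real COSMIC profiles, so recovery results here bound the
synthetic setting only.  Any 96-row catalog TSV can be swapped in.

## Annotation rules

"Likely pathogenic" is the five-clause disjunction: loss-of-function effect
(nonsense, frameshift, splice); known hotspot (exact-match lookup); ClinVar-
pathogenic (exact key lookup); amplification of a listed oncogene; complete
deletion of the gene or its wild-type allele (requires an explicit upstream
LOH/whole-gene flag — this package does not infer LOH).  Long genes are
those strictly above the 75th percentile (type-7 linear interpolation) of
panel CDS lengths.  Gene burden is SNV count divided by CDS kbp.  Recurrence
tables count each patient once per gene, exclude silent effects, and can be
restricted to MSS or MSI patients.  All resource lists (hotspots, ClinVar
keys, oncogenes, the 58-gene druggable list) are user-supplied files; no
downloads.

## Cohort statistics

* Mutation rates: counts divided by the panel target size in Mbp (3.75 Mbp
  for the default synthetic panel, matching the targeted design).
* Two-sample t: pooled-variance Student by default, Welch optional; missing
  values dropped and counted.  The country age comparison groups Colombia
  against pooled Mexico + USA.  On the bundled table this gives means
  54.6 vs 66.9 years with pooled-t p = 0.009; the source clinical report
  quotes p = 0.020 for this comparison, which does not re-derive from the
  printed ages under any standard two-sample variant we tried — the
  package reports the computed statistic and flags the discrepancy rather
  than matching it.
* Exact r×c test: Freeman–Halton probability-ordering rule (all tables with
  the observed margins whose conditional probability is <= the observed,
  with 1e-12 slack for ties), by full enumeration up to total n = 40 and by
  seeded Monte-Carlo permutation sampling (default 1e6 draws) above.  The
  2×2 case coincides with the classical two-sided Fisher test.
* "Advanced stage" is AJCC III/IV with known-stage patients as the default
  denominator (an all-patients denominator is an option).  Percents and
  printed means round half-away-from-zero, matching clinical-table style.

## Synthetic cohort generator

The generator defines the study conditions for every recovery test:

| parameter | default | rationale |
|---|---|---|
| patients / biopsies | 32 / 2–6 each | multiregion gastric study shape |
| subtype probabilities | 2:4:12:14 over EBV/MSI/CIN/GS | observed cohort composition |
| mutation burden (Poisson mean) | MSI 170, EBV 25, CIN 26, GS 22 | hypermutator MSI; implied by per-subtype clonal means and fractions |
| clonal fraction | EBV 0.34, MSI 0.36, CIN 0.27, GS 0.27 | per-subtype clonal SNV fractions |
| subclonal:private split | 16:52 of the non-clonal mass | cohort-wide label proportions |
| purity | U(0.3, 0.7) per biopsy | typical panel purity range |
| depth | Poisson(336) per site | mean tumor panel depth |
| error rate | 1e-3 per base | Illumina substitution error scale |
| caller threshold | 8 alt reads | reproduces low-VAF censoring with one parameter |
| silent / indel fractions | 0.45 of SNVs / 0.10 of mutations | panel coding-mutation proportions |

Observed reads follow the diploid model: expected VAF = purity × CCF / 2
with CCF 1 in carrier biopsies and 0 elsewhere — no mutation multiplicity
or copy-driven VAF distortion.  Subclonal carrier sets are uniform over
proper subsets of size >= 2 (the neutral choice; two-biopsy patients can
therefore only show clonal or private truth).  `called` means
carrier-and-above-threshold, so a zero threshold observes the truth exactly
— the basis of the perfect-recovery oracle tests.  MSI patients shift the
tumor length histograms of 20% of 100 microsatellite loci by 3 repeat
units; CIN patients get clonal |log2| >= 0.58 segments covering 35% of the
panel; EBV patients get read fractions U(0.005, 0.02) against a < 2e-5
background — all well separated from the decision thresholds, which is why
subtype recovery is expected to be 100% and tested as such.  Demographics
(sex, age, country, histology, stage) are drawn from plausible marginal
distributions for output realism only; no test depends on them.

All draws come from one seeded NumPy generator in a fixed order, so a
config+seed pair is byte-reproducible, including the emitted file bundle.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: copy-number-coupled allele fractions, mutation
multiplicity, shared ancestry between subclones beyond the bitmask
structure, caller-specific artifact modes, germline contamination, and
real COSMIC signature overlap.

## Problem sizes and determinism in the shipped checks

The test suite simulates cohorts of 8–400 patients (the 400-patient
single-subtype cohort exists to pool >= 2,000 clonal SNVs for stratified
signature recovery); the acceptance script uses 32-patient cohorts,
10,000-mutation spectra, and 20,000-draw Monte-Carlo comparisons.  All
seeds are fixed or derived from the `--seed` argument; hypothesis-based
property tests use bounded examples with no time-dependent behavior.

## Known limitations

* The CIN/GS threshold and the patient-level evidence aggregation
  (max/max/mean) are pragmatic choices; real-data concordance should be
  sensitivity-tested against them.
* The greedy conflict resolver is not exact maximum parsimony; adversarial
  pattern sets can drop more mutations than necessary (reported in the
  conflict file).
* Signature refitting inherits forward selection's greedy bias and the
  early-stopping sensitivity noted above; it performs no de novo
  extraction and no indel/doublet signatures.
* The bundled catalog is synthetic; scientific use requires a real COSMIC
  (or equivalent) catalog TSV.
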