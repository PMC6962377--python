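# Methods

This note documents the models, estimators and numerical choices behind
`mechanomir`, and what its synthetic data can and cannot establish.

## Scientific setting

Glioblastoma (GBM) growth inside the rigid skull exerts low compressive
solid stress (tens to ~200 Pa) on tumor and parenchymal cells. The package
quantifies three readouts of GBM cell lines (LN229, U251) compressed at
13–115 Pa in a transwell model: collective migration in a wound-healing
assay, single-cell shape (aspect ratio, AR), and downstream transcriptomic
signaling summarised through a miRNA–mRNA pathway interaction analysis.

## Wound closure

For each replicate, the cell-free gap area is measured at 0 h and 18 h and

    WC = (A_initial − A_final) / A_initial.

Because absolute closure varies day to day, conditions are summarised as the
matched-pair differential closure ΔWC = mean(WC_exp − WC_ctrl), in
percentage points, over replicates run the same day. Significance is a
one-sided paired t test (closure greater than control) at α = 0.05/5 = 0.01,
Bonferroni-corrected for the five pressure-versus-control comparisons.
Pairing is by explicit replicate id, never row order. The paired test is run
on raw per-replicate WC differences (whether the original analysis
normalised first is not stated; raw differences are the simplest faithful
reading). With zero variance across differences the t statistic is
undefined; the degenerate case maps to p = 0 for a uniformly positive
difference and p = 1 otherwise, so constant synthetic inputs behave sanely.

The convenience statistic `fold_increase(wc_ctrl, ΔWC) =
(100·wc_ctrl + ΔWC)/(100·wc_ctrl)` restates a differential in fold terms
(57.0% control closure + 23.2 pp ≈ 1.4×).

**Segmentation.** The cell-free gap is the largest dark connected component
after global thresholding and a 3-px binary closing. The threshold is the
histogram valley (`threshold_minimum`), falling back to Otsu when the
intensity histogram is unimodal. Otsu alone was rejected: when the residual
gap occupies a small minority of pixels its between-class-variance optimum
drifts into the cell-lawn intensity mode and the "dark" class swallows half
the lawn. Thresholding operates on a float view of the image so the
histogram stays at 256 bins regardless of integer bit depth. Uniform images
raise a degenerate-input error.

## Aspect-ratio mixture model

AR ≥ 1 by construction, so distributions are modelled on x = AR − 1. The
1-term density is a scaled lognormal

    f(x) = a · (x σ √(2π))⁻¹ · exp(−(ln x − µ)² / (2σ²)),

and the 2-term form is the sum of two such components. Each component peaks
at mode m = exp(µ − σ²) + 1 on the AR scale; a secondary component with
m ≥ 2 is read as a mechanically induced elongated subpopulation, while a
secondary mode below 2 describes two rounded subpopulations and is flagged
as not relevant.

**Histogramming.** Fixed bin width 0.1 AR over [1, 99.5th percentile],
density-normalised (integrates to 1 over the binned support), so SSE is
comparable across conditions and the fitted scale weights sum to ≈ 1.

**Fitting.** Bounded least squares (`scipy.optimize.least_squares`, trf) on
the histogram densities, parameters (a, µ, σ) per term with a ∈ [0, 2],
σ ∈ [0.01, 2]. The model predicts each bin's *integrated* component mass
divided by bin width (lognormal CDF differences) rather than the pdf at the
bin centre: the narrowest published secondary component (σ² = 10⁻⁴) is far
narrower than a bin, where centre evaluation is ill-posed but bin
integration remains smooth. Initialisation: weighted method of moments
(1-term); for 2-term, an exact weighted two-means split of ln x over bins
seeds the two components, and an additional start places the second
component at the largest positive residual of the 1-term initial fit (this
is what finds sub-bin-width spikes). Five further multistarts jitter the
base start (seeded, deterministic). Unweighted residuals are used; the
original analysis quotes plain SSE with no weighting statement.

**Model selection.** Between the 1- and 2-term fits of the same histogram,
smaller SSE wins (equivalently higher R², since both share the total sum of
squares; if the two rankings ever disagree SSE governs and a warning is
recorded; exact ties go to fewer terms). Because the models are nested, the
2-term fit always shaves some SSE off, so two identifiability guards are
applied before it can displace the 1-term fit:

* the SSE reduction must exceed the histogram's expected multinomial
  sampling-noise SSE, Σⱼ pⱼ(1−pⱼ)/(n w²) — reductions at or below this
  level are indistinguishable from noise chasing;
* the two fitted modes must be separated by at least one bin width —
  closer components are not resolvable as two populations at the histogram
  resolution.

Both guards err toward parsimony: in seeded simulations the rule never
invents a second population in single-component data, at the price of
occasionally missing a very faint one (a secondary carrying ~5% of the
mass under a heavy-tailed primary is near the detection floor at
n = 2000). Zero-variance histograms, fewer than 8 bins, or n < 50 raise a
fit error rather than returning garbage.

**Elongation statistic.** `percent_elongated` is the share of non-excluded
cells with AR ≥ 2. Cells touching the image border are auto-excluded from
mask measurements; dividing-cell exclusion cannot be inferred from a mask
and is accepted as an input flag.

## Condition presets

`data/presets.json` registers ten conditions (two cell lines × five
pressure conditions) used by every generator. Published constants carried
per condition: the 1–2 component peak modes, the fit R², the two quoted
secondary variances (10⁻⁴ at 23 Pa, 1.5×10⁻³ at 47 Pa), control wound
closures (57.0% LN229, 36.7% U251), the differentials printed for 23 Pa
(+23.2 / +17.8 pp) and U251 115 Pa (+13.6 pp), and the printed elongation
percentages (39.1% at LN229 23 Pa, 21.0% agar control, 5.8% U251 115 Pa).
Everything else is a documented stand-in chosen once: secondary component
weight 0.10 at LN229 23 Pa (its secondary peak was described as comparable
in height to the primary) and 0.05 elsewhere; unquoted secondary σ = 0.05;
unprinted elongation fractions fixed so each cell line's five-condition
average equals its printed average (23.8% LN229, 33.0% U251); unprinted
closures set to small plausible offsets. Component locations follow from
the modes by inverting the mode formula (µ = ln(m − 1) + σ²), and each
primary σ is solved numerically so the mixture's exact P(AR ≥ 2) equals the
condition's elongation fraction — every preset is therefore simultaneously
consistent with its published peak locations and its published elongation
percentage. The JSON is frozen output of `build_default_registry()`; a test
asserts they agree.

## Differential-expression filtering

The pipeline consumes, never computes, the upstream microarray statistics
(the empirical-Bayes ANOVA and FDR adjustment are performed by array
software). The filter keeps rows with p < 0.05 AND FDR < 0.05 AND
|FC| > 2, all strict, matching the printed criteria; boundary values are
excluded. Fold changes are signed with |FC| ≥ 1 (−2.03 = 2.03-fold down).
Survivors split by feature type into the coding-gene set and the
precursor-miRNA set; unknown types are routed out with a warning. Two
fixture tables transcribe the published panels: nine selected coding genes
(FC and FDR as printed; raw p set equal to FDR as a synthetic upper-bound
placeholder) and the 27 differentially regulated precursor miRNAs (FC as
printed; p and FDR set to a nominal significant 0.01 since only FC was
published; the two-class GBM-relevance split of the table is preserved).

## Interaction analysis

Per differentially regulated precursor miRNA, a pathway-database export
lists enriched pathways with an enrichment p and the miRNA's target genes
in each pathway. Processing steps:

1. **Substitution.** Array-reported ids map one-to-one to database ids
   (host-gene reports, precursor variants with identical mature sequence,
   isoform merges); unmatched ids pass through; conflicts are configuration
   errors. Both 5p/3p arms are treated under the precursor id.
2. **Consolidation.** Duplicate (miRNA, pathway) rows — e.g. the same
   pathway from two source databases — merge: target sets union, minimum
   enrichment p kept, database labels joined.
3. **Classification.** Each pathway name is assigned to one of seven groups
   (Cancer, Motility, DNA Repair, Cell Cycle, Apoptosis, Miscellaneous,
   Canonical) by ordered include/exclude keyword rules with Miscellaneous
   as total fallback. The shipped rules are editable reconstructions; the
   DNA Repair rule excludes "signaling" so that signaling-network pathways
   mentioning ATM land in Canonical, matching the published grouping.
4. **Scoring.** Per node: `intersects` = enrichment p < 0.05 (taken from
   the export — enrichment is the database's computation; an in-package
   hypergeometric recomputation was deliberately not substituted);
   `percent_overlap` = 100 · |targets ∩ DE| / |targets|;
   `cumulative_abs_fc` = Σ |FC| over DE targets.
5. **Aggregation.** Node values average by pathway group, by miRNA, and by
   a two-class miRNA relevance annotation, over *all* nodes present in the
   exports including zero-valued ones (the small group means printed in the
   original analysis are only reproducible under that convention). Group
   comparisons: one-way ANOVA plus Tukey–Kramer HSD at α = 0.05, with a
   compact-letter display; degenerate (zero-variance) inputs are reported
   as skipped rather than tested.
6. **Export.** Three miRNA × pathway matrices (intersections, percent
   overlap, cumulative |FC|) as TSV, rows blocked by relevance class,
   columns blocked by pathway group, deterministic order.

## Synthetic data: what it emulates and what it does not

The generators stand in for inputs that were never deposited: wound-image
pairs (dark vertical gap of exact known area on a speckled cell lawn,
16-bit, 1000×1000 px at 1.61 µm/px by default), AR samples drawn exactly
from a preset's mixture, expression tables in which exactly `n_de` features
pass the triple filter by construction, and a pathway database whose names
embed group keywords so classifier truth is known, with enrichment p < 0.05
and targets drawn from a supplied gene pool. All randomness flows through
explicit integer seeds (default 42).

Consequently, passing tests establish that the estimators recover known
ground truth under the stated noise models — not that real microscopy or
microarray data satisfy those models. Real wound images have ragged,
non-rectangular fronts; real AR distributions are only approximately
lognormal; real DE tables have correlated p/FDR structure; and the real
pathway-database content (517 pathways across 4 source databases in the
original run) is version-dependent and is not mirrored. The printed
heat-map extremes (50% maximum overlap, 115.98 maximum cumulative |FC|)
depend on that content and are covered by property contracts, not value
reproduction.

## Problem sizes and determinism

Simulated studies use n = 2000 cells per condition for mixture fitting
(matching the scale at which the published elongation percentages carry
±4 pp binomial error), 20 seeds per preset for stability checks, 400×500 px
images in segmentation tests, and expression tables of a few hundred to a
few thousand features. Pipeline runs are byte-reproducible for a fixed
config and seed; per-stage substreams derive from the master seed via
`SeedSequence` so stages stay independent.

## Known limitations

* Faint narrow secondary components (~5% mass) under heavy-tailed primaries
  sit at the detection floor of the selection rule at n = 2000.
* Component recovery for such faint spikes can lock onto a skew correction
  of the primary instead of the spike when the residual-peak start loses
  the least-squares race.
* The keyword classifier is name-based; pathways named unusually will fall
  to Miscellaneous (logged).
* The segmentation assumes one dominant dark gap; multi-wound images would
  need the largest-component rule revisited.
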