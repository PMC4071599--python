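# Methods

This note documents the models and conventions behind each stage of the
pipeline, the defaults for every parameter the underlying protocols leave
open, what the synthetic-data generator does and does not emulate, and the
known limitations.

## Dry-weight basis and salt correction

All composition values are normalized to grams of dry weight (gDW).
Lyophilized sponge tissue retains the sea salt dissolved in the evaporated
water, so the corrected dry mass is

    corrected = lyophilized − k · water_loss,

with `water_loss = wet − lyophilized`. The salt coefficient `k` is
configurable, default **0.035** — the mass of dissolved salt per gram of
seawater (35 g/kg salinity). An alternative reading of "multiply the water
lost by the specific gravity of seawater" would use k = SG − 1 ≈ 0.025;
both are supported via `salt_coefficient`, and neither is asserted as the
historically used value. A record whose implied salt mass meets or exceeds
its lyophilized mass is rejected as implausible rather than clamped.

The displacement-volume conversion factor is the **mean of per-sample
mass/volume ratios** with the sample SD of those ratios, not a regression
through the origin: the reported quantity is the spread of the factor
itself, which the ratio-mean estimator yields directly.

## Assay quantification

Standard curves are ordinary least-squares lines (signal on concentration,
μg/mL). Triplicates are averaged *before* back-calculation — standard
plate-assay practice, and the analysis consumes one value per biopsy.
Readings whose mean signal back-calculates to a negative concentration are
clamped to zero with a warning (not an error), so population summaries
remain computable; out-of-range signals warn. RNA uses A260 with a
configurable conversion (default **40 μg/mL per absorbance unit**); any
digestion/neutralization dilution is carried in the reading's dilution
factor. Sample SD uses the n−1 denominator throughout; CV% = 100·SD/mean,
SE = SD/√n.

## Variance partitioning

Per macro-component, per-biopsy values follow the one-way random-intercept
model y_ij = μ + a_i + e_ij with a_i ~ N(0, σ²_b) per sponge and e_ij ~
N(0, σ²_w). Fitting profiles the likelihood over λ = σ²_b/σ²_w: for fixed
λ, the GLS mean and σ²_w have closed forms, leaving a bounded 1-D search
(coarse log-spaced scan bracketing a Brent refinement, λ ∈ [0, 10⁶], the
boundary λ = 0 always checked). Unbalanced group sizes are supported.
REML is the default for reported variance shares (the convention of the
nlme/lme4 family this analysis follows); ML shares are reported alongside.

The likelihood-ratio test of σ²_b = 0 uses ML fits of both models and
refers 2·(ℓ_full − ℓ_null) to χ²₁. Because the null lies on the boundary
of the parameter space this is conservative; the 50:50 χ²₀:χ²₁ mixture
p-value is computed alongside, and the naive value is the headline one to
match the usual reporting convention. When within-group variability is
exactly zero the within variance is floored at 1e-12 with a warning.

A caveat that matters for interpretation: with only 4 individuals the
*point estimate* of the between-individual share is heavily dispersed
(SD ≈ 24 percentage points at a true share of 54%) and its mean is
Jensen-biased low by roughly 10 points, even though the REML variance
components themselves are unbiased. Recovery tests therefore aggregate
variance components across replicates before forming the share; a single
dataset's share should be read as order-of-magnitude information.

## FAME lipid profiling

Peak tables arrive pre-annotated (compound id, class, area, MW for
identified compounds); deconvolution and identification are upstream.
The processing chain:

1. **Intensity cut-off**: per sample, drop peaks below 0.05% (config
   `fame_rel_cutoff`) of the largest non-internal-standard peak.
2. **Consistency rule**: compounds identified against standards or a
   spectral database are kept unconditionally; unknowns (classified from
   fragmentation patterns) must be present in strictly more than 75% of
   samples.
3. **Backbone subtraction**: FAME signal reflects acyl chains and sterols,
   not glycerol/phosphate backbones, so a backbone mass fraction f_b is
   removed from the gravimetric lipid mass. With lipid classes weighted by
   mole share (glycerolipid:phospholipid **20:80**), each average molecule
   carrying 2 acyl chains of the mean identified FA MW, and backbone
   residues glycerol − 2 H₂O = 56.06 g/mol (glycerolipid) and glycerol +
   H₃PO₄ − 3 H₂O = 136.05 g/mol (phospholipid):
   f_b = Σ share·B / Σ share·(B + 2·M̄_FA) ≈ 0.16–0.18. The residue masses
   and chain count are config constants; the 20:80 ratio is the only part
   of this arithmetic fixed by the protocol, the rest is this package's
   declared convention.
4. **Quantification**: areas are treated as mass-proportional within the
   FA+sterol fraction (the stated equal-response approximation; adopted,
   not tested against chemistry). Per sample,
   abundance_i = (area_i/Σ areas) · lipid·(1−f_b) / MW_i, sums over
   retained peaks only, so retained abundances close exactly on the
   backbone-corrected lipid mass. Unknowns get the mean MW of all
   identified FAs and sterols. MWs are on the **free fatty-acid basis** by
   default (`fame_mw_basis`), since the biomass equation consumes free
   acids; the methyl-ester basis (+14.03 for FAs) is available.
5. **Coverage**: retained area over total pre-filter area (internal
   standard excluded from both), averaged across samples — the share of
   the lipid fraction the reported compounds explain (~82%).

The internal standard (5.1 μg nondecanoic acid) is carried for QC only;
quantification is total-signal-normalized, not ISTD-normalized.

## Amino acids

Acid hydrolysis converts ASN→ASP and GLN→GLU, so measured ASX/GLX pools
are split **50:50** per sample before averaging. Exactly 18 species are
carried: MET and CYS are absent by design (destroyed / not derivatized),
TRP carries a lower-bound flag (partial destruction during hydrolysis).
The cellular profile is whole-biomass minus skeleton, species-wise;
negative differences (possible because the two profiles average different
sample sets) are reported as-is with a flag, and excluded from the
percentage denominator (rendered 0%) when normalizing. Hydrolysis-time
optimization is a wet-lab step recorded as metadata only.

## Nucleotides

Strand symmetry (G = C, A = T for DNA; the same even-ratio assumption for
RNA, A = U) turns one GC fraction into four residue mole fractions.
Defaults: genome GC **0.3114**, transcriptome GC **0.3976**. The mean
residue MW is the abundance-weighted mean; total moles = mass / mean MW.
The default MW table reproduces the reference composition tables verbatim
— including RNA AMP/CMP/GMP entries that match deoxyribonucleotide rather
than standard ribonucleotide residues — because reproducing the reference
output is the primary goal; a standard polymerized-ribonucleotide table is
available via `rna_mw_basis: standard`. GC content is an input scalar; no
sequence files are parsed.

## Biomass equation

Coefficients are mmol/gDW (μmol for nucleotides internally, converted).
Cellular and skeleton (spongin) amino acids are kept as separate classes —
their compositions are distinct — with skeleton species suffixed `_skel`
so species labels stay unique across classes; pooling is available via
`pool_amino_acids`. Carbohydrate enters as anhydroglucose monomer
equivalents (residue MW **162**, configurable), matching the glucose
standard of the assay; no sugar profile is assumed. Unknown FAs/sterols
enter under their placeholder labels with imputed MW, flagged unresolved.
Any skeleton mass not accounted for by spongin amino-acid residues is
carried as a mass-basis `skeleton_inorganic` remainder (silica is never
asserted a value).

`mass_closure` re-multiplies molar coefficients by species MW and adds
mass-basis entries. **Known limitation**: with the reference hydrolysate
profiles the amino-acid residue mass alone (~1.3 g/gDW whole biomass,
~1.1 g/gDW skeleton) exceeds the gravimetric protein + skeleton masses, so
closure exceeds 1 g/gDW — an internal tension of hydrolysate-based
quantification (it recovers extracellular and non-protein amide nitrogen
that gravimetric assays attribute elsewhere). Closure is therefore a
reported diagnostic, never an asserted invariant, and the inorganic
remainder clamps at zero with a warning in this regime.

Equation output (CSV and `a SPECIES + … -> 1 g_biomass` reaction string)
is byte-deterministic: fixed 6-decimal half-even rounding, species sorted
by class then label.

## Synthetic data

The generator emulates the study design: **4 individuals × 5 biopsies**
per component, **23 FAME fractions**, **20 amino-acid samples** per
profile, **97 displacement pairs** (true ratio 0.091, ratio SD 0.012).
Macro-components draw a_i and e_ij Gaussian with total SD and
between-individual share set to the reference population values; values
are truncated at zero by **resampling, not clipping**, to avoid biasing
the small means (DNA, RNA). Assay readings invert the quantification
arithmetic through configured true curves with 3% triplicate CV (1% on
standards). FAME abundances are lognormal (positivity) around the
reference catalogue; areas are mass-proportional with an arbitrary
per-sample gain, plus sub-cutoff junk peaks and inconsistently detected
unknowns carrying ~17.5% of the signal so the filters and the ~82.5%
coverage regime are exercised. Amino-acid tables emit combined ASX/GLX
pools so the splitter runs.

What it does **not** emulate: spatial correlation within a sponge beyond
the individual grouping factor, inter-plate assay drift, non-Gaussian
assay error, compound-specific MS response differences, or any microbial
partitioning of the nucleic acids (all DNA/RNA is treated as sponge
derived). Passing recovery tests therefore demonstrates the pipeline's
arithmetic and the estimators' behavior under the stated model, not
robustness to real-data pathologies outside it.

Determinism: all randomness flows from one integer-seeded numpy
`default_rng`; identical seed and configuration give byte-identical
bundles and pipeline outputs.

## Problem sizes in tests

Recovery tests use 500 replicate 4×5 datasets for the variance-share
check, 1000 replicates for the boundary-size check of the LRT, 200
replicates for generator-moment checks, and single seeded bundles
elsewhere; these sizes give Monte-Carlo standard errors comfortably below
the effects being checked while keeping the suite fast.
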