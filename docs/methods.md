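# Methods

## Quantification model

Each SEC fraction is one TMT 11-plex: nine sample channels (three conditions
L, L+N, L+V × three replicates), one **reference** channel loaded with a
pooled mix of all samples taken *before* SEC, and one **empty** channel.
Channel-to-sample assignment may rotate between fractions; all quantification
resolves channels through the per-fraction plex design, whose invariants
(exactly one reference, one empty, nine samples covering every
condition × replicate pair once) are enforced at construction.

PSM filtering retains spectra with isolation purity **strictly > 0.5**
(the comparison is strict by design), no decoy or contaminant accession
prefix, and positive total reporter signal; spiked iRT standards are routed
to a QC stream.  Quantification is the log2 ratio of each sample channel to
the reference channel.  Because the reference is a pre-SEC pool present
identically in every plex, ratios are comparable across fractions by
construction and **no additional between-fraction renormalization is
applied** — this is an assumption, not a correction.  Aggregation uses the
median at both levels (PSM → peptide, tryptic peptides → protein); the
median is robust to the occasional aberrant charge state and is idempotent
on singletons.  Protein abundance deliberately excludes semi-tryptic
peptides so that cleavage products cannot masquerade as parent-protein
signal.  Peptides matching several accessions are kept under the accession
reported first by the upstream search; no razor-protein re-inference is
attempted.

The iRT control: the standards are labelled in every non-empty channel, so a
fraction fails the assignment check when the empty channel's median iRT
intensity exceeds 10% of the across-channel median or any labelled channel
falls below 10% of it; both ratios are configurable, and a fraction without
iRT records is reported "not evaluable" rather than failed.

## Terminomics conventions

A terminus is tryptic-specific when preceded by K/R or coincident with a
protein terminus.  Two conventions are deliberate choices where practice
varies: (1) a peptide starting at position 2 of a Met-initiated protein is a
native N-terminus (initiator-Met excision), not a cleavage event; (2)
cleavage after K/R counts as specific even before proline, matching the
strict-trypsin digestion rule used by the generator — `cleave_before_pro=False`
switches both the digest and the classifier to the ExPASy behaviour.  The
cleavage position is the P1 residue (immediately N-terminal of the scissile
bond): `start_pos − 1` for semi-N peptides, `end_pos` for semi-C peptides.
Windows are the ten residues P5…P1|P1′…P5′, padded with `-` beyond protein
termini; padded cells are counted separately and never enter motif tallies,
giving the conservation identity *residue counts + padding = n windows* at
every position.

## Moderated differential abundance

Per fraction and contrast (L+N vs L, L+V vs L), each semi-tryptic peptide
with ≥ 2 non-missing replicates per arm is tested with the moderated t:
pooled two-group variance s² on d = n₁+n₂−2 df, empirical-Bayes prior
(s₀², d₀) fitted by the method of moments on log variances — the expectation
identity E[log s²] = log s₀² + ψ(d/2) − log(d/2) − (ψ(d₀/2) − log(d₀/2)) and
the variance identity with trigamma terms, solved with a Newton iteration
for the trigamma inverse.  Posterior variance
s²_post = (d₀s₀² + d·s²)/(d₀+d); t = log2FC / √(s²_post(1/n₁+1/n₂)) on d+d₀
df.  Degenerate regimes are handled explicitly: homogeneous variances give
d₀ = ∞ with s₀² the mean variance (normal reference distribution);
zero-variance features are excluded from the fit and assigned s²_post = s₀²;
fewer than two estimable variances falls back to the ordinary t with a flag.
d₀ = 0 reproduces the ordinary equal-variance t exactly (verified to 1e-8
against scipy, and the full statistic to 1e-6 against an independent R
implementation of the same estimator).

Multiple testing: Benjamini–Hochberg step-up within each fraction × contrast
family — the reporting unit is per-fraction enrichment — with a global
family available behind a flag.  "Significant" requires adj p < 0.05 *and*
log2FC > 0: only enrichment upon treatment counts.  Missing values are never
imputed; under-observed features are reported untested.

## SEC profiles and release calls

Condition profiles average replicate log2 ratios per fraction (mean by
default, median available).  Difference profiles are element-wise
treatment − control with missing propagating.  Percentage distributions
divide each feature's linear intensity per fraction by its fraction-summed
total (×100); log2 matrices are back-transformed as 2^value with missing → 0
first (a raw-intensity mode exists for inputs that are already linear).
All-zero rows are excluded with a warning.

Release classification compares elution peaks (ties go to the earlier
fraction; peaks are invariant under monotone transforms): shift =
peptide peak − protein peak.  **shift ≥ 3 fractions toward later elution
(lower MW) ⇒ released**; |shift| < 3 ⇒ retained; shifts toward earlier
fractions never count as release and are mapped to retained (a product
cannot "release" into a larger assembly — such cases would indicate
re-association and are visible in the reported shift).  Calls are ambiguous
when either profile has < 3 non-zero fractions.  The threshold of 3
fractions is a documented default, validated on the scripted scenarios
(released products planted 11 fractions late are recovered at 100% in the
noise-free limit and ≥ 80% at reporter noise 0.3); the source analyses make
these calls by visual inspection, so no literature value exists to adopt.

Protease profiling subsets the protein percentage matrix to accessions in a
static protease annotation table (accession → family, a stand-in for a
MEROPS-derived list) and orders rows by agglomerative clustering (Euclidean
distance, complete linkage, configurable); rows are pre-sorted by label so
the leaf order is deterministic, and it is verified against a brute-force
greedy merge oracle.

## The synthetic-data generator

The generator is first-class, tested code and defines the study conditions:
21 fractions, TMT-11 with rotated channel assignment, 3 × 3 samples.
Elution is a log2-additive Gaussian bump (default amplitude 6 log2 units,
width σ = 1.5 fractions) over the fraction axis; two-peak behaviour is a
mixture of two Gaussians.  Reporter intensity for sample s in fraction f is
2^(baseline + bump(f) + δ_condition + ε), ε ~ N(0, σ_noise); baselines are
N(10, 1) log2 units.  The reference channel carries the pre-SEC pool,
modelled as the sample- and fraction-averaged linear signal — this keeps
log2 ratios centred near zero while preserving the elution shape (a
per-fraction mean would cancel the SEC profile in every ratio and make the
co-fractionation analysis degenerate).  The empty channel carries
sub-unit uniform noise; iRT spikes have equal expected intensity in all
labelled channels.  Peptides are emitted only in fractions where the bump
exceeds 1.2 log2 units above baseline, emulating a detection floor
(≈ 6–8 observed fractions per peptide at the default width).

Planted cleavage events choose positions where both flanking semi-tryptic
peptides fall in the searchable 7–30-residue range and full P5–P5′ windows
exist; the designated P1 residue (Asp with probability 0.8 by default) is
written into the sequence.  The N-terminal fragment always co-elutes with
its parent; the C-terminal fragment follows the event's behaviour —
*retained* (parent profile) or *released* (own Gaussian at a later target
fraction, in every condition).  Semi peptides sit 2 log2 units below their
parent's baseline and gain δ = 2 log2 units under both treatments by
default.  Scripted scenarios always present: a condition-specific complex
shift (treated peak moves from fraction 16 to 6), a treatment-specific
low-MW accumulation (extra component at fraction 19), a retained Asp-P1
event, and a released event whose parent peaks at fraction 8.  Protease
families are planted at family-specific peaks (ADAM-like at 4, DPP at 5,
proteasome at 10, caspase at 12, MMP14-like at 19) to reproduce the
high-vs-low-MW contrast the protease report should expose.

What the generator does **not** emulate: spectrum-level detail (m/z,
retention time), co-isolation ratio compression beyond the purity flag,
isotope-impurity cross-talk, intensity-dependent missingness, shared
peptides between proteins, or realistic proteome-scale redundancy.  Passing
tests therefore demonstrate the correctness of the computations and the
recoverability of planted structure under the stated noise model — not
performance on real instrument data.  No quantitative noise model for the
motivating dataset is published; σ_noise = 0.3 and the 5% missingness rate
were chosen once as testable, plausible values.

## Numerical and interface choices

Coordinates are 1-based inclusive throughout, with `-` marking protein
termini.  Missing reporter intensities are zeros at PSM level and become
missing only after normalization (log of zero is undefined); a non-positive
reference blanks the whole row.  Matrix TSVs round-trip exactly (index
recorded in an `#index:` header, missing values as empty cells, duplicate
row identifiers refused).  Pipeline outputs carry a provenance header
(config hash, seed, package version) with no timestamps or absolute paths,
so fixed-seed reruns are byte-identical; stages communicate through these
TSVs and are individually re-runnable.  All randomness flows from explicit
seeds through `numpy.random.default_rng`.

## Known limitations

Only two-group contrasts per fraction are supported (no multi-factor
designs, covariates, or intensity-trend variance modelling); there is no
molecular-weight calibration of fractions, no complex-membership
deconvolution beyond peak comparison, no FDR re-estimation of the upstream
search, and no imputation.  The PSM dialect is a minimal, documented subset
of the FragPipe format — files with the required columns parse, extra
columns are ignored.
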