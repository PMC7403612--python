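# Methods

## The procedure

The package curates a mitochondrial proteome from three independent evidence
layers computed over the candidate list (proteins identified in the purified
mitochondrial fraction):

* **Orthology** — membership in at least one of a panel of reference
  mitoproteomes (default four: *A. thaliana*, *M. musculus*,
  *S. cerevisiae*, *T. brucei* naming in the synthetic tables). "At least
  one" is deliberately permissive: reference mitoproteomes are themselves
  incomplete and only weakly overlapping.
* **Enrichment** — Mt/Cp > 1 **and** Mt/WC > 1, where each ratio is the mean
  of the mitochondrial-fraction replicates over the mean of the comparison
  replicates, with no pseudocount. A zero denominator with a positive
  numerator is the explicit INFINITE category rather than a sentinel value;
  a ratio of exactly 1 is *not* enriched. The log₁₀ Mt/Cp confidence bins
  are (0, 1] ("0.0–1.0", i.e. 1–10× more protein in the mitochondrial
  fraction; closed on the right so that exactly 10× falls here) and > 1
  ("> 1.0", more than 10×).
* **Targeting consensus** — strictly more than half of the surveyed
  transcriptome variants (2 of 3) must predict mitochondrial import for an
  ORF that starts with methionine. The denominator is the number of
  *surveyed* transcriptomes, not the number containing the transcript: a
  transcript found in only one variant cannot reach two votes and fails.
  This is the conservative reading; the alternative (denominator = variants
  containing the transcript) would accept single-variant evidence.

A candidate enters the proteome when **any** strategy supports it. The union
rule, rather than a 2-of-3 majority, is the primary rule because the three
layers have very different sensitivities (orthology and enrichment each
capture large, partly disjoint cohorts, targeting consensus a small one);
requiring two of three would discard most single-evidence members. A
strict-majority mode remains available (`strategy_union(..., majority=True)`)
for sensitivity analysis.

Curation then applies two manual-annotation rules, both conjunctions:

* **Removal** — clear non-mitochondrial functional annotation *and* no
  ortholog in any reference mitoproteome. Either condition alone is not
  enough: an annotated "contaminant" with a reference ortholog stays.
* **Reintegration** — a candidate that failed all strategies (in practice:
  failed enrichment) is recalled when the in-silico predicted mitoproteome
  contains it *and* its functional annotation is clearly mitochondrial.

The final proteome is ACCEPTED ∪ REINTEGRATED and the bookkeeping invariant
`final = union − removed + reintegrated` is asserted on every run. Members
whose chloroplast enrichment exceeds their mitochondrial enrichment
(Mt/Cp < 1) but that are retained through orthology or targeting are counted
in the summary, as a check on cross-fraction contamination.

### Protein inference

Peptides are canonicalised by mapping I → L (isobaric residues,
indistinguishable by standard MS; the direction is arbitrary but fixed) and
dropping peptides shorter than six residues. Grouping follows peptide-set
subsumption *through the leading protein*: every protein joins the protein
owning the largest superset of its peptide set (ties broken
lexicographically by identifier). This means B ⊆ A and C ⊆ A yields one
group {A, B, C} even when B and C are incomparable; two proteins with
identical sets are co-members with the lexicographically smaller one
leading. The implementation is a greedy pass over proteins in decreasing
set-size order with an inverted peptide index; tests check it against a
brute-force all-pairs subset oracle.

Unique peptides map only to members of a single group; peptides shared
across groups (razor) are excluded both from unique counts and from
quantification. No further razor accounting (e.g. assignment to the largest
group) is attempted.

The target-decoy threshold is the score cutoff admitting the most targets
subject to `#decoys ≥ cutoff / #targets ≥ cutoff ≤ α`; a lower cutoff that
adds only decoys is never preferred, so in the perfect-separation limit all
targets and zero decoys are accepted. The estimator is plain
`decoys/targets` (not `(decoys+1)/targets`), matching the convention of
counting reversed-database hits; on simulated scores it is conservative
whenever incorrect targets are rarer than decoys.

### Quantification

Group intensity per sample is the **sum** of unique-peptide intensities.
This replaces pairwise-ratio LFQ reconstruction (out of scope here) with the
simplest aggregate that preserves between-fraction ratios under the
multiplicative noise model; missing observations contribute zero. Whether
ratios should be computed on summed replicates or per replicate then
averaged is genuinely open; mean-of-replicates is used and exposed in
`enrichment_ratios`. P-values use Welch's unequal-variance t-test on log₁₀
intensities (the equal-variance assumption has no justification across
fractions); degenerate inputs are defined explicitly — identical
zero-variance sides give p = 1, separated zero-variance sides give the
smallest representable positive double, fewer than two replicates per side
gives an undefined p (None). Molecular weights use average (not
monoisotopic) residue masses plus one water, via pyteomics, reported in kDa.

## The synthetic experiment

`SimulationConfig` defaults *are* the simulated study conditions; they are
chosen once to emulate the fractionation design and are not tuned per test.

| parameter | default | why |
|---|---|---|
| `n_proteins` | 2000 | candidate-list scale of a purified-fraction experiment |
| `localization_proportions` | mito .55 / chloroplast .25 / cytosol .15 / dual .05 | a mitochondrial-fraction candidate list is mito-dominated (~2/3 true members), with chloroplast the main co-purifying compartment |
| `enrichment_fold` | 8 | order-of-magnitude organellar enrichment typical of gradient fractionation; the true fold in real data is unknown, this is a placeholder, not an estimate |
| `intensity_log_sd` | 0.2 (log₁₀) | ~1.6× multiplicative replicate scatter, typical label-free reproducibility; 0 is the exact zero-noise limit |
| `n_replicates_per_fraction` | 3 | standard design |
| `detectability` | 0.6 | fraction of tryptic peptides ever observed (flyability) |
| `missing_rate` | 0.1 | per-observation dropout |
| `truncation_prob` | 0.85 | per-variant probability that a transcript's 5' end (start Met + targeting signal) is lost; chosen so that ~40% of true members show a signal in ≥ 1 of 3 variants and only a few percent reach the 2-of-3 consensus, as observed in real transcriptome assemblies of this quality |
| `reference_coverage` | 0.2 | per-reference ortholog probability for a true member; gives ~59% coverage by ≥ 1 of 4 references, matching how sparsely divergent protists map onto model-organism mitoproteomes |
| `contaminant_rate` / `contaminant_leak` | 0.05 / 0.1 | 5% of non-mito proteins are recognisable contaminants leaking into the mito fraction at 0.1 × `enrichment_fold` (= 0.8× base), just below the enrichment boundary so they occasionally cross it under noise and exercise curation removal |
| `annotated_fraction` | 0.44 | share of proteins with assignable function; the rest are "unknown", the dominant class in protist proteomes |
| `predicted_coverage` | 0.6 | share of true members present in the in-silico predicted mitoproteome |

**Intensity model.** Every protein is present in every fraction at its base
abundance (log₁₀-normal across proteins, sd 0.5 around 10⁶); residents of an
organellar fraction are boosted by `enrichment_fold` there (dual-localized
proteins in both); the whole-cell fraction is the mixture
`Σ_c w_c · effect(protein, c)` with weights equal to the localization
proportions. Observed peptide intensity multiplies this expectation by
`10^ε`, ε ~ N(0, `intensity_log_sd`), independently per (peptide, fraction,
replicate). Consequences worth knowing:

* at zero noise, Mt/Cp of a mitochondrial protein equals the configured fold
  exactly, and a cytosolic protein's ratios equal exactly 1 — hence the
  exact zero-noise recovery property;
* under noise, a cytosolic protein exceeds both ratios with probability
  ≈ 1/3 (its three fraction means are exchangeable), so the enrichment
  strategy alone has a hard false-positive floor; overall precision depends
  on the cytosolic share of the candidate list. This mirrors the real
  situation in which enrichment calls on near-1 ratios are unreliable and
  curation matters;
* dual-localized proteins have Mt/Cp = 1 and are *never* called enriched —
  they are recovered through orthology/targeting, again as in real
  curation.

**What the generator does not emulate:** spectra (no m/z, retention time or
fragment evidence — intensities are abstract), between-run normalisation
drift, shared-peptide homology structure (random sequences share almost no
tryptic peptides, so protein groups are mostly singletons; grouping is
stress-tested separately on dense random instances), correlated missingness
(dropout is independent of abundance), and annotation errors (truth flags
are noiseless). Passing tests therefore validate the *procedure*, not the
biology of any particular data set.

**Decoy scores.** `simulate_decoy_scores` draws correct targets from
N(separation, 1) and both incorrect targets (a `false_target_fraction` =
0.1 share of the target list) and decoys from N(0, 1). The incorrect-target
share is what makes realized false-discovery proportions non-trivial: with
equal target/decoy list sizes and fewer incorrect targets than decoys, the
decoy estimate over-counts false positives, so the realized FDP at the 0.01
level sits well below 0.01.

## Numerical and formatting choices

* Tryptic digestion cleaves C-terminal to K/R except before P, no missed
  cleavages by default (0–2 supported); written by hand because ordered
  peptides and the concatenation property are needed, and checked against a
  regex-based cleaver in tests.
* Largest-remainder apportionment converts localization proportions into
  exact class counts (within one of the real-valued target).
* All randomness derives from numpy `default_rng([stream, seed])` with a
  distinct stream id per generator, so the generators are independently
  reproducible and adding one does not perturb the others.
* Percent figures round half away from zero to integer percent.
* Category-level enrichment uses the geometric mean of finite Mt/Cp ratios
  (ratios are multiplicative); members with no chloroplast signal are
  tallied as "infinite", not averaged. Log₁₀ bins are (0,1], (1,2], > 2 and
  "infinite"; synthetic categories can also fall at ≤ 0, an extra bin real
  enriched-category figures do not need.
* TSV throughout (UTF-8, header row); FASTA via Biopython; summaries as
  JSON with sorted keys so reruns are byte-identical.

## Problem sizes used by tests and the acceptance script

Grouping-oracle equivalence runs 200 random instances of ≤ 20 proteins and
≤ 50 peptides; FDR calibration runs 20 simulations of 10,000 targets +
10,000 decoys at 3-sd separation; end-to-end recovery runs the default
2,000-protein configuration; the consensus closed form uses 2,000
signal-bearing proteins. These sizes keep the full run in tens of seconds
while leaving Monte-Carlo error far below the tested tolerances.

## Known limitations

* The union rule's precision is bounded by the enrichment layer's ~1/3
  false-positive rate on ratio-near-1 proteins; with a candidate list
  dominated by non-organellar proteins, precision would degrade and the
  majority mode or a p-value gate on the volcano statistics would be
  preferable.
* Razor-peptide intensity is discarded entirely; proteins quantifiable only
  through shared peptides are flagged unquantifiable rather than estimated.
* The FDR estimator is the plain decoys/targets ratio; it is slightly
  anti-conservative relative to (decoys+1)/targets at very small acceptance
  sets.
* Reintegration requires the annotation flags as *inputs*; the package does
  not replicate manual annotation or database lookups.
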