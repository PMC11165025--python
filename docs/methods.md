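# Methods

## Model and inference

All inference is carrier-based: a sample carries a feature (allele, residue,
or coding variant) if at least one of its two chromosomes bears it, so every
comparison reduces to a 2×2 table of carrier counts. Conditioning on both
margins leaves a single free cell `A` (case carriers) with the noncentral
hypergeometric law

    P_ψ(A = x) ∝ C(K, x) · C(N−K, n₁−x) · ψˣ,

over the feasible support, where `n₁` is the number of cases, `K` the total
number of carriers, `N` the grand total and ψ the odds ratio. At ψ = 1 this
is the central hypergeometric distribution.

**Two-sided p-value.** The point-probability rule: the sum of central point
probabilities of all tables with the observed margins whose probability does
not exceed the observed table's. A relative slack of 1 + 10⁻⁷ absorbs
floating-point ties in the comparison (the same device R's `fisher.test`
uses); exact-rational enumeration in the test suite confirms the float path
to ~10⁻⁹ relative error on hundreds of random tables.

**Odds ratio.** For tables with all cells positive, the conditional MLE: the
ψ solving `E_ψ[A] = a`. `E_ψ[A]` is strictly increasing in ψ, so the root is
found by bracketed Brent on log ψ (initial bracket `[10⁻⁸, 10⁸]`, expanded on
demand; `xtol = 10⁻¹⁰`). When `a` sits on the support boundary the
conditional likelihood is maximised at 0 or ∞ and that boundary value is
returned explicitly. With a zero cell, the reported estimate is instead the
continuity-corrected cross-product `(a·d)/(b·c)` after adding 0.5. Two
correction modes exist: `zero_cells_only` (the default) adds 0.5 only to
zero cells; `all_cells` adds it everywhere (Haldane–Anscombe). The default
was chosen because it reproduces the reference results this package is
validated against; the mode is always recorded in the output.

**Confidence interval.** Exact test inversion on the conditional tails: the
lower bound solves `P_ψ(A ≥ a) = α/2`, the upper `P_ψ(A ≤ a) = α/2`, by the
same log-scale Brent solve; boundary counts give 0 / ∞ ends. Endpoints
reproduce their nominal tail probabilities to better than 10⁻⁶ (asserted in
tests). For zero-cell tables the CI is still the inversion interval of the
*uncorrected* table; it is therefore not a CI for the corrected
cross-product estimate, merely the exact interval for ψ.

*Numerical note.* Some reference software computes the same inversion with a
coarse root-search stopping tolerance (~10⁻⁴ on 1/ψ), which can shift a very
large upper bound by around 1% — e.g. 1275.67 where the accurate solve gives
1287.43 for the table (3, 1; 11, 89). This package always solves to ≤10⁻⁸
relative tolerance; the defining tail property, not a legacy rounding, is
the contract.

All probability arithmetic is done in log space (`gammaln` weights,
`logsumexp` normalisation), so margins in the thousands are handled without
overflow.

## Residue fine-mapping

Alleles are expanded to aligned mature-protein sequences (1-based positions
counted from the first residue after signal-peptide cleavage). This frame is
forced by the codon arithmetic: residue *i* must span CDS bases
`3(i−1)+1 … 3i` for the residue↔variant pairs the analysis reports (e.g.
position 140 ↔ base 419). Carrier status is diplotype-level, mirroring the
allele definition; dosage is out of scope. Gaps never match a residue
feature. The per-position χ² builds the R×2 matrix of residue-carrier counts
(a heterozygote for two residues contributes to two rows) and applies
Pearson's statistic without continuity correction, df = R−1.

The residue screen tests every (position, residue) pair observed in cases at
positions polymorphic within the cohort, reports raw p-values by default
(matching small-case-series practice), and offers Bonferroni or
Benjamini–Hochberg annotation behind a flag.

## Variant mapping

`distinguishing_variant` reduces a risk residue to the **minimal** run of
one or two consecutive bases inside its own codon at which all risk alleles
share bases that differ, as a tuple, from every other allele. Runs of width
1 are tried before width 2, leftmost first; a single-letter label like
`C419` therefore means one base suffices, while `CT559-560` means no single
position separates the sets but the pair does. Variants outside the
residue's codon (pure linkage) are deliberately not searched; the mapping is
codon-local by design, and a residue without a codon-local separator raises
an explicit error rather than returning a proxy.

## Synthetic cohorts

The free generator draws diploid genotypes under Hardy–Weinberg from a
configurable allele-frequency pool (remainder mass pooled into a neutral
background allele) and assigns case status by a logistic model on risk
carrier status: non-carrier odds `p₀/(1−p₀)`, carrier odds multiplied by the
target odds ratio ψ₀. Groups are filled by batched rejection sampling with a
hard iteration cap; one seeded `numpy` generator drives each run and
replicate studies derive child seeds from a `SeedSequence`.

Defaults are the emulated study design: 4 cases, 100 tolerant controls,
1000 population controls, B\*15:01 allele frequency `1−√(1−0.107)` (so the
carrier frequency is 10.7%), carrier target OR 22.9, baseline case
probability 10⁻³ (SCAR is rare). What the generator does **not** emulate:
linkage disequilibrium between HLA alleles, population stratification,
phenotype misclassification, and typing error. Calibration results obtained
on it (type-I error, coverage, recovery) therefore speak to the inference
engine under the stated sampling model, not to robustness against those
real-data features.

The **study fixture** is a separate, fully deterministic object: the four
case genotypes, 100 tolerant controls whose carrier margins are fixed
exactly (11× B\*15:01, 10× B\*13:01, 2× B\*35:05, 4× B\*37:01, 2× B\*39:01,
11× B\*51:01, plus control-only alleles B\*40:01/B\*46:01/B\*58:01 sized so
the residue-carrier margins come out at 24, 27 and 28), and matching
sequence tables. Only marginal counts are reported in the source material;
the fixture places risk alleles on distinct control samples, which is the
simplest completion and irrelevant to every 2×2 result (they depend on
margins only). The alignment and CDS are **synthetic**: a fixed
pseudo-random background over the 338-residue mature protein with the nine
analytically relevant positions pinned to specific residues and codons
(chosen so each printed residue↔variant pair emerges from the
codon-arithmetic search, e.g. W180 = TGG vs L180 = CTG forces `T538`;
L187 = CTG against a P/V mixture forces `CT559-560`), plus one private
substitution per allele so all sequences are distinct. They are stand-ins
for IMGT/HLA data, not copies of it; a loader accepts user-supplied aligned
FASTA or TSV for real alignments.

## Pipeline and determinism

`run_full_analysis` chains the allele screen, the residue screen, the
residue→variant mapping for significant residues, and the predictor table,
writing TSVs at full float precision alongside a display rendering (p to
three significant figures, scientific below 10⁻³; OR to one decimal ≥ 10,
two below). Re-running with identical inputs is byte-identical; a JSON
manifest records tool version, seed and configuration. A degenerate feature
(carried by everyone or no one) is reported as p = 1 with a (0, ∞) interval
instead of failing the screen.

## Problem sizes used in validation

The packaged experiments run at the scales the design dictates: desk-scale
exact results on the 104-sample fixture; oracle equivalence on 500 random
tables with margins ≤ 30 (exact rational enumeration) and 100 positive
tables (grid likelihood maximisation); type-I error over 2000 null cohorts
of 4 cases / 100 controls; recovery and coverage over 500 replicates of 200
cases / 5000 controls at ψ₀ = 20. The whole suite completes in well under a
minute on one CPU.

## Known limitations

* Exact conditional inference is conservative at these sample sizes; the
  type-I error check asserts conservatism, not exactness of level.
* The cross-product/CML discrepancy for zero-cell tables means the reported
  OR and its CI come from different constructions there (documented above).
* The residue screen treats residues marginally; no haplotype phasing, no
  peptide-binding or structural modelling.
* The variant mapping is codon-local only and assumes the supplied CDS table
  uses the same mature-protein frame as the alignment.
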