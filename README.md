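# hlassoc

Carrier-based HLA association analysis for small pharmacogenetic case
series: exact conditional inference on 2×2 carrier tables, amino-acid-level
fine-mapping of HLA alleles, residue-to-coding-variant mapping, and
evaluation of carrier-defined genetic predictors — together with a synthetic
diploid-cohort simulator for calibration studies.

## The problem

Severe cutaneous adverse reactions (SCAR: SJS/TEN, DRESS, acute
erythroderma) to a drug are rare but life-threatening, and for several drugs
the risk concentrates in carriers of specific HLA class I alleles
(abacavir/B\*57:01, carbamazepine/B\*15:02, allopurinol/B\*58:01). A typical
discovery setting is tiny: a handful of cases, a drug-tolerant control
group, and a population reference. At that scale the only defensible
inference is exact: condition on both margins of the carrier table and work
with the noncentral hypergeometric law of the case-carrier count.

For a 2×2 carrier table with `a` case carriers, `b` case non-carriers, `c`
control carriers and `d` control non-carriers, the count `A = a` given both
margins follows

    P_ψ(A = x) ∝ C(K, x) · C(N−K, n₁−x) · ψˣ

with `n₁ = a+b`, `K = a+c`, `N = a+b+c+d`, and ψ the odds ratio. `hlassoc`
computes:

* **p** — the two-sided Fisher exact p-value (point-probability rule: sum of
  all tables no more probable than the observed one at ψ = 1);
* **OR** — the conditional maximum-likelihood estimate, the ψ solving
  `E_ψ[A] = a` (the estimator R's `fisher.test` reports), with Haldane-style
  0.5-corrected cross-products when a cell is zero;
* **95% CI** — exact test inversion: the lower bound solves
  `P_ψ(A ≥ a) = α/2`, the upper `P_ψ(A ≤ a) = α/2`;
* residue-level versions of all of the above after expanding each allele to
  its aligned mature-protein sequence, plus an R×2 Pearson χ² per aligned
  position;
* the minimal codon-local coding variant distinguishing the risk alleles
  (codon *i* spans CDS bases `3(i−1)+1 … 3i`), and the sensitivity /
  specificity of any allele, residue or variant used as a carrier-defined
  screening predictor.

## Worked example

The package ships a deterministic study fixture: four SCAR cases genotyped
at HLA-B (`13:01/15:01`, `15:01/51:01`, `15:01/37:01`, `39:01/35:05`) and
100 amoxicillin-tolerant controls with fixed carrier margins, plus a
matching protein alignment and per-allele CDS table.

```python
from hlassoc import study_fixture, associate_allele, residue_fisher, parse_allele
from hlassoc.residues import ResidueFeature

cohort, alignment, cds = study_fixture()

r = associate_allele(cohort, parse_allele("B*15:01"))
print(r.table.as_tuple(), f"p={r.p_two_sided:.3g}", f"OR={r.or_estimate:.3g}",
      f"CI=({r.ci_low:.3g}, {r.ci_high:.6g})")
# (3, 1, 11, 89) p=0.00734 OR=22.9 CI=(1.68, 1287.43)

s = residue_fisher(cohort, alignment, ResidueFeature.parse("S140"))
print(s.table.as_tuple(), f"p={s.p_two_sided:.3g}", f"OR={s.or_estimate:.3g}")
# (4, 0, 13, 87) p=0.000518 OR=53.5
```

Three of four cases carry B\*15:01 against 11% of tolerant controls
(p = 7.34×10⁻³, conditional-MLE OR 22.9); serine at mature-protein position
140 — shared by B\*15:01 and B\*35:05, hence present in **all four** cases —
is stronger still (p = 5.18×10⁻⁴, zero-cell-corrected OR 53.5). Its
codon-local coding variant C419 screens cases with 100% sensitivity and 87%
specificity:

```bash
hlassoc fixture --out fx
hlassoc predict fx/cohort.tsv --features "B*15:01,C419,T538" \
        --alignment fx/alignment.fasta --cds fx/cds.fasta
# C419     4  0  13  87  100  87  0.000517602  53.5385
# B*15:01  3  1  11  89   75  89  0.00734234   22.8584
# T538     3  1  11  89   75  89  0.00734234   22.8584
```

The CLI also exposes `cohort validate|summarize`, `assoc alleles`,
`assoc residues`, `simulate` (Hardy–Weinberg cohorts with a configurable
carrier odds ratio) and `run` (full pipeline: allele screen → residue screen
→ predictor table, written as TSV plus a JSON run manifest).

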