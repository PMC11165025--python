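"""Amino-acid-level fine-mapping of HLA carrier associations.

Allele calls are expanded to aligned mature-protein residues, and the same
carrier logic used for alleles is applied to (position, residue) features: a
sample carries residue R at position p if at least one of its two alleles has
R at p in the alignment. Positions are 1-based in mature-protein numbering
(counted from the first residue after signal-peptide cleavage), which keeps
the residue/codon correspondence used downstream exact.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import chi2_contingency

from .exact2x2 import AssociationResult, result_from_table, _rank_key
from .genotypes import Cohort, ContingencyTable2x2, HlassocError, _table_from_status

__all__ = [
    "AlignmentTable",
    "ResidueFeature",
    "read_alignment",
    "polymorphic_positions",
    "residue_carrier_status",
    "residue_carriers",
    "residue_fisher",
    "position_chisq",
    "screen_residues",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")


class AlignmentError(HlassocError, ValueError):
    pass


@dataclass(frozen=True)
class ResidueFeature:
    """One amino acid at one aligned mature-protein position, e.g. S140."""

    position: int
    residue: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position {self.position} must be >= 1")
        if self.residue not in AMINO_ACIDS:
            raise ValueError(f"residue {self.residue!r} is not a standard amino acid")

    @property
    def label(self) -> str:
        return f"{self.residue}{self.position}"

    @classmethod
    def parse(cls, label: str) -> "ResidueFeature":
        m = re.fullmatch(r"([A-Z])(\d+)", label.strip())
        if not m:
            raise ValueError(f"cannot parse residue feature {label!r}")
        return cls(int(m.group(2)), m.group(1))

    def __str__(self) -> str:  # pragma: no cover
        return self.label


@dataclass
class AlignmentTable:
    """Allele label -> aligned mature-protein residue string.

    All strings share one coordinate frame (equal length); position 1 is the
    first mature-protein residue. Gap characters never match any residue
    feature, so an allele with a gap at a queried position is a non-carrier.
    """

    entries: dict[str, str]
    locus: str = "B"
    gap: str = "-"

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.entries.values()}
        if len(lengths) > 1:
            raise AlignmentError(
                f"aligned sequences have ragged lengths {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        return len(next(iter(self.entries.values()))) if self.entries else 0

    def __contains__(self, allele_label: str) -> bool:
        return allele_label in self.entries

    def residue_at(self, allele_label: str, position: int) -> str:
        if allele_label not in self.entries:
            raise AlignmentError(f"allele {allele_label!r} not in alignment")
        if not 1 <= position <= self.length:
            raise AlignmentError(
                f"position {position} outside alignment (1..{self.length})"
            )
        return self.entries[allele_label][position - 1]

    def missing_from(self, allele_labels: Iterable[str]) -> list[str]:
        return sorted(set(allele_labels) - set(self.entries))


def read_alignment(path: str | Path, locus: str = "B") -> AlignmentTable:
    """Load an alignment from aligned FASTA (record id = allele label) or a
    two-column TSV (``allele``, ``sequence``)."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        from Bio import SeqIO

        entries = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
        }
    else:
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"allele", "sequence"} <= set(df.columns):
            raise AlignmentError(
                f"{path}: TSV alignment needs columns 'allele' and 'sequence'"
            )
        entries = dict(zip(df["allele"], df["sequence"].str.upper()))
    if not entries:
        raise AlignmentError(f"{path}: no sequences found")
    return AlignmentTable(entries, locus=locus)


def _check_cohort_covered(cohort: Cohort, alignment: AlignmentTable) -> None:
    labels = {a.label for s in cohort.samples for a in s.alleles}
    missing = alignment.missing_from(labels)
    if missing:
        raise AlignmentError(
            f"cohort alleles missing from alignment: {', '.join(missing)}"
        )


def polymorphic_positions(
    alignment: AlignmentTable, alleles: Iterable[str] | None = None
) -> list[int]:
    """Positions with >= 2 distinct non-gap residues among ``alleles``."""
    labels = list(alleles) if alleles is not None else sorted(alignment.entries)
    unknown = alignment.missing_from(labels)
    if unknown:
        raise AlignmentError(f"unknown allele(s): {', '.join(unknown)}")
    out = []
    for pos in range(1, alignment.length + 1):
        residues = {
            alignment.entries[l][pos - 1]
            for l in labels
            if alignment.entries[l][pos - 1] != alignment.gap
        }
        if len(residues) >= 2:
            out.append(pos)
    return out


def residue_carrier_status(
    cohort: Cohort, alignment: AlignmentTable, feature: ResidueFeature
) -> dict[str, bool]:
    """True iff either allele of the sample bears ``feature.residue`` at
    ``feature.position``; gaps never match."""
    _check_cohort_covered(cohort, alignment)
    return {
        s.sample_id: any(
            alignment.residue_at(a.label, feature.position) == feature.residue
            for a in s.alleles
        )
        for s in cohort.samples
    }


def residue_carriers(
    cohort: Cohort,
    alignment: AlignmentTable,
    feature: ResidueFeature,
    case_group: str = "case",
    control_group: str = "tolerant_control",
) -> ContingencyTable2x2:
    """Carrier 2x2 table for a residue feature."""
    status = residue_carrier_status(cohort, alignment, feature)
    return _table_from_status(cohort, status, case_group, control_group)


def residue_fisher(
    cohort: Cohort,
    alignment: AlignmentTable,
    feature: ResidueFeature,
    case_group: str = "case",
    control_group: str = "tolerant_control",
    alpha: float = 0.05,
    correction_mode: str = "zero_cells_only",
) -> AssociationResult:
    """Exact carrier association of one residue feature."""
    table = residue_carriers(cohort, alignment, feature, case_group, control_group)
    return result_from_table(feature.label, table, alpha, correction_mode)


def position_chisq(
    cohort: Cohort,
    alignment: AlignmentTable,
    position: int,
    case_group: str = "case",
    control_group: str = "tolerant_control",
) -> tuple[float, int, float]:
    """Pearson chi-square over all residues at one aligned position.

    Builds the R x 2 matrix of residue-carrier counts (rows: distinct
    residues observed at the position, columns: case / control group) and
    returns (statistic, dof, p). No continuity correction; dof = R - 1.
    Because carrier counts are diplotype-level, a sample heterozygous for two
    residues contributes to two rows.
    """
    _check_cohort_covered(cohort, alignment)
    residues = sorted(
        {
            alignment.residue_at(a.label, position)
            for s in cohort.samples
            if s.group in (case_group, control_group)
            for a in s.alleles
        }
        - {alignment.gap}
    )
    if len(residues) < 2:
        raise AlignmentError(
            f"position {position} is monomorphic in the cohort; the "
            "chi-square contrast is undefined"
        )
    counts = []
    for res in residues:
        feat = ResidueFeature(position, res)
        t = residue_carriers(cohort, alignment, feat, case_group, control_group)
        counts.append([t.a, t.c])
    stat, p, dof, _ = chi2_contingency(counts, correction=False)
    return float(stat), int(dof), float(p)


def screen_residues(
    cohort: Cohort,
    alignment: AlignmentTable,
    case_group: str = "case",
    control_group: str = "tolerant_control",
    alpha: float = 0.05,
    correction_mode: str = "zero_cells_only",
    adjust: str | None = None,
) -> list[AssociationResult]:
    """Exact association of every case-observed residue at polymorphic
    positions, most significant first."""
    _check_cohort_covered(cohort, alignment)
    cases = cohort.group(case_group)
    if not cases:
        raise HlassocError(f"group {case_group!r} is empty")
    cohort_labels = sorted({a.label for s in cohort.samples for a in s.alleles})
    positions = polymorphic_positions(alignment, cohort_labels)
    features = []
    for pos in positions:
        case_residues = sorted(
            {
                alignment.residue_at(a.label, pos)
                for s in cases
                for a in s.alleles
            }
            - {alignment.gap}
        )
        features.extend(ResidueFeature(pos, r) for r in case_residues)
    results = [
        residue_fisher(
            cohort, alignment, f, case_group, control_group, alpha, correction_mode
        )
        for f in features
    ]
    results.sort(key=_rank_key)
    if adjust:
        from .exact2x2 import adjust_results

        results = adjust_results(results, adjust)
    return results


def count_significant(results: Iterable[AssociationResult], alpha: float = 0.05) -> int:
    """Number of screen results with (raw) p below ``alpha``."""
    return sum(r.p_two_sided < alpha for r in results)
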