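"""Residue-to-coding-variant mapping and pharmacogenetic predictor metrics.

CDS coordinates are mature-protein-relative and 1-based: codon i of the
mature protein spans CDS positions 3*(i-1)+1 .. 3*i, so every CDS position
maps back to exactly one residue via ceil(pos/3). A risk residue is reduced
to the minimal run of one or two consecutive bases inside its own codon that
separates the risk alleles from all others; that variant then defines a
carrier-based predictor whose sensitivity and specificity are evaluated on a
cohort.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Union

from .exact2x2 import AssociationResult, result_from_table
from .genotypes import (
    AlleleCall,
    Cohort,
    ContingencyTable2x2,
    HlassocError,
    carrier_status,
    _table_from_status,
)
from .residues import AlignmentTable, ResidueFeature, residue_carrier_status

__all__ = [
    "CdsVariant",
    "PredictorMetrics",
    "residue_to_codon",
    "codon_of_cds_position",
    "read_cds",
    "distinguishing_variant",
    "predictor_metrics",
    "rank_predictors",
]

Feature = Union[AlleleCall, ResidueFeature, "CdsVariant"]

_BASES = set("ACGT")


class NotCodonLocalError(HlassocError, ValueError):
    """No 1-2 base run inside the codon separates risk from other alleles."""


class AmbiguousVariantError(HlassocError, ValueError):
    """Risk alleles do not agree on any candidate base run in the codon."""


@dataclass(frozen=True)
class CdsVariant:
    """One or two consecutive CDS bases defining a carrier feature.

    ``label`` is bases + start position, e.g. ``"C419"`` or ``"CT559-560"``.
    An optional dbSNP id travels as an annotation string and is never
    resolved externally.
    """

    positions: tuple[int, ...]
    bases: str
    rsid: str | None = None

    def __post_init__(self) -> None:
        if len(self.positions) not in (1, 2):
            raise ValueError("a CDS variant spans one or two positions")
        if len(self.positions) == 2 and self.positions[1] != self.positions[0] + 1:
            raise ValueError(f"positions {self.positions} are not consecutive")
        if len(self.bases) != len(self.positions):
            raise ValueError("one base per position required")
        if not set(self.bases) <= _BASES:
            raise ValueError(f"bases {self.bases!r} outside ACGT")
        if self.positions[0] < 1:
            raise ValueError("CDS positions are 1-based")

    @property
    def label(self) -> str:
        if len(self.positions) == 1:
            return f"{self.bases}{self.positions[0]}"
        return f"{self.bases}{self.positions[0]}-{self.positions[1]}"

    @classmethod
    def parse(cls, label: str) -> "CdsVariant":
        m = re.fullmatch(r"([ACGT]+)(\d+)(?:-(\d+))?", label.strip())
        if not m:
            raise ValueError(f"cannot parse CDS variant {label!r}")
        bases, start = m.group(1), int(m.group(2))
        if m.group(3) is None:
            positions: tuple[int, ...] = (start,)
        else:
            positions = tuple(range(start, int(m.group(3)) + 1))
        return cls(positions, bases)

    def __str__(self) -> str:  # pragma: no cover
        return self.label


def residue_to_codon(position: int) -> tuple[int, int]:
    """CDS span (start, end) of mature-protein residue ``position``."""
    if position < 1:
        raise ValueError(f"residue position {position} must be >= 1")
    return 3 * (position - 1) + 1, 3 * position


def codon_of_cds_position(pos: int) -> int:
    """Residue index whose codon contains CDS position ``pos``."""
    if pos < 1:
        raise ValueError(f"CDS position {pos} must be >= 1")
    return math.ceil(pos / 3)


def read_cds(path: str | Path) -> dict[str, str]:
    """Per-allele mature CDS sequences from FASTA (record id = allele label)."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def distinguishing_variant(
    cds_table: Mapping[str, str],
    feature: ResidueFeature,
    risk_alleles: Iterable[str],
    other_alleles: Iterable[str],
) -> CdsVariant:
    """Minimal codon-local base run separating risk alleles from the rest.

    Scans runs of one, then two consecutive positions within the residue's
    codon, leftmost first, and returns the first run at which every risk
    allele shares the same bases and that shared run differs from every other
    allele's bases over the same span.
    """
    risk = sorted(set(risk_alleles))
    other = sorted(set(other_alleles))
    if not risk or not other:
        raise ValueError("risk and other allele sets must be non-empty")
    start, end = residue_to_codon(feature.position)
    for label in risk + other:
        if label not in cds_table:
            raise HlassocError(f"allele {label!r} missing from CDS table")
        if len(cds_table[label]) < end:
            raise HlassocError(
                f"CDS of {label!r} is shorter than codon span {start}-{end}"
            )

    def span_bases(label: str, s: int, width: int) -> str:
        return cds_table[label][s - 1 : s - 1 + width]

    any_consistent = False
    for width in (1, 2):
        for s in range(start, end - width + 2):
            risk_bases = {span_bases(l, s, width) for l in risk}
            if len(risk_bases) != 1:
                continue
            any_consistent = True
            shared = next(iter(risk_bases))
            if all(span_bases(l, s, width) != shared for l in other):
                positions = tuple(range(s, s + width))
                return CdsVariant(positions, shared)
    if not any_consistent:
        raise AmbiguousVariantError(
            f"risk alleles disagree at every base run of codon "
            f"{feature.position}; no consistent variant exists"
        )
    raise NotCodonLocalError(
        f"no 1-2 base run inside codon {feature.position} separates the risk "
        "alleles from all others"
    )


def cds_variant_status(
    cohort: Cohort, cds_table: Mapping[str, str], variant: CdsVariant
) -> dict[str, bool]:
    """Per-sample carrier status of a CDS variant (either allele matches)."""
    labels = {a.label for s in cohort.samples for a in s.alleles}
    missing = sorted(labels - set(cds_table))
    if missing:
        raise HlassocError(
            f"cohort alleles missing from CDS table: {', '.join(missing)}"
        )
    s0 = variant.positions[0]
    width = len(variant.positions)

    def hit(label: str) -> bool:
        seq = cds_table[label]
        if len(seq) < variant.positions[-1]:
            raise HlassocError(
                f"CDS of {label!r} does not cover position {variant.positions[-1]}"
            )
        return seq[s0 - 1 : s0 - 1 + width] == variant.bases

    return {
        s.sample_id: any(hit(a.label) for a in s.alleles) for s in cohort.samples
    }


@dataclass(frozen=True)
class PredictorMetrics:
    """Confusion counts of a carrier-defined predictor on a case/control split.

    tp: case carriers, fn: case non-carriers, fp: control carriers,
    tn: control non-carriers.
    """

    feature: str
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)

    @property
    def sensitivity_pct(self) -> int:
        """Display value: percentage rounded to the nearest integer."""
        return round(100 * self.sensitivity)

    @property
    def specificity_pct(self) -> int:
        return round(100 * self.specificity)

    @property
    def table(self) -> ContingencyTable2x2:
        return ContingencyTable2x2(self.tp, self.fn, self.fp, self.tn)


def _feature_status(
    cohort: Cohort,
    feature: Feature,
    alignment: AlignmentTable | None,
    cds_table: Mapping[str, str] | None,
) -> tuple[str, dict[str, bool]]:
    if isinstance(feature, AlleleCall):
        return feature.label, carrier_status(cohort, feature)
    if isinstance(feature, ResidueFeature):
        if alignment is None:
            raise HlassocError("residue feature needs an alignment table")
        return feature.label, residue_carrier_status(cohort, alignment, feature)
    if isinstance(feature, CdsVariant):
        if cds_table is None:
            raise HlassocError("CDS variant feature needs a CDS table")
        return feature.label, cds_variant_status(cohort, cds_table, feature)
    raise TypeError(f"unsupported feature type {type(feature).__name__}")


def predictor_metrics(
    cohort: Cohort,
    feature: Feature,
    case_group: str = "case",
    control_group: str = "tolerant_control",
    alignment: AlignmentTable | None = None,
    cds_table: Mapping[str, str] | None = None,
) -> PredictorMetrics:
    """Sensitivity/specificity of a carrier-defined genetic predictor.

    Carriers in the case group are true positives; carriers in the control
    group are false positives. Exact fractions are retained; the ``*_pct``
    properties round for display.
    """
    label, status = _feature_status(cohort, feature, alignment, cds_table)
    t = _table_from_status(cohort, status, case_group, control_group)
    return PredictorMetrics(feature=label, tp=t.a, fn=t.b, fp=t.c, tn=t.d)


def rank_predictors(
    cohort: Cohort,
    features: Iterable[Feature],
    case_group: str = "case",
    control_group: str = "tolerant_control",
    alpha: float = 0.05,
    alignment: AlignmentTable | None = None,
    cds_table: Mapping[str, str] | None = None,
    correction_mode: str = "zero_cells_only",
) -> list[tuple[PredictorMetrics, AssociationResult]]:
    """Joint predictor table: metrics plus exact association per feature.

    Sorted by p ascending, then sensitivity and specificity descending, then
    label (a stable, fully deterministic order).
    """
    features = list(features)
    if not features:
        raise ValueError("at least one feature is required")
    out = []
    for f in features:
        m = predictor_metrics(
            cohort, f, case_group, control_group, alignment, cds_table
        )
        assoc = result_from_table(m.feature, m.table, alpha, correction_mode)
        out.append((m, assoc))
    out.sort(
        key=lambda pair: (
            pair[1].p_two_sided,
            -pair[0].sensitivity,
            -pair[0].specificity,
            pair[0].feature,
        )
    )
    return out
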