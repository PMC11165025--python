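"""HLA genotype parsing, cohort I/O, and carrier-based contingency tables.

The unit of association throughout the package is *carrier status*: a sample
carries an allele (or, downstream, a residue or coding variant) if at least
one of its two chromosomes bears it. Allele calls are normalised to two-field
("four-digit", protein-level) resolution; higher-resolution calls are
truncated, never rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger("hlassoc")

#: closed vocabulary of cohort group labels
GROUPS = ("case", "tolerant_control", "population_control")


class HlassocError(Exception):
    """Base class for package errors."""


class AlleleParseError(HlassocError, ValueError):
    """Malformed HLA allele string."""


class CohortFormatError(HlassocError, ValueError):
    """Genotype table does not conform to the expected TSV layout."""


class CohortValidationError(HlassocError, ValueError):
    """Genotype table parsed but violates a cohort invariant."""


# ---------------------------------------------------------------------------
# allele calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class AlleleCall:
    """A single HLA allele call in standard nomenclature.

    Parameters
    ----------
    gene
        Locus symbol, e.g. ``"B"``.
    fields
        One to four numeric nomenclature fields, e.g. ``(15, 1)``.
    raw
        The original string the call was parsed from (kept for provenance;
        ignored in comparisons).
    """

    gene: str
    fields: tuple[int, ...]
    raw: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if not self.gene:
            raise AlleleParseError("allele gene symbol is empty")
        if not 1 <= len(self.fields) <= 4:
            raise AlleleParseError(
                f"allele must have 1-4 numeric fields, got {self.fields!r}"
            )

    @property
    def label(self) -> str:
        """Canonical two-field label, e.g. ``"B*15:01"``."""
        two = self.fields[:2]
        return f"{self.gene}*" + ":".join(f"{f:02d}" for f in two)

    def two_field(self) -> "AlleleCall":
        """Deterministic truncation to two-field (protein) resolution."""
        return AlleleCall(self.gene, self.fields[:2], self.raw)

    def matches(self, other: "AlleleCall") -> bool:
        """Equality at two-field resolution."""
        return self.gene == other.gene and self.fields[:2] == other.fields[:2]

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.label


def parse_allele(text: str) -> AlleleCall:
    """Parse an HLA allele string such as ``"HLA-B*15:01:01"``.

    The optional ``HLA-`` prefix is stripped and fields beyond the second are
    retained on the call but ignored by :attr:`AlleleCall.label`.
    """
    if not text or not text.strip():
        raise AlleleParseError("empty allele string")
    s = text.strip()
    body = s[4:] if s.upper().startswith("HLA-") else s
    if "*" not in body:
        raise AlleleParseError(f"allele {text!r} lacks the '*' separator")
    gene, _, rest = body.partition("*")
    gene = gene.strip()
    if not gene:
        raise AlleleParseError(f"allele {text!r} has an empty gene symbol")
    parts = rest.split(":")
    fields = []
    for tok in parts:
        tok = tok.strip()
        if not tok.isdigit():
            raise AlleleParseError(
                f"allele {text!r}: field {tok!r} is not numeric"
            )
        fields.append(int(tok))
    if not fields:
        raise AlleleParseError(f"allele {text!r} has no numeric fields")
    return AlleleCall(gene, tuple(fields[:4]), raw=s)


# ---------------------------------------------------------------------------
# samples and cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleGenotype:
    """A diploid genotype at one HLA locus with a study group label."""

    sample_id: str
    group: str
    alleles: tuple[AlleleCall, AlleleCall]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CohortValidationError(
                f"sample {self.sample_id!r}: unknown group {self.group!r}; "
                f"expected one of {GROUPS}"
            )
        if len(self.alleles) != 2:
            raise CohortValidationError(
                f"sample {self.sample_id!r}: exactly two allele calls required"
            )

    def carries(self, allele: AlleleCall) -> bool:
        """True if either chromosome matches at two-field resolution."""
        return any(a.matches(allele) for a in self.alleles)


@dataclass
class Cohort:
    """A collection of samples genotyped at a single locus."""

    samples: list[SampleGenotype]
    locus: str = "B"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for s in self.samples:
            if s.sample_id in seen:
                raise CohortValidationError(
                    f"duplicate sample_id {s.sample_id!r}"
                )
            seen.add(s.sample_id)
            for a in s.alleles:
                if a.gene != self.locus:
                    raise CohortValidationError(
                        f"sample {s.sample_id!r}: allele {a.label} is not at "
                        f"locus {self.locus!r}"
                    )

    def __len__(self) -> int:
        return len(self.samples)

    def group(self, label: str) -> list[SampleGenotype]:
        return [s for s in self.samples if s.group == label]

    def group_size(self, label: str) -> int:
        return len(self.group(label))

    def observed_alleles(self, group: str | None = None) -> list[AlleleCall]:
        """Distinct two-field alleles observed, sorted by label.

        Restricted to ``group`` when given.
        """
        pool = self.samples if group is None else self.group(group)
        seen: dict[str, AlleleCall] = {}
        for s in pool:
            for a in s.alleles:
                tf = a.two_field()
                seen.setdefault(tf.label, tf)
        return [seen[k] for k in sorted(seen)]


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Carrier counts for a case/control comparison.

    ``a`` case carriers, ``b`` case non-carriers, ``c`` control carriers,
    ``d`` control non-carriers.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 0:
                raise CohortValidationError(
                    f"table cell {name}={v!r} must be a non-negative integer"
                )

    @property
    def n_cases(self) -> int:
        return self.a + self.b

    @property
    def n_controls(self) -> int:
        return self.c + self.d

    @property
    def total(self) -> int:
        return self.n_cases + self.n_controls

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    def swapped(self) -> "ContingencyTable2x2":
        """Case and control rows exchanged (odds ratio reciprocal)."""
        return ContingencyTable2x2(self.c, self.d, self.a, self.b)


def carrier_status(cohort: Cohort, allele: AlleleCall) -> dict[str, bool]:
    """Per-sample carrier status of ``allele`` at two-field resolution.

    Homozygotes count once: the map is boolean, not a dosage.
    """
    if allele.gene != cohort.locus:
        raise CohortValidationError(
            f"allele {allele.label} is not at cohort locus {cohort.locus!r}"
        )
    return {s.sample_id: s.carries(allele) for s in cohort.samples}


def _table_from_status(
    cohort: Cohort,
    status: Mapping[str, bool],
    case_group: str,
    control_group: str,
) -> ContingencyTable2x2:
    cases = cohort.group(case_group)
    controls = cohort.group(control_group)
    if not cases:
        raise CohortValidationError(f"group {case_group!r} is empty")
    if not controls:
        raise CohortValidationError(f"group {control_group!r} is empty")
    a = sum(status[s.sample_id] for s in cases)
    c = sum(status[s.sample_id] for s in controls)
    return ContingencyTable2x2(a, len(cases) - a, c, len(controls) - c)


def carrier_table(
    cohort: Cohort,
    allele: AlleleCall,
    case_group: str = "case",
    control_group: str = "tolerant_control",
) -> ContingencyTable2x2:
    """Carrier 2x2 table (case carriers, case non-carriers; control ditto)."""
    status = carrier_status(cohort, allele)
    return _table_from_status(cohort, status, case_group, control_group)


def carrier_frequency(cohort: Cohort, allele: AlleleCall, group: str) -> float:
    """Fraction of samples in ``group`` carrying ``allele``."""
    members = cohort.group(group)
    if not members:
        raise CohortValidationError(f"group {group!r} is empty")
    return sum(s.carries(allele) for s in members) / len(members)


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def _is_blank(v) -> bool:
    return pd.isna(v) or (isinstance(v, str) and not v.strip())


def read_cohort(path: str | Path, locus: str = "B") -> Cohort:
    """Read a genotype TSV into a :class:`Cohort`.

    Two layouts are accepted (UTF-8, tab-delimited, header required):

    * columns ``sample_id``, ``group``, ``allele1``, ``allele2``;
    * columns ``sample_id``, ``group``, ``genotype`` with
      ``genotype = "allele1/allele2"``.

    Rows in which both allele calls are missing are treated as incomplete
    samples and dropped with a logged warning. A row with exactly one blank
    call is malformed and raises.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = set(df.columns)
    if not {"sample_id", "group"} <= cols:
        raise CohortFormatError(
            f"{path}: missing required column(s) "
            f"{sorted({'sample_id', 'group'} - cols)}"
        )
    if {"allele1", "allele2"} <= cols:
        pairs = list(zip(df["allele1"], df["allele2"]))
    elif "genotype" in cols:
        pairs = []
        for g in df["genotype"]:
            if _is_blank(g):
                pairs.append((None, None))
            elif "/" in g:
                a1, _, a2 = g.partition("/")
                pairs.append((a1, a2))
            else:
                raise CohortFormatError(
                    f"{path}: genotype {g!r} is not 'allele1/allele2'"
                )
    else:
        raise CohortFormatError(
            f"{path}: need columns allele1+allele2 or genotype"
        )

    samples: list[SampleGenotype] = []
    for (_, row), (a1, a2) in zip(df.iterrows(), pairs):
        if _is_blank(a1) and _is_blank(a2):
            logger.warning(
                "sample %r: incomplete genotype, excluded", row["sample_id"]
            )
            continue
        if _is_blank(a1) or _is_blank(a2):
            raise CohortValidationError(
                f"sample {row['sample_id']!r}: one of two allele calls is "
                "blank"
            )
        calls = (_qualify(a1, locus), _qualify(a2, locus))
        samples.append(SampleGenotype(row["sample_id"], row["group"], calls))
    return Cohort(samples, locus=locus)


def _qualify(text: str, locus: str) -> AlleleCall:
    """Parse an allele, accepting bare ``15:01`` shorthand for the locus."""
    s = text.strip()
    if "*" not in s:
        s = f"{locus}*{s}"
    return parse_allele(s)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Serialise a cohort as a normalised two-allele-column TSV."""
    rows = [
        {
            "sample_id": s.sample_id,
            "group": s.group,
            "allele1": s.alleles[0].label,
            "allele2": s.alleles[1].label,
        }
        for s in cohort.samples
    ]
    pd.DataFrame(rows, columns=["sample_id", "group", "allele1", "allele2"]).to_csv(
        path, sep="\t", index=False
    )


def summarize_cohort(cohort: Cohort) -> pd.DataFrame:
    """Per-group sample counts and carrier counts of every observed allele."""
    records = []
    for allele in cohort.observed_alleles():
        rec = {"allele": allele.label}
        for g in GROUPS:
            members = cohort.group(g)
            if members:
                rec[f"{g}_carriers"] = sum(s.carries(allele) for s in members)
                rec[f"{g}_n"] = len(members)
        records.append(rec)
    return pd.DataFrame(records)
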