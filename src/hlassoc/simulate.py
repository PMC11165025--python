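"""Synthetic diploid HLA-B cohorts with known association structure.

Two generators live here:

* a free simulator — Hardy-Weinberg genotypes from a configurable allele
  frequency pool, with case status assigned by a logistic model on risk
  carrier status at a chosen carrier odds ratio. It is the basis of type-I
  error, power, CI-coverage and parameter-recovery experiments.
* a deterministic study fixture — a four-patient case series with a
  100-member drug-tolerant control group whose allele- and residue-level
  carrier counts are fixed exactly, together with a matching mature-protein
  alignment and per-allele CDS table. Control genotypes place risk alleles on
  distinct samples (only marginal counts are constrained, and all 2x2 results
  depend on margins alone). The alignment and CDS sequences are synthetic:
  a fixed pseudo-random background with the analytically relevant residues
  and codons pinned at the polymorphic positions.

Default parameters of :class:`SimulationConfig` mirror the emulated study:
four cases, 100 tolerant controls, 1000 population controls, a B*15:01
carrier frequency of 10.7% in the general population, and a carrier odds
ratio of 22.9.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from .genotypes import (
    AlleleCall,
    Cohort,
    HlassocError,
    SampleGenotype,
    parse_allele,
    write_cohort,
)
from .residues import AlignmentTable

__all__ = [
    "SimulationConfig",
    "SimulationError",
    "StudyFixture",
    "allele_freq_for_carrier",
    "carrier_freq_of_allele",
    "simulate_population",
    "simulate_case_control",
    "study_fixture",
    "write_fixture",
]


class SimulationError(HlassocError, RuntimeError):
    pass


def allele_freq_for_carrier(carrier_freq: float) -> float:
    """Allele frequency q with diploid carrier frequency 1-(1-q)^2."""
    if not 0.0 <= carrier_freq <= 1.0:
        raise ValueError("carrier frequency must be in [0, 1]")
    return 1.0 - math.sqrt(1.0 - carrier_freq)


def carrier_freq_of_allele(q: float) -> float:
    """Diploid carrier frequency of an allele with frequency q under HWE."""
    return 1.0 - (1.0 - q) ** 2


#: allele frequencies emulating the study population: carrier frequencies of
#: 10.7% (B*15:01, the general-population figure) and the tolerant-control
#: carrier rates of the other alleles seen in the case series
STUDY_ALLELE_FREQS: dict[str, float] = {
    "B*15:01": allele_freq_for_carrier(0.107),
    "B*13:01": allele_freq_for_carrier(0.10),
    "B*35:05": allele_freq_for_carrier(0.02),
    "B*37:01": allele_freq_for_carrier(0.04),
    "B*39:01": allele_freq_for_carrier(0.02),
    "B*51:01": allele_freq_for_carrier(0.11),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study-shaped generative model for a diploid case/control cohort.

    ``allele_freqs`` may sum to less than one; the remainder is pooled into
    ``other_label``. Case status follows a logistic model on carrier status
    of any allele in ``risk_alleles``: non-carrier odds are
    ``baseline_case_prob/(1-baseline_case_prob)``, carrier odds are that
    times ``target_or``.
    """

    allele_freqs: Mapping[str, float] = field(
        default_factory=lambda: dict(STUDY_ALLELE_FREQS)
    )
    risk_alleles: tuple[str, ...] = ("B*15:01",)
    target_or: float = 22.9
    baseline_case_prob: float = 1e-3
    n_case: int = 4
    n_tolerant: int = 100
    n_population: int = 1000
    seed: int = 0
    locus: str = "B"
    other_label: str = "B*00:00"

    def __post_init__(self) -> None:
        total = 0.0
        for label, q in self.allele_freqs.items():
            if not 0.0 <= q <= 1.0:
                raise SimulationError(f"frequency of {label!r} is {q}, not in [0,1]")
            total += q
        if total > 1.0 + 1e-9:
            raise SimulationError(f"allele frequencies sum to {total:.4f} > 1")
        if self.target_or <= 0:
            raise SimulationError("target odds ratio must be > 0")
        if not 0.0 < self.baseline_case_prob < 1.0:
            raise SimulationError("baseline case probability must be in (0,1)")
        if self.n_case < 1 or self.n_tolerant < 1 or self.n_population < 0:
            raise SimulationError("group sizes out of range")

    def pool(self) -> tuple[list[str], np.ndarray]:
        labels = list(self.allele_freqs)
        probs = np.array([self.allele_freqs[l] for l in labels], dtype=float)
        rest = 1.0 - probs.sum()
        if rest > 1e-12:
            labels.append(self.other_label)
            probs = np.append(probs, rest)
        return labels, probs / probs.sum()


def simulate_population(
    config: SimulationConfig,
    n: int,
    rng: np.random.Generator | None = None,
) -> list[tuple[str, str]]:
    """Draw ``n`` diploid genotypes (pairs of allele labels) under HWE."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    labels, probs = config.pool()
    idx = rng.choice(len(labels), size=(n, 2), p=probs)
    return [(labels[i], labels[j]) for i, j in idx]


def simulate_case_control(config: SimulationConfig) -> Cohort:
    """Simulate a full cohort at the configured group sizes.

    Population genotypes are drawn in batches; case status is assigned by
    the logistic carrier model and groups are filled by rejection until
    ``n_case`` cases and ``n_tolerant + n_population`` controls accumulate.
    The true odds ratio is recorded in the cohort metadata.
    """
    rng = np.random.default_rng(config.seed)
    labels, probs = config.pool()
    calls = {l: parse_allele(l) for l in labels}
    risk = set(config.risk_alleles)
    odds0 = config.baseline_case_prob / (1.0 - config.baseline_case_prob)
    p_noncar = odds0 / (1.0 + odds0)
    odds1 = odds0 * config.target_or
    p_car = odds1 / (1.0 + odds1)

    n_controls_needed = config.n_tolerant + config.n_population
    # expected fraction of draws that become cases, for batch sizing
    q_car = sum(
        carrier_freq_of_allele(config.allele_freqs.get(l, 0.0)) for l in risk
    )
    case_rate = max(1e-6, (1 - q_car) * p_noncar + q_car * p_car)
    batch = int(
        min(
            2_000_000,
            max(
                512,
                4 * config.n_case / case_rate,
                2 * n_controls_needed,
            ),
        )
    )

    risk_idx = np.array([i for i, l in enumerate(labels) if l in risk])
    cases: list[tuple[str, str]] = []
    controls: list[tuple[str, str]] = []
    filled = False
    for _ in range(200):
        idx = rng.choice(len(labels), size=(batch, 2), p=probs)
        carrier = np.isin(idx, risk_idx).any(axis=1)
        p_case = np.where(carrier, p_car, p_noncar)
        is_case = rng.random(batch) < p_case
        for r in np.flatnonzero(is_case)[: config.n_case - len(cases)]:
            cases.append((labels[idx[r, 0]], labels[idx[r, 1]]))
        for r in np.flatnonzero(~is_case)[: n_controls_needed - len(controls)]:
            controls.append((labels[idx[r, 0]], labels[idx[r, 1]]))
        if len(cases) >= config.n_case and len(controls) >= n_controls_needed:
            filled = True
            break
    if not filled:
        raise SimulationError(
            "could not fill the requested group sizes within the iteration cap"
        )

    samples = [
        SampleGenotype(f"sim_case_{i+1:04d}", "case", (calls[a], calls[b]))
        for i, (a, b) in enumerate(cases)
    ]
    samples += [
        SampleGenotype(
            f"sim_tc_{i+1:05d}", "tolerant_control", (calls[a], calls[b])
        )
        for i, (a, b) in enumerate(controls[: config.n_tolerant])
    ]
    samples += [
        SampleGenotype(
            f"sim_pc_{i+1:05d}", "population_control", (calls[a], calls[b])
        )
        for i, (a, b) in enumerate(controls[config.n_tolerant :])
    ]
    return Cohort(
        samples,
        locus=config.locus,
        metadata={
            "true_or": config.target_or,
            "seed": config.seed,
            "baseline_case_prob": config.baseline_case_prob,
            "risk_alleles": list(config.risk_alleles),
        },
    )


# ---------------------------------------------------------------------------
# deterministic study fixture
# ---------------------------------------------------------------------------

_AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_MATURE_LENGTH = 338  # residues in the mature HLA-B heavy chain
_BACKGROUND_SEED = 893  # fixed: the fixture is a constant, not a simulation

#: the four case genotypes of the emulated case series
CASE_GENOTYPES: tuple[tuple[str, str], ...] = (
    ("B*13:01", "B*15:01"),
    ("B*15:01", "B*51:01"),
    ("B*15:01", "B*37:01"),
    ("B*39:01", "B*35:05"),
)

#: tolerant-control composition: (first allele, count); the second allele is
#: always the neutral filler B*07:02. Counts reproduce the reported marginal
#: carrier counts of the case-series alleles, and the extra control-only
#: alleles carry the residue features at the rates implied by the reported
#: predictor specificities.
CONTROL_COMPOSITION: tuple[tuple[str, int], ...] = (
    ("B*15:01", 11),
    ("B*13:01", 10),
    ("B*35:05", 2),
    ("B*37:01", 4),
    ("B*39:01", 2),
    ("B*51:01", 11),
    ("B*40:01", 11),
    ("B*46:01", 14),
    ("B*58:01", 15),
    ("B*07:02", 20),
)

# residue/codon state carried by every allele unless overridden below
_DEFAULT_STATE: dict[int, tuple[str, str]] = {
    14: ("L", "TTG"),
    17: ("M", "ATG"),
    48: ("P", "CCT"),
    121: ("S", "AGC"),
    140: ("F", "TTC"),
    180: ("L", "CTG"),
    187: ("V", "GTG"),
    306: ("V", "GTC"),
    329: ("P", "CCA"),
}

# the risk-residue block shared by B*15:01-like alleles (W180 is separate:
# only B*15:01 keeps the tryptophan, its relatives carry L180)
_RISK_CORE: dict[int, tuple[str, str]] = {
    14: ("W", "TGG"),
    17: ("V", "GTG"),
    48: ("A", "GCT"),
    121: ("R", "AGG"),
    140: ("S", "TCC"),
    187: ("L", "CTG"),
    306: ("I", "ATC"),
    329: ("T", "ACA"),
}

_ALLELE_OVERRIDES: dict[str, dict[int, tuple[str, str]]] = {
    "B*15:01": {**_RISK_CORE, 180: ("W", "TGG")},
    "B*15:02": dict(_RISK_CORE),
    "B*35:05": dict(_RISK_CORE),
    "B*40:01": {48: ("A", "GCT"), 187: ("L", "CTG")},
    "B*46:01": {
        14: ("W", "TGG"),
        17: ("V", "GTG"),
        121: ("R", "AGG"),
        187: ("P", "CCG"),
    },
    "B*58:01": {306: ("I", "ATC"), 329: ("T", "ACA")},
    "B*13:01": {},
    "B*37:01": {},
    "B*39:01": {},
    "B*51:01": {},
    "B*07:02": {},
}

#: one private background substitution per allele, so every fixture allele
#: has a distinct sequence and private-residue carrier tables mirror the
#: allele carrier tables
_PRIVATE_POSITION: dict[str, int] = {
    "B*13:01": 201,
    "B*15:01": 202,
    "B*35:05": 203,
    "B*37:01": 204,
    "B*39:01": 205,
    "B*51:01": 206,
    "B*07:02": 207,
    "B*40:01": 208,
    "B*46:01": 209,
    "B*58:01": 210,
    "B*15:02": 211,
}


def _codon_map() -> dict[str, str]:
    from Bio.Data.CodonTable import unambiguous_dna_by_id

    fwd = unambiguous_dna_by_id[1].forward_table
    inv: dict[str, str] = {}
    for codon, aa in sorted(fwd.items()):
        inv.setdefault(aa, codon)
    return inv


def _background() -> tuple[list[str], list[str]]:
    """Fixed pseudo-random mature-protein background and its codons."""
    rng = np.random.default_rng(_BACKGROUND_SEED)
    codon_of = _codon_map()
    aas = [str(a) for a in rng.choice(list(_AA_ORDER), size=_MATURE_LENGTH)]
    codons = [codon_of[a] for a in aas]
    return aas, codons


def _build_sequences() -> tuple[dict[str, str], dict[str, str]]:
    bg_aa, bg_codon = _background()
    codon_of = _codon_map()
    proteins: dict[str, str] = {}
    cds: dict[str, str] = {}
    for allele, overrides in _ALLELE_OVERRIDES.items():
        aa = list(bg_aa)
        codons = list(bg_codon)
        state = {**_DEFAULT_STATE, **overrides}
        for pos, (res, codon) in state.items():
            aa[pos - 1] = res
            codons[pos - 1] = codon
        ppos = _PRIVATE_POSITION[allele]
        base = aa[ppos - 1]
        private = _AA_ORDER[(_AA_ORDER.index(base) + 1) % len(_AA_ORDER)]
        aa[ppos - 1] = private
        codons[ppos - 1] = codon_of[private]
        proteins[allele] = "".join(aa)
        cds[allele] = "".join(codons)
    return proteins, cds


class StudyFixture(NamedTuple):
    cohort: Cohort
    alignment: AlignmentTable
    cds: dict[str, str]


def study_fixture() -> StudyFixture:
    """The packaged deterministic study cohort plus sequence tables.

    Four cases with the case-series genotypes and 100 tolerant controls with
    exactly the reported allele- and residue-carrier margins, a mature-
    protein alignment over 11 HLA-B alleles (the six case-series alleles,
    B*15:02, and four control-only alleles), and the matching per-allele
    CDS table. Byte-identical on every call.
    """
    labels = sorted(_ALLELE_OVERRIDES)
    calls = {l: parse_allele(l) for l in labels}
    samples = [
        SampleGenotype(f"case_{i+1}", "case", (calls[a], calls[b]))
        for i, (a, b) in enumerate(CASE_GENOTYPES)
    ]
    k = 0
    filler = calls["B*07:02"]
    for allele, count in CONTROL_COMPOSITION:
        for _ in range(count):
            k += 1
            samples.append(
                SampleGenotype(
                    f"tc_{k:03d}", "tolerant_control", (calls[allele], filler)
                )
            )
    cohort = Cohort(samples, locus="B", metadata={"fixture": "study"})
    proteins, cds = _build_sequences()
    alignment = AlignmentTable(proteins, locus="B")
    return StudyFixture(cohort, alignment, cds)


def write_fixture(outdir: str | Path) -> dict[str, Path]:
    """Write the study fixture as cohort.tsv, alignment.fasta, cds.fasta."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fx = study_fixture()
    paths = {
        "cohort": outdir / "cohort.tsv",
        "alignment": outdir / "alignment.fasta",
        "cds": outdir / "cds.fasta",
    }
    write_cohort(fx.cohort, paths["cohort"])
    with open(paths["alignment"], "w") as fh:
        for allele in sorted(fx.alignment.entries):
            fh.write(f">{allele}\n{fx.alignment.entries[allele]}\n")
    with open(paths["cds"], "w") as fh:
        for allele in sorted(fx.cds):
            fh.write(f">{allele}\n{fx.cds[allele]}\n")
    return paths
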