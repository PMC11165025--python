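"""End-to-end orchestration: allele screen, residue screen, predictor table.

The run writes three TSV reports (alleles, residues, predictors) plus a JSON
manifest with versions, seed and configuration, and is byte-identical for
identical inputs. Numbers are written at full precision alongside a display
rendering (p to three significant figures; odds ratios to one decimal at or
above 10, two decimals below).
"""

from __future__ import annotations

import json
import logging
import math
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .exact2x2 import AssociationResult, screen_alleles
from .genotypes import Cohort, HlassocError, read_cohort
from .predictors import (
    CdsVariant,
    NotCodonLocalError,
    distinguishing_variant,
    rank_predictors,
    read_cds,
)
from .residues import (
    AlignmentTable,
    ResidueFeature,
    count_significant,
    read_alignment,
    screen_residues,
)

logger = logging.getLogger("hlassoc")


def configure_logging(level: int = logging.INFO) -> None:
    """Console logging setup shared by the CLI entry points."""
    logging.basicConfig(
        level=level, format="%(asctime)s %(name)s %(levelname)s %(message)s"
    )


class PipelineError(HlassocError, RuntimeError):
    """A stage failure, tagged with the stage that raised it."""


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    cohort: str
    alignment: str | None = None
    cds: str | None = None
    case_group: str = "case"
    control_group: str = "tolerant_control"
    alpha: float = 0.05
    correction_mode: str = "zero_cells_only"
    adjust: str | None = None
    outdir: str = "hlassoc_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise PipelineError(f"alpha={self.alpha} must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not raw:
            raise PipelineError(f"{path}: empty run configuration")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise PipelineError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# display formatting
# ---------------------------------------------------------------------------

def format_p(p: float) -> str:
    """Three significant figures, scientific below 1e-3 (report style)."""
    if p < 1e-3:
        return f"{p:.2e}"
    return f"{p:.3g}"


def format_or(x: float) -> str:
    if math.isinf(x):
        return "Inf"
    if x == 0.0:
        return "0"
    return f"{x:.1f}" if x >= 10 else f"{x:.2f}"


def association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Full-precision association table with display columns."""
    rows = []
    for r in results:
        a, b, c, d = r.table.as_tuple()
        rows.append(
            {
                "feature": r.feature,
                "a": a,
                "b": b,
                "c": c,
                "d": d,
                "p": r.p_two_sided,
                "or": r.or_estimate,
                "or_method": r.or_method,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p_adjusted": r.p_adjusted,
                "p_display": format_p(r.p_two_sided),
                "or_display": format_or(r.or_estimate),
                "ci_display": f"{format_or(r.ci_low)}-{format_or(r.ci_high)}",
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# full analysis
# ---------------------------------------------------------------------------

def _stage(name: str):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except HlassocError as exc:
            raise PipelineError(f"[{name}] {exc}") from exc

    return wrap


def significant_residue_variants(
    alignment: AlignmentTable,
    cds_table: dict[str, str],
    residue_results: list[AssociationResult],
    alpha: float,
) -> dict[str, CdsVariant]:
    """Map each significant risk residue to its codon-local CDS variant.

    Residues whose codon holds no 1-2 base separating run are skipped with a
    warning (the mapping is defined codon-locally only).
    """
    out: dict[str, CdsVariant] = {}
    for r in residue_results:
        if r.p_two_sided >= alpha:
            continue
        feat = ResidueFeature.parse(r.feature)
        risk = [
            l
            for l in sorted(alignment.entries)
            if alignment.entries[l][feat.position - 1] == feat.residue
        ]
        other = [l for l in sorted(alignment.entries) if l not in set(risk)]
        try:
            out[r.feature] = distinguishing_variant(cds_table, feat, risk, other)
        except NotCodonLocalError as exc:
            logger.warning("residue %s: %s", r.feature, exc)
    return out


def run_full_analysis(config: RunConfig) -> dict:
    """Run the allele screen, residue screen and predictor evaluation.

    Returns a bundle with the three result frames, the residue-to-variant
    map, and the paths written. Stages after the allele screen require the
    alignment (and, for predictors, the CDS table) and are skipped when the
    corresponding input is absent.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort = _stage("cohort")(read_cohort, config.cohort)
    logger.info(
        "cohort: %d samples (%d cases, %d controls)",
        len(cohort),
        cohort.group_size(config.case_group),
        cohort.group_size(config.control_group),
    )

    allele_results = _stage("alleles")(
        screen_alleles,
        cohort,
        config.case_group,
        config.control_group,
        config.alpha,
        "cases",
        config.correction_mode,
        config.adjust,
    )
    allele_df = association_frame(allele_results)
    allele_path = outdir / "allele_associations.tsv"
    allele_df.to_csv(allele_path, sep="\t", index=False)

    bundle: dict = {
        "cohort": cohort,
        "alleles": allele_df,
        "paths": {"alleles": allele_path},
    }

    residue_results: list[AssociationResult] = []
    alignment = None
    if config.alignment:
        alignment = _stage("residues")(read_alignment, config.alignment)
        residue_results = _stage("residues")(
            screen_residues,
            cohort,
            alignment,
            config.case_group,
            config.control_group,
            config.alpha,
            config.correction_mode,
            config.adjust,
        )
        residue_df = association_frame(residue_results)
        residue_path = outdir / "residue_associations.tsv"
        residue_df.to_csv(residue_path, sep="\t", index=False)
        bundle["residues"] = residue_df
        bundle["paths"]["residues"] = residue_path
        logger.info(
            "residues: %d tested, %d with p < %g",
            len(residue_results),
            count_significant(residue_results, config.alpha),
            config.alpha,
        )

    if config.cds and alignment is not None:
        cds_table = _stage("predictors")(read_cds, config.cds)
        variants = _stage("predictors")(
            significant_residue_variants,
            alignment,
            cds_table,
            residue_results,
            config.alpha,
        )
        from .genotypes import parse_allele

        feature_objs: list = [
            parse_allele(res.feature)
            for res in allele_results
            if res.p_two_sided < config.alpha
        ]
        feature_objs += list(variants.values())
        if feature_objs:
            ranked = _stage("predictors")(
                rank_predictors,
                cohort,
                feature_objs,
                config.case_group,
                config.control_group,
                config.alpha,
                alignment,
                cds_table,
                config.correction_mode,
            )
            pred_rows = []
            for metrics, assoc in ranked:
                pred_rows.append(
                    {
                        "predictor": metrics.feature,
                        "tp": metrics.tp,
                        "fn": metrics.fn,
                        "fp": metrics.fp,
                        "tn": metrics.tn,
                        "sensitivity": metrics.sensitivity,
                        "specificity": metrics.specificity,
                        "sensitivity_pct": metrics.sensitivity_pct,
                        "specificity_pct": metrics.specificity_pct,
                        "p": assoc.p_two_sided,
                        "or": assoc.or_estimate,
                        "or_method": assoc.or_method,
                        "p_display": format_p(assoc.p_two_sided),
                        "or_display": format_or(assoc.or_estimate),
                    }
                )
            pred_df = pd.DataFrame(pred_rows)
            pred_path = outdir / "predictors.tsv"
            pred_df.to_csv(pred_path, sep="\t", index=False)
            bundle["predictors"] = pred_df
            bundle["variant_map"] = {k: v.label for k, v in variants.items()}
            bundle["paths"]["predictors"] = pred_path

    manifest = {
        "tool": "hlassoc",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": asdict(config),
        "n_samples": len(cohort),
        "variant_map": bundle.get("variant_map", {}),
    }
    manifest_path = outdir / "run_manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    bundle["paths"]["manifest"] = manifest_path
    return bundle
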