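"""Config-driven end-to-end runner.

A single YAML (or in-memory dict) configuration describes the exposure
GWAS, any number of outcome GWASs with their cohort metadata, the LD
matrix, selection thresholds and power scenarios. The run executes the
canonical stage order -- select instruments, harmonize and align each
exposure/outcome pair, estimate per cohort (Wald ratio with one
instrument, IVW with several), pool cohorts per outcome trait with the
heterogeneity-driven model choice, tabulate F statistics and power -- and
writes one TSV per stage plus a combined results table. Per-cohort
estimates available only as published OR/CI (``external_estimates``) are
reconstructed on the log scale and enter the meta stage alongside
estimates computed from summary statistics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import yaml

from . import estimate as est
from . import meta as meta_mod
from .io import (
    read_associations,
    read_ld_matrix,
    write_results_table,
)
from .power import PowerScenario, binary_mr_power
from .select import align_to_increasing, harmonize_pair, select_instruments
from .types import (
    AssociationRecord,
    ConfigurationError,
    HarmonizationError,
    LDMatrix,
    MetaResult,
    MREstimate,
    SelectionCriteria,
    StudyMeta,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class OutcomeSource:
    """One outcome GWAS: file, cohort metadata and column mapping."""

    path: Path
    meta: StudyMeta
    column_map: Optional[dict] = None


@dataclass
class RunConfig:
    """Validated run configuration (see the YAML schema in the docs)."""

    exposure_path: Path
    exposure_meta: StudyMeta
    ld_path: Path
    outcomes: List[OutcomeSource] = field(default_factory=list)
    exposure_column_map: Optional[dict] = None
    external_estimates: List[dict] = field(default_factory=list)
    criteria: SelectionCriteria = field(default_factory=SelectionCriteria)
    se_method: str = "first_order"
    ci_level: float = 0.95
    meta_model: str = "auto"  # auto | fixed | random
    q_alpha: float = 0.05
    power_scenarios: List[dict] = field(default_factory=list)
    output_dir: Path = Path("targetmr_results")
    or_decimals: int = 2

    def __post_init__(self) -> None:
        if self.meta_model not in ("auto", "fixed", "random"):
            raise ConfigurationError(f"meta_model must be auto|fixed|random, got {self.meta_model!r}")
        labels = [o.meta.label for o in self.outcomes] + [
            e.get("label", "") for e in self.external_estimates
        ]
        if len(labels) != len(set(labels)):
            raise ConfigurationError("outcome cohort labels must be unique")
        for p in [self.exposure_path, self.ld_path] + [o.path for o in self.outcomes]:
            if not Path(p).exists():
                raise ConfigurationError(f"input file not found: {p}")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text())
        base = path.parent

        def _resolve(p: str) -> Path:
            p = Path(p)
            return p if p.is_absolute() else base / p

        exp = raw["exposure"]
        exposure_meta = StudyMeta(
            label=exp.get("label", "exposure"),
            trait=exp.get("trait", "exposure"),
            n=int(exp.get("n", 0)),
        )
        outcomes = []
        for out in raw.get("outcomes", []):
            meta = StudyMeta(
                label=out.get("label", out.get("trait", "outcome")),
                trait=out.get("trait", "outcome"),
                trait_type=out.get("trait_type", "binary"),
                n=int(out.get("n", 0)),
                n_cases=int(out.get("n_cases", 0)),
                n_controls=int(out.get("n_controls", 0)),
            )
            outcomes.append(
                OutcomeSource(path=_resolve(out["file"]), meta=meta,
                              column_map=out.get("column_map"))
            )
        sel = raw.get("selection", {})
        criteria = SelectionCriteria(
            p_max=float(sel.get("p_max", 5e-8)),
            maf_min=float(sel.get("maf_min", 0.01)),
            ld_r2_max=float(sel.get("ld_r2_max", 0.3)),
            drop_palindromic=bool(sel.get("drop_palindromic", True)),
        )
        return cls(
            exposure_path=_resolve(exp["file"]),
            exposure_meta=exposure_meta,
            exposure_column_map=exp.get("column_map"),
            ld_path=_resolve(raw["ld_file"]),
            outcomes=outcomes,
            external_estimates=raw.get("external_estimates", []),
            criteria=criteria,
            se_method=raw.get("se_method", "first_order"),
            ci_level=float(raw.get("ci_level", 0.95)),
            meta_model=raw.get("meta_model", "auto"),
            q_alpha=float(raw.get("q_alpha", 0.05)),
            power_scenarios=raw.get("power_scenarios", []),
            output_dir=_resolve(raw.get("output_dir", "targetmr_results")),
            or_decimals=int(raw.get("or_decimals", 2)),
        )


def _write_tsv(path: Path, header: Sequence[str], rows: Sequence[Sequence]) -> None:
    lines = ["\t".join(header)]
    for row in rows:
        lines.append("\t".join("" if v is None else str(v) for v in row))
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute the full analysis; returns stage outputs keyed by stage name.

    Writes selection.tsv, harmonized.tsv, estimates.tsv, meta.tsv,
    f_statistics.tsv, power.tsv and combined.tsv under
    ``config.output_dir``. Any stage error aborts the run with a
    :class:`PipelineError`; partially written outputs are removed.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []
    results: Dict[str, object] = {}

    def _emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        written.append(path)

    stage = "read_inputs"
    try:
        exposure = read_associations(
            config.exposure_path, config.exposure_column_map, config.exposure_meta
        )
        ld = read_ld_matrix(config.ld_path)
        outcome_data = [
            (src.meta, read_associations(src.path, src.column_map, src.meta))
            for src in config.outcomes
        ]

        stage = "select"
        instruments = select_instruments(exposure, config.criteria, ld)
        logger.info("retained instruments: %s", ", ".join(instruments.rsids) or "(none)")
        _emit(
            "selection.tsv",
            lambda p: _write_tsv(
                p,
                ["rsid", "retained", "reason"],
                [(r, str(keep).lower(), why) for r, keep, why in instruments.selection_log],
            ),
        )
        results["instruments"] = instruments

        stage = "harmonize"
        cohort_pairs = []  # (meta, aligned pairs)
        harmonized_rows = []
        for meta, recs in outcome_data:
            by_rsid = {r.rsid: r for r in recs}
            pairs = []
            for exp_rec in instruments.records:
                if exp_rec.rsid not in by_rsid:
                    logger.warning(
                        "%s absent from outcome %s; dropped from that cohort",
                        exp_rec.rsid, meta.label,
                    )
                    continue
                pair = align_to_increasing(harmonize_pair(exp_rec, by_rsid[exp_rec.rsid]))
                pairs.append(pair)
                harmonized_rows.append(
                    (meta.label, pair.rsid, pair.effect_allele, pair.other_allele,
                     f"{pair.exposure_beta:.6g}", f"{pair.exposure_se:.6g}",
                     f"{pair.outcome_beta:.6g}", f"{pair.outcome_se:.6g}",
                     pair.orientation_action)
                )
            cohort_pairs.append((meta, pairs))
        _emit(
            "harmonized.tsv",
            lambda p: _write_tsv(
                p,
                ["cohort", "rsid", "effect_allele", "other_allele",
                 "exposure_beta", "exposure_se", "outcome_beta", "outcome_se",
                 "orientation_action"],
                harmonized_rows,
            ),
        )
        results["harmonized"] = cohort_pairs

        stage = "estimate"
        estimates: List[MREstimate] = []  # every reported row
        cohort_level: List[MREstimate] = []  # one per cohort, feeds the meta stage
        for meta, pairs in cohort_pairs:
            if not pairs:
                continue
            for pair in pairs:  # per-instrument Wald rows
                res = est.wald_ratio(pair, config.se_method, config.ci_level)
                estimates.append(
                    _relabel(res, method=f"wald_ratio[{pair.rsid}]",
                             exposure=config.exposure_meta.trait, outcome=meta.label)
                )
            if len(pairs) == 1:
                res = est.wald_ratio(pairs[0], config.se_method, config.ci_level)
            else:
                res = est.ivw(pairs, config.ci_level)
            res = _relabel(res, exposure=config.exposure_meta.trait, outcome=meta.label)
            cohort_level.append(res)
            if len(pairs) > 1:
                estimates.append(res)
        for ext in config.external_estimates:
            reconstructed = meta_mod.estimate_from_or_ci(
                float(ext["or"]), float(ext["ci_low"]), float(ext["ci_high"]),
                method=ext.get("method", "wald_ratio"),
                n_snps=int(ext.get("n_snps", 1)),
                ci_level=config.ci_level,
                exposure=config.exposure_meta.trait,
                outcome=ext.get("label", ext.get("outcome", "external")),
            )
            cohort_level.append(reconstructed)
            estimates.append(reconstructed)
        _emit("estimates.tsv", lambda p: write_results_table(estimates, p, config.or_decimals))
        results["estimates"] = estimates
        results["cohort_estimates"] = cohort_level

        stage = "meta"
        outcome_trait = {}  # cohort label -> trait, for grouping
        for meta, _ in cohort_pairs:
            outcome_trait[meta.label] = meta.trait
        for ext in config.external_estimates:
            outcome_trait[ext.get("label", "external")] = ext.get("outcome", "outcome")
        groups: Dict[str, List[MREstimate]] = {}
        for e in cohort_level:
            groups.setdefault(outcome_trait.get(e.outcome, e.outcome), []).append(e)
        meta_results: List[MetaResult] = []
        for trait, group in groups.items():
            model = config.meta_model
            if model == "auto":
                model = meta_mod.decide_model(group, config.q_alpha)
                logger.info("meta model for %s: %s (auto)", trait, model)
            pooled = (
                meta_mod.pool_fixed(group, config.ci_level)
                if model == "fixed"
                else meta_mod.pool_random(group, config.ci_level)
            )
            meta_results.append(_relabel(pooled, outcome=trait))
        _emit("meta.tsv", lambda p: write_results_table(meta_results, p, config.or_decimals))
        results["meta"] = meta_results

        stage = "f_statistics"
        f_rows = [
            (rec.rsid, f"{est.f_statistic(rec):.2f}") for rec in instruments.records
        ]
        _emit("f_statistics.tsv", lambda p: _write_tsv(p, ["rsid", "f_statistic"], f_rows))
        results["f_statistics"] = {r.rsid: est.f_statistic(r) for r in instruments.records}

        stage = "power"
        power_rows = []
        powers = {}
        for sc in config.power_scenarios:
            scenario = PowerScenario(
                n=int(sc["n"]),
                case_fraction=float(sc["case_fraction"]),
                or_per_sd=float(sc["or_per_sd"]),
                r2=float(sc["r2"]),
                alpha=float(sc.get("alpha", 0.05)),
            )
            pw = binary_mr_power(scenario)
            label = sc.get("label", f"n{scenario.n}")
            powers[label] = pw
            power_rows.append(
                (label, scenario.n, f"{scenario.case_fraction:.4g}",
                 f"{scenario.or_per_sd:.4g}", f"{scenario.r2:.4g}",
                 f"{scenario.alpha:.3g}", f"{pw:.4f}")
            )
        _emit(
            "power.tsv",
            lambda p: _write_tsv(
                p, ["scenario", "n", "case_fraction", "or_per_sd", "r2", "alpha", "power"],
                power_rows,
            ),
        )
        results["power"] = powers

        stage = "combined"
        _emit(
            "combined.tsv",
            lambda p: write_results_table(list(estimates) + list(meta_results), p,
                                          config.or_decimals),
        )
        results["output_files"] = list(written)
        return results
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc


def _relabel(res, **kwargs):
    from dataclasses import replace

    return replace(res, **kwargs)
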