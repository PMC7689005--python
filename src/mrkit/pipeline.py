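"""End-to-end orchestration: read -> clump -> harmonize -> estimate ->
sensitivity -> power -> report.

The pipeline is deterministic given the seed, writes tidy TSV tables plus a
JSON summary, and applies a Bonferroni-adjusted significance threshold
(alpha_overall / bonferroni_k, e.g. 0.05/2 = 0.025 when two exposures are
tested against one outcome).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import clumping, estimators, power, sensitivity, summary_data
from .errors import ConfigurationError, PipelineError

logger = logging.getLogger(__name__)

DEFAULT_METHODS = ("ivw_fixed", "ivw_random", "weighted_median", "egger_slope")

ESTIMATES_COLUMNS = (
    "exposure", "outcome", "method", "n_snps", "beta", "se",
    "ci_low", "ci_high", "pval", "significant",
)


@dataclass
class AnalysisConfig:
    """Settings for one two-sample MR analysis run."""

    exposure_path: str
    outcome_path: str
    out_dir: str
    ld_path: str | None = None
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    r2_threshold: float = clumping.DEFAULT_R2_THRESHOLD
    window_bp: int = clumping.DEFAULT_WINDOW_BP
    p_threshold: float = clumping.DEFAULT_P_THRESHOLD
    palindrome_eaf_limit: float = summary_data.DEFAULT_PALINDROME_EAF_LIMIT
    methods: tuple[str, ...] = DEFAULT_METHODS
    alpha_overall: float = 0.05
    bonferroni_k: int = 2
    n_boot: int = 1000
    seed: int = 0
    n_outcome: int | None = None  # for power; defaults to the table's max N
    power_target: float = 0.8
    plots: bool = False

    _COERCE = {
        "window_bp": int, "bonferroni_k": int, "n_boot": int, "seed": int,
        "n_outcome": int, "r2_threshold": float, "p_threshold": float,
        "palindrome_eaf_limit": float, "alpha_overall": float,
        "power_target": float, "plots": lambda v: v.lower() in ("1", "true", "yes"),
        "methods": lambda v: tuple(m.strip() for m in v.split(",") if m.strip()),
    }

    def __post_init__(self) -> None:
        if not self.methods:
            raise ConfigurationError("method list must be non-empty")
        if not 0 < self.alpha_overall < 1:
            raise ConfigurationError("alpha_overall must be in (0, 1)")
        if self.bonferroni_k < 1:
            raise ConfigurationError("bonferroni_k must be >= 1")

    @property
    def per_test_alpha(self) -> float:
        """Bonferroni-adjusted two-sided significance threshold."""
        return self.alpha_overall / self.bonferroni_k

    @classmethod
    def from_file(cls, path, **overrides) -> "AnalysisConfig":
        """Plain key=value config file; later CLI overrides win."""
        values: dict = {}
        valid = {f.name for f in dataclasses.fields(cls) if not f.name.startswith("_")}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigurationError(f"{path}:{lineno}: expected key=value, got {raw!r}")
            key, val = (part.strip() for part in line.split("=", 1))
            if key not in valid:
                raise ConfigurationError(f"{path}:{lineno}: unknown setting {key!r}")
            values[key] = cls._COERCE.get(key, str)(val)
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values)


@dataclass
class AnalysisResult:
    config: AnalysisConfig
    counts: dict[str, int]
    estimates: list[estimators.MrEstimate]
    significant: dict[str, bool]
    report: sensitivity.SensitivityReport
    power_summary: dict[str, float]
    written: list[str] = field(default_factory=list)


def _format_estimates_tsv(result: AnalysisResult) -> str:
    cfg = result.config
    lines = ["\t".join(ESTIMATES_COLUMNS)]
    for est in result.estimates:
        lines.append("\t".join([
            cfg.exposure_name, cfg.outcome_name, est.method, str(est.n_snps),
            f"{est.beta:.6g}", f"{est.se:.6g}", f"{est.ci_low:.6g}",
            f"{est.ci_high:.6g}", f"{est.pval:.4g}",
            str(result.significant[est.method]).lower(),
        ]))
    return "\n".join(lines) + "\n"


def _write_outputs(result: AnalysisResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)

    def emit(name: str, text: str) -> None:
        (out_dir / name).write_text(text)
        result.written.append(str(out_dir / name))

    emit("estimates.tsv", _format_estimates_tsv(result))
    emit("sensitivity.txt", sensitivity.format_report(result.report))

    loo = ["excluded\tbeta\tse\tci_low\tci_high\tpval\tn_snps"]
    for row in result.report.loo_table:
        e = row.estimate
        loo.append(f"{row.excluded_rsid}\t{e.beta:.6g}\t{e.se:.6g}"
                   f"\t{e.ci_low:.6g}\t{e.ci_high:.6g}\t{e.pval:.4g}\t{e.n_snps}")
    emit("leave_one_out.tsv", "\n".join(loo) + "\n")

    funnel = ["rsid\twald_beta\tinverse_se"]
    for frow in result.report.funnel_table:
        funnel.append(f"{frow.rsid}\t{frow.wald_beta:.6g}\t{frow.inv_se:.6g}")
    emit("funnel.tsv", "\n".join(funnel) + "\n")

    summary = {
        "counts": result.counts,
        "per_test_alpha": result.config.per_test_alpha,
        "estimates": [
            {**dataclasses.asdict(e), "significant": result.significant[e.method]}
            for e in result.estimates
        ],
        "heterogeneity": {
            "q_statistic": result.report.q_statistic,
            "q_df": result.report.q_df,
            "q_pval": result.report.q_pval,
        },
        "egger_intercept": {
            "estimate": result.report.egger_intercept,
            "se": result.report.egger_intercept_se,
            "pval": result.report.egger_intercept_pval,
        },
        "instrument_strength": {
            "r2_total": result.report.r2_total,
            "r2_method": result.report.r2_method,
            "f_min": min(result.report.f_stats.values()),
            "f_max": max(result.report.f_stats.values()),
            "weak_instruments": result.report.weak_instruments,
        },
        "power": result.power_summary,
        "seed": result.config.seed,
    }
    emit("summary.json", json.dumps(summary, indent=1, sort_keys=True) + "\n")


def run_analysis(config: AnalysisConfig) -> AnalysisResult:
    """Run the full MR analysis and write its artifacts to ``config.out_dir``.

    Raises :class:`~mrkit.errors.PipelineError` with stage-count diagnostics
    when fewer than 3 usable instruments survive harmonization.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("mrkit")
    root.addHandler(handler)
    try:
        return _run(config, out_dir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: AnalysisConfig, out_dir: Path) -> AnalysisResult:
    exposure = summary_data.read_summary_stats(config.exposure_path)
    outcome = summary_data.read_summary_stats(config.outcome_path)
    counts = {"exposure_read": len(exposure), "outcome_read": len(outcome)}
    logger.info("read %d exposure and %d outcome SNPs", len(exposure), len(outcome))

    if config.ld_path is not None:
        ld = clumping.read_ld_matrix(config.ld_path)
        exposure = clumping.clump(
            exposure, ld,
            r2_threshold=config.r2_threshold,
            window_bp=config.window_bp,
            p_threshold=config.p_threshold,
        )
    else:
        exposure = [s for s in exposure if s.pval <= config.p_threshold]
    counts["clumped"] = len(exposure)
    logger.info("%d instruments after clumping/significance filter", len(exposure))

    insts = summary_data.harmonize_pair(
        exposure, outcome, palindrome_eaf_limit=config.palindrome_eaf_limit
    )
    usable = summary_data.usable_instruments(insts)
    counts["harmonized"] = len(insts)
    counts["analyzed"] = len(usable)
    logger.info("%d harmonized, %d usable instruments", len(insts), len(usable))

    if len(usable) < 3:
        raise PipelineError(
            "fewer than 3 usable instruments after harmonization; stage counts: "
            f"{counts}"
        )

    estimates = estimators.estimate_all(
        usable, methods=config.methods, n_boot=config.n_boot,
        seed=config.seed, alpha=config.alpha_overall,
    )
    significant = {e.method: bool(e.pval < config.per_test_alpha) for e in estimates}

    n_exposure = max((s.n for s in exposure if s.n is not None), default=None)
    report = sensitivity.sensitivity_report(usable, n_exposure=n_exposure,
                                            alpha=config.alpha_overall)

    n_outcome = config.n_outcome
    if n_outcome is None:
        n_outcome = max((i for i in (s.n for s in outcome) if i is not None), default=None)
    power_summary: dict[str, float] = {}
    if n_outcome is not None and 0 < report.r2_total < 1:
        mde = power.min_detectable_effect(
            n_outcome, report.r2_total, config.alpha_overall, config.power_target
        )
        ivw_beta = next((e.beta for e in estimates if e.method == "ivw_fixed"), None)
        power_summary = {
            "n_outcome": n_outcome,
            "r2_exposure": report.r2_total,
            "alpha": config.alpha_overall,
            "power_target": config.power_target,
            "min_detectable_effect": mde,
        }
        if ivw_beta is not None:
            power_summary["power_at_ivw_estimate"] = power.mr_power(
                ivw_beta, n_outcome, report.r2_total, config.alpha_overall
            )

    result = AnalysisResult(
        config=config, counts=counts, estimates=estimates,
        significant=significant, report=report, power_summary=power_summary,
    )
    _write_outputs(result, out_dir)
    if config.plots:
        from . import plots

        result.written.extend(plots.render_all(usable, result, out_dir))
    logger.info("wrote %d artifacts to %s", len(result.written), out_dir)
    return result
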