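"""Heterogeneity and robustness diagnostics for an MR instrument set.

Covers Cochran's Q (heterogeneity of per-SNP Wald ratios around the pooled
IVW estimate), leave-one-out re-estimation, the funnel table (per-SNP
estimate against its precision), per-SNP instrument-strength F statistics,
and the total fraction of exposure variance explained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ConfigurationError, InsufficientInstrumentsError
from .estimators import MrEstimate, cochran_q_components, ivw, mr_egger, wald_ratio
from .summary_data import HarmonizedInstrument, SnpAssociation, usable_instruments

WEAK_F_THRESHOLD = 10.0

ALL_SNPS_LABEL = "(all)"


@dataclass
class LooRow:
    excluded_rsid: str  # ALL_SNPS_LABEL for the full-set row
    estimate: MrEstimate


@dataclass
class FunnelRow:
    rsid: str
    wald_beta: float
    inv_se: float


@dataclass
class InstrumentStrength:
    f_stats: dict[str, float]
    r2_per_snp: dict[str, float]
    r2_total: float
    weak: list[str]
    r2_method: str  # "eaf" or "f_approx"


@dataclass
class SensitivityReport:
    q_statistic: float
    q_df: int
    q_pval: float
    egger_intercept: float
    egger_intercept_se: float
    egger_intercept_pval: float
    loo_table: list[LooRow]
    funnel_table: list[FunnelRow]
    f_stats: dict[str, float]
    r2_total: float
    r2_method: str
    weak_instruments: list[str] = field(default_factory=list)


def cochran_q(insts: Sequence[HarmonizedInstrument]) -> tuple[float, int, float]:
    """Cochran's Q of the Wald ratios about the fixed-effect IVW estimate.

    Q = sum_k w_k (r_k - beta_IVW)^2 with w_k = (beta_X/sigma_Y)^2; under
    homogeneity Q ~ chi-square with k-1 degrees of freedom.
    """
    insts = usable_instruments(insts)
    k = len(insts)
    if k < 2:
        raise InsufficientInstrumentsError(f"Cochran's Q requires >= 2 instruments, got {k}")
    bx = np.array([i.beta_exposure for i in insts])
    by = np.array([i.beta_outcome for i in insts])
    sy = np.array([i.se_outcome for i in insts])
    q, _ = cochran_q_components(bx, by, sy)
    df = k - 1
    pval = float(stats.chi2.sf(q, df))
    return q, df, pval


def leave_one_out(
    insts: Sequence[HarmonizedInstrument], alpha: float = 0.05
) -> list[LooRow]:
    """Fixed-effect IVW re-estimated with each instrument removed in turn.

    The first row (labelled ``(all)``) is the full-set estimate; each
    following row is labelled by the excluded rsid.
    """
    insts = usable_instruments(insts)
    if len(insts) < 3:
        raise InsufficientInstrumentsError(
            f"leave-one-out requires >= 3 instruments, got {len(insts)}"
        )
    rows = [LooRow(ALL_SNPS_LABEL, ivw(insts, "fixed", alpha))]
    for i, inst in enumerate(insts):
        subset = insts[:i] + insts[i + 1:]
        rows.append(LooRow(inst.rsid, ivw(subset, "fixed", alpha)))
    return rows


def funnel_table(insts: Sequence[HarmonizedInstrument]) -> list[FunnelRow]:
    """Per-SNP (Wald beta, 1/Wald SE) pairs — the data behind a funnel plot."""
    insts = usable_instruments(insts)
    if not insts:
        raise InsufficientInstrumentsError("funnel table requires >= 1 instrument")
    rows = []
    for inst in insts:
        est = wald_ratio(inst)
        rows.append(FunnelRow(inst.rsid, est.beta, 1.0 / est.se))
    return rows


def instrument_strength(
    insts: Sequence[HarmonizedInstrument] | Sequence[SnpAssociation],
    n_exposure: int | None = None,
) -> InstrumentStrength:
    """Per-SNP F statistics and exposure variance explained.

    F = (beta_X/sigma_X)^2.  Per-SNP r² uses the standardized-trait
    approximation 2·eaf·(1-eaf)·beta_X² when every frequency is available,
    else falls back to F/(F + n - 2), which needs ``n_exposure`` (taken from
    the records' own n when not passed).  Instruments with F < 10 are
    flagged weak.
    """
    f_stats: dict[str, float] = {}
    r2: dict[str, float] = {}
    triples = []
    for item in insts:
        if isinstance(item, HarmonizedInstrument):
            if not item.usable:
                continue
            triples.append((item.rsid, item.beta_exposure, item.se_exposure,
                            item.eaf_exposure, None))
        else:
            triples.append((item.rsid, item.beta, item.se, item.eaf, item.n))
    if not triples:
        raise InsufficientInstrumentsError("no usable instruments")

    have_all_eaf = all(t[3] is not None for t in triples)
    for rsid, beta, se, eaf, n in triples:
        f = (beta / se) ** 2
        f_stats[rsid] = f
        if have_all_eaf:
            r2[rsid] = 2 * eaf * (1 - eaf) * beta ** 2
        else:
            n_eff = n_exposure if n_exposure is not None else n
            if n_eff is None:
                raise ConfigurationError(
                    f"{rsid}: eaf missing and no sample size available for the "
                    "F-based r² fallback; pass n_exposure"
                )
            r2[rsid] = f / (f + n_eff - 2)
    weak = [r for r, f in f_stats.items() if f < WEAK_F_THRESHOLD]
    return InstrumentStrength(
        f_stats=f_stats,
        r2_per_snp=r2,
        r2_total=float(sum(r2.values())),
        weak=weak,
        r2_method="eaf" if have_all_eaf else "f_approx",
    )


def sensitivity_report(
    insts: Sequence[HarmonizedInstrument],
    n_exposure: int | None = None,
    alpha: float = 0.05,
) -> SensitivityReport:
    """Assemble the full diagnostic bundle for a harmonized instrument set."""
    q, df, q_pval = cochran_q(insts)
    _, intercept = mr_egger(insts, alpha)
    strength = instrument_strength(insts, n_exposure)
    return SensitivityReport(
        q_statistic=q,
        q_df=df,
        q_pval=q_pval,
        egger_intercept=intercept.beta,
        egger_intercept_se=intercept.se,
        egger_intercept_pval=intercept.pval,
        loo_table=leave_one_out(insts, alpha),
        funnel_table=funnel_table(insts),
        f_stats=strength.f_stats,
        r2_total=strength.r2_total,
        r2_method=strength.r2_method,
        weak_instruments=strength.weak,
    )


def format_report(report: SensitivityReport) -> str:
    """Human-readable serialization with machine-readable table sections."""
    lines = [
        "# MR sensitivity report",
        "",
        "## Pleiotropy (MR-Egger intercept)",
        "intercept\tstandard_error\tp_value",
        f"{report.egger_intercept:.6g}\t{report.egger_intercept_se:.6g}"
        f"\t{report.egger_intercept_pval:.4g}",
        "",
        "## Heterogeneity (Cochran's Q, fixed-effect IVW)",
        "q_statistic\tq_df\tp_value",
        f"{report.q_statistic:.4f}\t{report.q_df}\t{report.q_pval:.4g}",
        "",
        f"## Instrument strength (r² via {report.r2_method})",
        f"r2_total\t{report.r2_total:.6g}",
        f"weak_instruments\t{','.join(report.weak_instruments) or 'none'}",
        "rsid\tf_statistic",
    ]
    for rsid, f in report.f_stats.items():
        lines.append(f"{rsid}\t{f:.2f}")
    lines += ["", "## Leave-one-out (fixed-effect IVW)",
              "excluded\tbeta\tse\tci_low\tci_high\tpval\tn_snps"]
    for row in report.loo_table:
        e = row.estimate
        lines.append(
            f"{row.excluded_rsid}\t{e.beta:.6g}\t{e.se:.6g}\t{e.ci_low:.6g}"
            f"\t{e.ci_high:.6g}\t{e.pval:.4g}\t{e.n_snps}"
        )
    lines += ["", "## Funnel", "rsid\twald_beta\tinverse_se"]
    for frow in report.funnel_table:
        lines.append(f"{frow.rsid}\t{frow.wald_beta:.6g}\t{frow.inv_se:.6g}")
    lines.append("")
    return "\n".join(lines)
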