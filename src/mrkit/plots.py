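"""Optional diagnostic plots (scatter, forest, leave-one-out, funnel).

Tables are the canonical pipeline outputs; these renderings are a
convenience behind ``--plots`` and need matplotlib (the ``plots`` extra).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

from .summary_data import HarmonizedInstrument


def _mpl():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def render_all(
    insts: Sequence[HarmonizedInstrument], result, out_dir
) -> list[str]:
    plt = _mpl()
    out_dir = Path(out_dir)
    written = []

    bx = [i.beta_exposure for i in insts]
    by = [i.beta_outcome for i in insts]
    sx = [i.se_exposure for i in insts]
    sy = [i.se_outcome for i in insts]

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(bx, by, xerr=sx, yerr=sy, fmt="o", ms=3, lw=0.8, alpha=0.7)
    for est in result.estimates:
        if est.method in ("ivw_fixed", "egger_slope"):
            xs = [min(bx + [0]), max(bx)]
            icpt = result.report.egger_intercept if est.method == "egger_slope" else 0.0
            ax.plot(xs, [icpt + est.beta * x for x in xs], label=est.method)
    ax.set_xlabel("SNP effect on exposure (SD)")
    ax.set_ylabel("SNP effect on outcome (SD)")
    ax.legend(fontsize=8)
    path = out_dir / "scatter.png"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(str(path))

    fig, ax = plt.subplots(figsize=(5, 0.5 + 0.4 * len(result.estimates)))
    ys = range(len(result.estimates))
    ax.errorbar(
        [e.beta for e in result.estimates], list(ys),
        xerr=[[e.beta - e.ci_low for e in result.estimates],
              [e.ci_high - e.beta for e in result.estimates]],
        fmt="s", capsize=3,
    )
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_yticks(list(ys), [e.method for e in result.estimates])
    ax.set_xlabel("causal estimate (SD/SD) with 95% CI")
    path = out_dir / "forest.png"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(str(path))

    loo = [r for r in result.report.loo_table if r.excluded_rsid != "(all)"]
    full = result.report.loo_table[0].estimate
    fig, ax = plt.subplots(figsize=(5, 0.5 + 0.18 * len(loo)))
    ax.errorbar(
        [r.estimate.beta for r in loo], range(len(loo)),
        xerr=[[r.estimate.beta - r.estimate.ci_low for r in loo],
              [r.estimate.ci_high - r.estimate.beta for r in loo]],
        fmt="o", ms=2.5, lw=0.8,
    )
    ax.axvline(full.beta, color="tab:red", lw=0.8)
    ax.set_yticks(range(len(loo)), [r.excluded_rsid for r in loo], fontsize=6)
    ax.set_xlabel("IVW estimate excluding each SNP")
    path = out_dir / "leave_one_out.png"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(str(path))

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter([r.wald_beta for r in result.report.funnel_table],
               [r.inv_se for r in result.report.funnel_table], s=12)
    ax.axvline(full.beta, color="tab:red", lw=0.8)
    ax.set_xlabel("per-SNP Wald ratio")
    ax.set_ylabel("1 / SE of Wald ratio")
    path = out_dir / "funnel.png"
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
    written.append(str(path))
    return written
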