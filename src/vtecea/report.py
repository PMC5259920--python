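"""Human-readable report bundle: results tables, tornado, CEAC, run log.

CSV files are the contract; the markdown report is a convenience rendering of
the same numbers. Every emitted figure is reproducible from the parameter
file, life table and seed recorded in the run log.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .analyses import BaseCaseResult, CeacResult, TornadoEntry, tornado_frame
from .parameters import ModelParameters, iter_params

__all__ = ["write_run_log", "write_base_case", "write_tornado", "write_psa", "render_report"]


def write_run_log(out_dir, p: ModelParameters, extra: dict | None = None) -> Path:
    """Record software version, seed, and parameter provenance for a run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = {
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "package_version": __version__,
        "seed": p.settings.seed,
        "assumed_parameters": [
            path for path, prm in iter_params(p) if prm.source == "assumption"
        ],
        "half_cycle_correction": p.settings.half_cycle_correction,
        "discount_rate": p.settings.discount_rate,
    }
    if extra:
        log.update(extra)
    path = out / "run_log.json"
    path.write_text(json.dumps(log, indent=2))
    return path


def write_base_case(out_dir, result: BaseCaseResult) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frame_path = out / "base_case.csv"
    result.to_frame().to_csv(frame_path)
    summary = {
        "vs_lmwh_vka_6m": _incremental_dict(result.vs_lmwh_vka_6m),
        "vs_lmwh_vka_18m": _incremental_dict(result.vs_lmwh_vka_18m),
    }
    json_path = out / "base_case.json"
    json_path.write_text(json.dumps(summary, indent=2))
    return [frame_path, json_path]


def _incremental_dict(inc) -> dict:
    return {
        "delta_cost": inc.delta_cost,
        "delta_qaly": inc.delta_qaly,
        "delta_ly": inc.delta_ly,
        "icer": inc.icer,
        "tag": inc.tag,
        "delta_cost_anticoagulant": inc.delta_cost_anticoagulant,
        "delta_cost_monitoring_admin": inc.delta_cost_monitoring_admin,
        "delta_cost_events": inc.delta_cost_events,
        "delta_events_per_1000": inc.delta_events_per_1000,
    }


def write_tornado(out_dir, entries: list[TornadoEntry], comparison: str) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    path = out / f"tornado_{comparison.replace('/', '_')}.csv"
    tornado_frame(entries).to_csv(path, index=False)
    return path


def write_psa(out_dir, ceac: CeacResult) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ceac_path = out / "ceac.csv"
    ceac.ceac_frame().to_csv(ceac_path, index=False)
    draws_path = out / "psa_draws.csv"
    ceac.draws.to_csv(draws_path, index=False)
    return [ceac_path, draws_path]


def render_report(
    out_dir,
    base: BaseCaseResult | None = None,
    tornado: list[TornadoEntry] | None = None,
    psa: CeacResult | None = None,
    scenarios: pd.DataFrame | None = None,
    aux_sensitivity: pd.DataFrame | None = None,
) -> Path:
    """Assemble a markdown report from whichever analyses were run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    lines = ["# Cost-effectiveness results", ""]
    if base is not None:
        lines += ["## Deterministic base case", "", base.to_frame().round(3).to_markdown(), ""]
        for label, inc in (
            ("apixaban 18 m vs LMWH/VKA 6 m", base.vs_lmwh_vka_6m),
            ("apixaban 18 m vs LMWH/VKA 18 m", base.vs_lmwh_vka_18m),
        ):
            icer = f"GBP {inc.icer:,.0f}/QALY" if inc.icer is not None else inc.tag
            lines.append(
                f"- {label}: dCost GBP {inc.delta_cost:,.0f}, dQALY {inc.delta_qaly:.3f}, "
                f"dLY {inc.delta_ly:.3f}, ICER {icer}"
            )
        lines.append("")
    if tornado:
        lines += ["## One-way sensitivity (top 15 by ICER spread)", ""]
        lines.append(tornado_frame(tornado).head(15).round(1).to_markdown(index=False))
        lines.append("")
    if psa is not None:
        lines += [
            "## Probabilistic sensitivity",
            "",
            f"{psa.n_draws} draws, seed {psa.seed}; probability apixaban is the most "
            f"cost-effective option at GBP 20,000/QALY: {psa.prob_apixaban_at_threshold:.1%}",
            "",
            psa.ceac_frame().iloc[::5].round(4).to_markdown(index=False),
            "",
        ]
    if scenarios is not None:
        lines += ["## Treatment-duration scenarios", "", scenarios.round(3).to_markdown(index=False), ""]
    if aux_sensitivity is not None:
        lines += [
            "## Sensitivity to auxiliary (non-published) inputs",
            "",
            aux_sensitivity.round(3).to_markdown(index=False),
            "",
        ]
    path = out / "report.md"
    path.write_text("\n".join(lines))
    return path
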