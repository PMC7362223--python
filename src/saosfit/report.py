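"""Machine-readable (JSON) and human-readable (Markdown) fit reports."""

from __future__ import annotations

import json
from os import PathLike
from pathlib import Path

import numpy as np

from .models import MaterialParameters
from .regression import ModelRanking, RegressionResult
from .scaling import CharacteristicTimes, SpreadingKinetics

__all__ = ["ranking_to_dict", "parameters_to_dict", "spreading_to_dict",
           "ranking_markdown", "parameters_markdown", "write_report"]


def ranking_to_dict(ranking: ModelRanking) -> dict:
    return {
        "selected": ranking.selected,
        "tie_tolerance": ranking.tie_tolerance,
        "entries": [
            {
                "model_or_class": e.model_or_class,
                "members": list(e.member_names),
                "adj_r2": e.adj_r2,
                "r2": e.r2,
                "residual_sd": e.residual_sd,
                "n_params": e.n_params,
            }
            for e in ranking.entries
        ],
        "failures": dict(ranking.failures),
    }


def parameters_to_dict(params: MaterialParameters) -> dict:
    return {
        "model": params.model_name,
        "physical": params.physical,
        "parameters": {
            sym: {"estimate": est, "stderr": se}
            for sym, (est, se) in params.values.items()
        },
    }


def regression_to_dict(res: RegressionResult) -> dict:
    return {
        "model": res.model_name,
        "terms": list(res.terms),
        "K": res.k.tolist(),
        "K_stderr": res.k_stderr.tolist(),
        "r2": res.r2,
        "adj_r2": res.adj_r2,
        "n_obs": res.n_obs,
        "residual_sd": res.residual_sd,
        "condition_number": res.condition_number,
    }


def spreading_to_dict(kin: SpreadingKinetics) -> dict:
    return {
        "A_mm": kin.A,
        "t0_s": kin.t0,
        "tau_s_s": kin.tau_s,
        "stderr": dict(kin.standard_errors),
        "rss": kin.fit_rss,
    }


def times_to_dict(times: CharacteristicTimes) -> dict:
    return {
        "tau1_s": times.tau1,
        "tau1_stderr": times.tau1_stderr,
        "tau2_s": times.tau2,
        "tau2_stderr": times.tau2_stderr,
    }


def _md_table(header: list[str], rows: list[list[str]]) -> str:
    lines = ["| " + " | ".join(header) + " |",
             "| " + " | ".join("---" for _ in header) + " |"]
    lines += ["| " + " | ".join(r) + " |" for r in rows]
    return "\n".join(lines)


def ranking_markdown(ranking: ModelRanking) -> str:
    rows = [
        [e.model_or_class, "/".join(e.member_names), f"{e.adj_r2:.4f}",
         f"{e.residual_sd:.4g}", str(e.n_params)]
        for e in ranking.entries
    ]
    table = _md_table(
        ["Model class", "Members", "Adjusted R²", "Residual SD (Pa)",
         "Elements"],
        rows,
    )
    return (f"## Model applicability\n\n{table}\n\n"
            f"Selected (parsimony within ±{ranking.tie_tolerance} adjusted "
            f"R²): **{ranking.selected}**\n")


def parameters_markdown(params: MaterialParameters) -> str:
    unit = {"E": "Pa", "eta": "Pa·s"}
    rows = []
    for sym, (est, se) in params.values.items():
        u = unit["eta"] if sym.startswith("eta") else unit["E"]
        se_txt = "—" if np.isnan(se) else f"{se:.4g}"
        rows.append([f"{sym} ({u})", f"{est:.6g}", se_txt])
    table = _md_table(["Parameter", "Estimate", "Std. error"], rows)
    flag = "" if params.physical else \
        "\n\n**Warning:** non-physical (negative) estimates — the model " \
        "likely does not describe this material."
    return f"## {params.model_name} parameters\n\n{table}{flag}\n"


def write_report(
    directory: str | PathLike,
    ranking: ModelRanking | None = None,
    parameters: list[MaterialParameters] | None = None,
    regressions: list[RegressionResult] | None = None,
    spreading: SpreadingKinetics | None = None,
) -> Path:
    """Write ``report.json`` and ``report.md`` into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    doc: dict = {}
    md_parts: list[str] = []
    if ranking is not None:
        doc["ranking"] = ranking_to_dict(ranking)
        md_parts.append(ranking_markdown(ranking))
    if regressions:
        doc["regressions"] = [regression_to_dict(r) for r in regressions]
    if parameters:
        doc["parameters"] = [parameters_to_dict(p) for p in parameters]
        md_parts += [parameters_markdown(p) for p in parameters]
    if spreading is not None:
        doc["spreading"] = spreading_to_dict(spreading)
        md_parts.append(
            "## Strut spreading\n\n"
            f"A = {spreading.A:.4g} mm, t0 = {spreading.t0:.4g} s, "
            f"tau_s = {spreading.tau_s:.4g} s (RSS {spreading.fit_rss:.3g})\n")
    (directory / "report.json").write_text(json.dumps(doc, indent=2))
    (directory / "report.md").write_text("\n".join(md_parts))
    return directory / "report.json"
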