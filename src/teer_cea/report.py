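"""Tabular and graphical report writers plus run manifests.

Every command writes a manifest (config hash, seed, command, package version,
timestamp) next to its outputs so any artifact can be regenerated from the
same configuration and seed. Currency columns in CSV reports are rounded to
whole CNY and QALYs to two decimals, matching conventional reporting
precision; the JSON companions keep full precision.
"""

from __future__ import annotations

import datetime
import hashlib
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .economics import (
    COMPARATOR,
    INTERVENTION,
    CEAResult,
    calibrate,
    evaluate,
    scenario_device_price,
    threshold_device_price,
)
from .parameters import ParameterSet, to_document
from .sensitivity import (
    DEFAULT_WTP_GRID,
    acceptability_at,
    ceac,
    ceac_crossover,
    one_way,
    run_psa,
)

#: published device prices (CNY) used in the regional scenario analysis
SCENARIO_DEVICE_PRICES = {
    "germany": 247_478.0,
    "us": 197_597.0,
    "japan": 179_504.0,
    "uk": 143_951.0,
}


def make_manifest(params: ParameterSet, command: str, seed: int | None = None) -> dict:
    config_bytes = yaml.safe_dump(to_document(params), sort_keys=True).encode()
    return {
        "command": command,
        "seed": seed,
        "config_sha256": hashlib.sha256(config_bytes).hexdigest(),
        "package_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }


def _write_manifest(manifest: dict, out_dir: Path, name: str) -> None:
    (out_dir / name).write_text(json.dumps(manifest, indent=2))


def _cea_row(label: str, device_cost, overall, lifetime_cost, lifetime_qaly,
             cea: CEAResult | None) -> dict:
    row = {
        "scenario": label,
        "device_cost_cny": device_cost,
        "overall_mitraclip_cost_cny": overall,
        "lifetime_cost_cny": round(lifetime_cost),
        "lifetime_qaly": round(lifetime_qaly, 2),
    }
    if cea is None:
        row.update({"incremental_cost_cny": None, "incremental_qaly": None,
                    "icer_cny_per_qaly": None, "icer_wtp_ratio": None})
    else:
        row.update({
            "incremental_cost_cny": round(cea.delta_cost),
            "incremental_qaly": round(cea.delta_qaly, 2),
            "icer_cny_per_qaly": "dominant" if cea.dominant
            else (round(cea.icer) if cea.icer is not None else "undefined"),
            "icer_wtp_ratio": round(cea.icer / cea.wtp, 1)
            if cea.icer is not None else None,
        })
    return row


def cmd_run(params: ParameterSet, out_dir: str | Path, seed: int | None = None) -> dict:
    """Base-case deterministic run: two-arm table (CSV) + full-precision JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outcome = evaluate(params)
    mc, omt = outcome.arms[INTERVENTION], outcome.arms[COMPARATOR]

    rows = [
        _cea_row("base_case_omt", None, None, omt.lifetime_cost, omt.lifetime_qaly, None),
        _cea_row("base_case_mitraclip", round(params.costs.device),
                 round(params.costs.one_time_total),
                 mc.lifetime_cost, mc.lifetime_qaly, outcome.cea),
    ]
    pd.DataFrame(rows).to_csv(out_dir / "base_case.csv", index=False)

    summary = {
        "wtp_cny_per_qaly": params.econ.wtp,
        "arms": {
            arm: {
                "lifetime_cost_cny": r.lifetime_cost,
                "lifetime_qaly": r.lifetime_qaly,
                "life_years": r.life_years,
                "hospitalizations": r.hospitalizations,
                "undiscounted_cost_cny": r.undiscounted_cost,
            }
            for arm, r in outcome.arms.items()
        },
        "incremental_cost_cny": outcome.cea.delta_cost,
        "incremental_qaly": outcome.cea.delta_qaly,
        "icer_cny_per_qaly": outcome.cea.icer,
        "icer_wtp_ratio": outcome.cea.icer_wtp_ratio,
        "nmb_cny": outcome.cea.nmb,
        "icer_undefined": outcome.cea.icer is None,
        "dominant": outcome.cea.dominant,
    }
    (out_dir / "base_case.json").write_text(json.dumps(summary, indent=2))
    _write_manifest(make_manifest(params, "run", seed), out_dir, "manifest_run.json")
    return summary


def cmd_scenario(params: ParameterSet, prices: dict[str, float] | None = None,
                 out_dir: str | Path = ".", seed: int | None = None) -> pd.DataFrame:
    """Device-price scenario table, including the threshold (cost-effective) price."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prices = dict(SCENARIO_DEVICE_PRICES) if prices is None else prices
    outcome = evaluate(params)
    base = (outcome.arms[INTERVENTION], outcome.arms[COMPARATOR])

    rows = [
        _cea_row("base_case", round(params.costs.device),
                 round(params.costs.one_time_total),
                 base[0].lifetime_cost, base[0].lifetime_qaly, outcome.cea)
    ]
    for label, price in prices.items():
        cea = scenario_device_price(base, params, price)
        shift = price - params.costs.device
        rows.append(_cea_row(
            f"scenario_{label}", round(price),
            round(params.costs.one_time_total + shift),
            base[0].lifetime_cost + shift, base[0].lifetime_qaly, cea,
        ))

    price_star = threshold_device_price(base, params)
    cea_star = scenario_device_price(base, params, max(price_star, 0.0))
    rows.append(_cea_row(
        "cost_effective_price", round(price_star),
        round(params.costs.one_time_total + price_star - params.costs.device),
        base[0].lifetime_cost + price_star - params.costs.device,
        base[0].lifetime_qaly, cea_star,
    ))

    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "scenarios.csv", index=False)
    _write_manifest(make_manifest(params, "scenario", seed), out_dir, "manifest_scenario.json")
    return df


def cmd_dsa(params: ParameterSet, out_dir: str | Path, seed: int | None = None,
            plot: bool = True) -> pd.DataFrame:
    """One-way sensitivity analysis: tornado table (CSV) and diagram (PNG)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = one_way(params)
    base_icer = evaluate(params).cea.icer
    df = pd.DataFrame(
        {
            "parameter": [e.name for e in entries],
            "low": [e.low for e in entries],
            "high": [e.high for e in entries],
            "icer_at_low": [e.icer_at_low for e in entries],
            "icer_at_high": [e.icer_at_high for e in entries],
            "swing": [e.swing for e in entries],
        }
    )
    df.to_csv(out_dir / "tornado.csv", index=False)

    if plot:
        shown = entries[::-1]
        fig, ax = plt.subplots(figsize=(8, 0.4 * len(shown) + 1.5))
        for i, e in enumerate(shown):
            lo, hi = sorted((e.icer_at_low, e.icer_at_high))
            ax.barh(i, hi - lo, left=lo, color="#4878d0")
        ax.axvline(base_icer, color="k", lw=1, label="base-case ICER")
        ax.set_yticks(range(len(shown)), [e.name for e in shown])
        ax.set_xlabel("ICER (CNY/QALY)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out_dir / "tornado.png", dpi=120)
        plt.close(fig)

    _write_manifest(make_manifest(params, "dsa", seed), out_dir, "manifest_dsa.json")
    return df


def cmd_psa(params: ParameterSet, n_iter: int, seed: int, out_dir: str | Path,
            plot: bool = True) -> dict:
    """Probabilistic sensitivity analysis: samples CSV, scatter, CEAC."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    samples = run_psa(params, n_iter=n_iter, seed=seed)
    wtp = params.econ.wtp

    df = pd.DataFrame(
        {
            "draw": [s.index for s in samples],
            "cost_mitraclip": [s.cost[INTERVENTION] for s in samples],
            "cost_omt": [s.cost[COMPARATOR] for s in samples],
            "qaly_mitraclip": [s.qaly[INTERVENTION] for s in samples],
            "qaly_omt": [s.qaly[COMPARATOR] for s in samples],
            "delta_cost": [s.delta_cost for s in samples],
            "delta_qaly": [s.delta_qaly for s in samples],
        }
    )
    df.to_csv(out_dir / "psa_samples.csv", index=False)

    curve = ceac(samples, DEFAULT_WTP_GRID)
    pd.DataFrame({"wtp": [p_.wtp for p_ in curve],
                  "acceptability": [p_.acceptability for p_ in curve]}
                 ).to_csv(out_dir / "ceac.csv", index=False)

    if plot:
        fig, ax = plt.subplots(figsize=(6, 5))
        ax.scatter(df["delta_qaly"], df["delta_cost"], s=4, alpha=0.3)
        grid = np.linspace(df["delta_qaly"].min(), df["delta_qaly"].max(), 10)
        ax.plot(grid, wtp * grid, "k-", lw=1, label=f"WTP = {wtp:,.0f} CNY/QALY")
        ax.set_xlabel("incremental QALY")
        ax.set_ylabel("incremental cost (CNY)")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out_dir / "psa_scatter.png", dpi=120)
        plt.close(fig)

        fig, ax = plt.subplots(figsize=(6, 4))
        w = [p_.wtp for p_ in curve]
        a = [p_.acceptability for p_ in curve]
        ax.plot(w, a, label="MitraClip")
        ax.plot(w, [1 - x for x in a], label="OMT")
        ax.axvline(wtp, color="k", lw=1, ls="--")
        ax.set_xlabel("WTP threshold (CNY/QALY)")
        ax.set_ylabel("probability cost-effective")
        ax.legend()
        fig.tight_layout()
        fig.savefig(out_dir / "ceac.png", dpi=120)
        plt.close(fig)

    summary = {
        "n_iter": n_iter,
        "seed": seed,
        "acceptability_at_wtp": acceptability_at(samples, wtp),
        "ceac_crossover_wtp": ceac_crossover(samples),
    }
    (out_dir / "psa_summary.json").write_text(json.dumps(summary, indent=2))
    _write_manifest(make_manifest(params, "psa", seed), out_dir, "manifest_psa.json")
    return summary


def cmd_calibrate(params: ParameterSet, targets: dict[str, float], free: list[str],
                  out_dir: str | Path, seed: int | None = None) -> dict:
    """Calibrate free parameters to targets; write fitted config + residual report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fitted, rep = calibrate(params, targets, free)
    (out_dir / "calibrated_config.yaml").write_text(
        yaml.safe_dump(to_document(fitted), sort_keys=False)
    )
    report = {
        "success": rep.success,
        "message": rep.message,
        "targets": rep.targets,
        "achieved": rep.achieved,
        "relative_residuals": rep.relative_residuals,
        "max_abs_relative_residual": rep.max_abs_relative_residual,
        "fitted": rep.fitted,
        "n_evaluations": rep.n_evaluations,
    }
    (out_dir / "calibration.json").write_text(json.dumps(report, indent=2))
    _write_manifest(make_manifest(params, "calibrate", seed), out_dir,
                    "manifest_calibrate.json")
    return report
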