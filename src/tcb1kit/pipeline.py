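"""End-to-end scenarios: simulate, score, and report.

A scenario is a serializable config (dict, or YAML/JSON on disk) naming one
of five analyses and its parameters; :func:`run_scenario` validates it,
runs the simulation and scoring with the given seed, and returns a report
holding both raw counts and derived statistics, so a run is reproducible
from its persisted config alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import barrier_stats, divergence_dating, expression_qpcr
from .cross_model import PlantGenotype
from .pollination_sim import (
    DEFAULT_ACCEPTANCE_BIAS,
    EarCount,
    ScreenConfig,
    estimate_leak_and_bias,
    simulate_mixed_pollination,
    simulate_open_pollinated_screen,
    simulate_reversion_experiment,
)

__all__ = ["SCENARIOS", "ConfigError", "run_scenario", "render_summary",
           "load_config", "classify_reversion_table"]


class ConfigError(ValueError):
    """Raised when a scenario config fails validation; lists field paths."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid scenario config: " + "; ".join(errors))


# scenario -> {field: (type(s), required)}
_SCHEMAS: dict[str, dict[str, tuple[tuple[type, ...], bool]]] = {
    "mixed_pollination": {
        "mix_weight": ((int, float), False),
        "leak": ((int, float), False),
        "n_kernels": ((int,), False),
        "bias": ((dict,), False),
        "test_haplotype": ((str,), False),
        "expression_level": ((int, float), False),
    },
    "screen": {
        "n_plants": ((int,), False),
        "kernels_per_ear": ((int,), False),
        "r": ((int, float), False),
        "leak": ((int, float), False),
        "knockout_fraction": ((int, float), False),
        "alpha": ((int, float), False),
    },
    "reversion": {
        "n_females": ((int,), False),
        "reversion_prob": ((int, float), False),
        "n_kernels": ((int,), False),
        "expression_model": ((list, tuple), False),
        "leak_band": ((list, tuple), False),
        "mix_weight": ((int, float), False),
    },
    "qpcr": {
        "ct_table": ((str,), True),
        "strengths": ((dict,), False),
        "threshold": ((int, float), False),
    },
    "divergence": {
        "fasta": ((str,), False),
        "n_diff": ((int,), False),
        "n_sites": ((int,), False),
        "mu": ((int, float), False),
        "splits": ((dict,), False),
    },
}

SCENARIOS = tuple(_SCHEMAS)


def _validate(config: dict) -> tuple[str, int, dict]:
    errors: list[str] = []
    if not isinstance(config, dict) or not config:
        raise ConfigError(["config: must be a non-empty mapping"])
    scenario = config.get("scenario")
    if scenario not in _SCHEMAS:
        raise ConfigError(
            [f"scenario: got {scenario!r}, expected one of {list(_SCHEMAS)}"]
        )
    seed = config.get("seed", 0)
    if not isinstance(seed, int):
        errors.append("seed: must be an integer")
    schema = _SCHEMAS[scenario]
    params = {k: v for k, v in config.items() if k not in ("scenario", "seed")}
    for key, value in params.items():
        if key not in schema:
            errors.append(f"{scenario}.{key}: unknown field")
        elif not isinstance(value, schema[key][0]):
            errors.append(
                f"{scenario}.{key}: expected "
                f"{'/'.join(t.__name__ for t in schema[key][0])}, "
                f"got {type(value).__name__}"
            )
    for key, (_, required) in schema.items():
        if required and key not in params:
            errors.append(f"{scenario}.{key}: required field missing")
    if errors:
        raise ConfigError(errors)
    return scenario, seed, params


def _ear_dict(ear: EarCount) -> dict:
    return asdict(ear)


def classify_reversion_table(df) -> list[dict]:
    """Classify every female of a reversion table into significance tiers."""
    out = []
    for row in df.itertuples(index=False):
        test = EarCount(f"{row.female_id}-test", row.test_purple,
                        row.test_yellow, 0, row.test_purple + row.test_yellow)
        ctrl = EarCount(f"{row.female_id}-ctrl", row.ctrl_purple,
                        row.ctrl_yellow, 0, row.ctrl_purple + row.ctrl_yellow)
        cls = barrier_stats.classify_ear(test, ctrl)
        out.append({
            "female_id": row.female_id,
            "reverted_truth": bool(row.reverted),
            "p_value": cls.p_value,
            "tier": cls.tier,
            "barrier_strength": cls.barrier_strength,
        })
    return out


def _run_mixed_pollination(seed: int, p: dict) -> dict:
    ears = simulate_mixed_pollination(
        test_female=PlantGenotype.homozygous(
            p.get("test_haplotype", "Tcb1-s"),
            expression_level=p.get("expression_level", 1.0),
        ),
        donor_a=PlantGenotype.homozygous("tcb1", r1="R1-sc"),
        donor_b=PlantGenotype.homozygous("Tcb1-s", r1="r1-r"),
        mix_weight=p.get("mix_weight", 0.5),
        n_kernels=p.get("n_kernels", 300),
        leak=p.get("leak", 0.03),
        seed=seed,
        acceptance_bias=p.get("bias", dict(DEFAULT_ACCEPTANCE_BIAS)),
    )
    cls = barrier_stats.classify_ear(ears["test"], ears["neutral"])
    est = estimate_leak_and_bias(ears["test"], ears["neutral"],
                                 p.get("mix_weight", 0.5))
    return {
        "ears": {k: _ear_dict(v) for k, v in ears.items()},
        "classification": {"p_value": cls.p_value, "tier": cls.tier,
                           "barrier_strength": cls.barrier_strength},
        "estimates": est,
    }


def _run_screen(seed: int, p: dict) -> dict:
    cfg = ScreenConfig(
        n_plants=p.get("n_plants", 6000),
        kernels_per_ear=p.get("kernels_per_ear", 300),
        r=p.get("r", 0.06),
        leak=p.get("leak", 0.0),
        knockout_fraction=p.get("knockout_fraction", 0.0),
        seed=seed,
    )
    ears = simulate_open_pollinated_screen(cfg)
    flagged = barrier_stats.flag_screen_outliers(
        ears, null_fraction=cfg.r / 2.0, alpha=p.get("alpha", 0.05)
    )
    truth_ko = ~flagged["barrier"]
    n_ko = int(truth_ko.sum())
    report = {
        "config": asdict(cfg),
        "n_ears": len(flagged),
        "n_knockout_true": n_ko,
        "n_flagged": int(flagged["flagged"].sum()),
        "mean_sugary_fraction_barrier":
            float(flagged.loc[flagged["barrier"], "sugary_fraction"].mean())
            if flagged["barrier"].any() else None,
        "mean_sugary_fraction_knockout":
            float(flagged.loc[truth_ko, "sugary_fraction"].mean())
            if n_ko else None,
        "sensitivity":
            float((flagged["flagged"] & truth_ko).sum() / n_ko) if n_ko else None,
        "false_flags": int((flagged["flagged"] & flagged["barrier"]).sum()),
    }
    return report


def _run_reversion(seed: int, p: dict) -> dict:
    df = simulate_reversion_experiment(
        n_females=p.get("n_females", 36),
        reversion_prob=p.get("reversion_prob", 0.18),
        expression_model=tuple(p.get("expression_model", (0.05, 0.6, 0.5))),
        n_kernels=p.get("n_kernels", 300),
        seed=seed,
        leak_band=tuple(p.get("leak_band", (0.0, 0.15))),
        mix_weight=p.get("mix_weight", 0.5),
    )
    rows = classify_reversion_table(df)
    tiers = {"strong": 0, "partial": 0, "none": 0}
    for r in rows:
        tiers[r["tier"]] += 1
    detected = [r for r in rows if r["tier"] != "none"]
    n_true = sum(r["reverted_truth"] for r in rows)
    return {
        "n_females": len(rows),
        "n_reverted_true": n_true,
        "tier_counts": tiers,
        "n_detected": len(detected),
        "true_positive": sum(r["reverted_truth"] for r in detected),
        "females": rows,
    }


def _run_qpcr(seed: int, p: dict) -> dict:
    ct = expression_qpcr.read_ct_table(p["ct_table"])
    summaries = expression_qpcr.summarize_table(ct)
    report: dict[str, Any] = {
        "lines": {
            s.line_name: {"relative_expression": s.relative_expression,
                          "sem": s.sem, "n_biological": s.n_biological}
            for s in summaries
        }
    }
    if "strengths" in p:
        report["association"] = expression_qpcr.expression_barrier_association(
            summaries, p["strengths"], threshold=p.get("threshold")
        )
    return report


def _run_divergence(seed: int, p: dict) -> dict:
    mu = p.get("mu", divergence_dating.DEFAULT_MU)
    splits = p.get("splits", dict(divergence_dating.DEFAULT_SPLITS))
    if "fasta" in p:
        res = divergence_dating.date_fasta_pair(p["fasta"], mu=mu, splits=splits)
    else:
        if "n_diff" not in p or "n_sites" not in p:
            raise ConfigError(
                ["divergence: needs either 'fasta' or both 'n_diff' and 'n_sites'"]
            )
        years = divergence_dating.divergence_time(p["n_diff"], p["n_sites"], mu)
        res = divergence_dating.DatingResult(
            divergence=p["n_diff"] / p["n_sites"], mu=mu, years=years,
            splits=splits,
            ordering=divergence_dating.place_against_splits(years, splits),
        )
    return {"divergence": res.divergence, "mu": res.mu, "years": res.years,
            "splits": res.splits, "ordering": res.ordering}


_RUNNERS = {
    "mixed_pollination": _run_mixed_pollination,
    "screen": _run_screen,
    "reversion": _run_reversion,
    "qpcr": _run_qpcr,
    "divergence": _run_divergence,
}


def run_scenario(config: dict, out_dir=None) -> dict:
    """Validate ``config``, run its scenario, and return the report.

    The report carries the scenario name, seed and echoed config so that a
    rerun from the persisted report's config reproduces it exactly.  If
    ``out_dir`` is given, ``report.json`` and ``summary.txt`` are written.
    """
    scenario, seed, params = _validate(config)
    result = _RUNNERS[scenario](seed, params)
    report = {"scenario": scenario, "seed": seed, "config": config,
              "result": result}
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(
            json.dumps(report, indent=2, default=float) + "\n"
        )
        (out / "summary.txt").write_text(render_summary(report))
    return report


def render_summary(report: dict) -> str:
    """Human-readable digest of a scenario report."""
    lines = [f"scenario: {report['scenario']} (seed {report['seed']})"]
    res = report["result"]
    s = report["scenario"]
    if s == "mixed_pollination":
        for name, ear in res["ears"].items():
            frac = ear["n_purple"] / ear["n_total"] if ear["n_total"] else float("nan")
            lines.append(
                f"  {name:8s} ear: {ear['n_purple']:5d} purple / "
                f"{ear['n_total']:5d} kernels ({100 * frac:.1f}% tcb1-sired)"
            )
        c = res["classification"]
        lines.append(
            f"  test vs neutral: p = {c['p_value']:.3g}, tier = {c['tier']}, "
            f"barrier strength = {c['barrier_strength']:.2f}"
        )
        e = res["estimates"]
        lines.append(
            f"  recovered leak = {e['leak']:.3f}, "
            f"bias tcb1 = {e['bias_tcb1']:.3f}"
        )
    elif s == "screen":
        lines.append(
            f"  {res['n_ears']} ears, {res['n_knockout_true']} true knockouts, "
            f"{res['n_flagged']} flagged "
            f"({res['false_flags']} false flags)"
        )
        if res["mean_sugary_fraction_barrier"] is not None:
            lines.append(
                "  mean sugary fraction (barrier ears): "
                f"{res['mean_sugary_fraction_barrier']:.4f}"
            )
        if res["mean_sugary_fraction_knockout"] is not None:
            lines.append(
                "  mean sugary fraction (knockout ears): "
                f"{res['mean_sugary_fraction_knockout']:.4f}"
            )
    elif s == "reversion":
        t = res["tier_counts"]
        lines.append(
            f"  {res['n_females']} females, {res['n_reverted_true']} truly "
            f"reverted; tiers strong={t['strong']} partial={t['partial']} "
            f"none={t['none']}"
        )
    elif s == "qpcr":
        for name, v in res["lines"].items():
            lines.append(
                f"  {name}: relative expression "
                f"{v['relative_expression']:.3g} +/- {v['sem']:.3g} (SEM)"
            )
        if "association" in res:
            a = res["association"]
            lines.append(
                f"  expression-barrier Spearman rho = {a['spearman_rho']:.3f}"
            )
    elif s == "divergence":
        lines.append(
            f"  divergence d = {res['divergence']:.4g}; "
            f"T = {res['years']:,.0f} years"
        )
        for name, rel in res["ordering"].items():
            lines.append(f"  vs {name} split ({res['splits'][name]:,.0f} yr): {rel}")
    return "\n".join(lines) + "\n"


def load_config(path) -> dict:
    """Load a scenario config from YAML or JSON."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)
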