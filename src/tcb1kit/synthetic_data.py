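"""Synthetic fixture generators with known ground truth.

Every consumer of this package (simulators, scoring statistics, qPCR
summaries, divergence dating) can be exercised on generated inputs whose
generating parameters are emitted alongside as a truth record, so pipeline
estimates can be checked for parameter recovery without any external data.

Determinism: each fixture draws from a pseudo-random stream derived from
``(seed, design)``, so adding a new design never perturbs the streams of
existing ones.  Generated TSVs embed their spec as a ``#`` header comment;
FASTA records carry it in the description line.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cross_model import PlantGenotype
from .pollination_sim import (
    DEFAULT_ACCEPTANCE_BIAS,
    ScreenConfig,
    ears_to_frame,
    simulate_mixed_pollination,
    simulate_open_pollinated_screen,
    simulate_reversion_experiment,
)

__all__ = [
    "DESIGNS",
    "FixtureSpec",
    "make_mix_fixture",
    "make_qpcr_fixture",
    "make_seqpair_fixture",
    "make_screen_fixture",
    "make_reversion_fixture",
    "make_fixture",
]

#: Stable per-design stream offsets; append only, never reorder.
DESIGNS: dict[str, int] = {
    "mixed_pollination": 1,
    "screen": 2,
    "reversion": 3,
    "qpcr": 4,
    "seqpair": 5,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Seed + design + per-design parameters for one fixture."""

    seed: int
    design: str
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.design not in DESIGNS:
            raise ValueError(
                f"unknown design {self.design!r}; expected one of {sorted(DESIGNS)}"
            )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng([self.seed, DESIGNS[self.design]])

    def stream_seed(self) -> int:
        """A derived integer seed for simulators that take one."""
        return int(self.rng().integers(0, 2**31 - 1))

    def header(self) -> str:
        return "# fixture-spec: " + json.dumps(
            {"seed": self.seed, "design": self.design, **self.parameters},
            sort_keys=True,
        )


def _write_truth(out_dir: Path, truth: dict) -> Path:
    path = out_dir / "truth.json"
    path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return path


def _write_tsv(df: pd.DataFrame, path: Path, spec: FixtureSpec) -> None:
    with open(path, "w") as fh:
        fh.write(spec.header() + "\n")
        df.to_csv(fh, sep="\t", index=False)


def make_mix_fixture(spec: FixtureSpec, out_dir) -> dict:
    """Three-receiver mixed-pollination ear counts + generating truth.

    Parameters (all optional): ``mix_weight`` (tcb1 donor fraction, default
    0.5), ``leak`` (default 0.03), ``n_kernels`` (default 300), ``bias``
    (acceptance bias map), ``test_haplotype`` (default "Tcb1-s").
    """
    p = spec.parameters
    mix_weight = p.get("mix_weight", 0.5)
    leak = p.get("leak", 0.03)
    n_kernels = p.get("n_kernels", 300)
    bias = p.get("bias", dict(DEFAULT_ACCEPTANCE_BIAS))
    test_hap = p.get("test_haplotype", "Tcb1-s")
    ears = simulate_mixed_pollination(
        test_female=PlantGenotype.homozygous(test_hap),
        donor_a=PlantGenotype.homozygous("tcb1", r1="R1-sc"),
        donor_b=PlantGenotype.homozygous("Tcb1-s", r1="r1-r"),
        mix_weight=mix_weight,
        n_kernels=n_kernels,
        leak=leak,
        seed=spec.stream_seed(),
        acceptance_bias=bias,
    )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_tsv(ears_to_frame(ears), out_dir / "ears.tsv", spec)
    truth = {
        "design": spec.design, "seed": spec.seed, "mix_weight": mix_weight,
        "leak": leak, "bias": bias, "n_kernels": n_kernels,
        "test_haplotype": test_hap,
    }
    _write_truth(out_dir, truth)
    return {"ears": ears, "truth": truth, "files": ["ears.tsv", "truth.json"]}


def make_qpcr_fixture(spec: FixtureSpec, out_dir) -> dict:
    """Ct table with planted per-line fold changes.

    Parameters: ``lines`` maps line name -> relative expression versus the
    reference gene (default emulates a strong line at 400 and a silenced one
    at 1); ``sigma`` is the per-technical-replicate Ct noise SD (default
    0.2); ``baseline_ct`` the reference-gene Ct (default 20).  Ct for the
    target is baseline - log2(expression) + noise, so at sigma=0 the
    comparative-Ct pipeline recovers each fold exactly.
    """
    p = spec.parameters
    lines: dict[str, float] = p.get("lines", {"Tcb1-s": 400.0, "W22": 1.0})
    sigma = p.get("sigma", 0.2)
    baseline = p.get("baseline_ct", 20.0)
    if sigma < 0:
        raise ValueError("Ct noise sigma must be nonnegative")
    if any(f <= 0 for f in lines.values()):
        raise ValueError("fold changes must be positive")
    rng = spec.rng()
    rows = []
    for line, fold in sorted(lines.items()):
        for gene, true_ct in (("target", baseline - math.log2(fold)),
                              ("reference", baseline)):
            for bio in range(1, 4):
                for tech in range(1, 4):
                    rows.append({
                        "sample_id": f"{line}-b{bio}-t{tech}",
                        "line_name": line, "gene": gene,
                        "biological_rep": bio, "technical_rep": tech,
                        "ct": true_ct + (rng.normal(0.0, sigma) if sigma else 0.0),
                    })
    df = pd.DataFrame(rows)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_tsv(df, out_dir / "ct_table.tsv", spec)
    truth = {"design": spec.design, "seed": spec.seed, "lines": lines,
             "sigma": sigma, "baseline_ct": baseline}
    _write_truth(out_dir, truth)
    return {"ct_table": df, "truth": truth,
            "files": ["ct_table.tsv", "truth.json"]}


def make_seqpair_fixture(spec: FixtureSpec, out_dir) -> dict:
    """A pre-aligned FASTA pair with exactly ``n_substitutions`` differences.

    Parameters: ``length`` (default 1296), ``n_substitutions`` (default 15),
    ``n_gap_columns`` (default 0) — gap columns are inserted into the second
    sequence and excluded from comparable sites by the counter.
    """
    p = spec.parameters
    length = p.get("length", 1296)
    n_sub = p.get("n_substitutions", 15)
    n_gaps = p.get("n_gap_columns", 0)
    if n_sub + n_gaps > length:
        raise ValueError("n_substitutions + gap columns exceed sequence length")
    rng = spec.rng()
    bases = np.array(list("ACGT"))
    seq_a = rng.choice(bases, size=length)
    seq_b = seq_a.copy()
    positions = rng.choice(length, size=n_sub + n_gaps, replace=False)
    sub_pos, gap_pos = positions[:n_sub], positions[n_sub:]
    for i in sub_pos:
        others = [b for b in "ACGT" if b != seq_a[i]]
        seq_b[i] = others[rng.integers(0, 3)]
    for i in gap_pos:
        seq_b[i] = "-"
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    desc = spec.header().lstrip("# ")
    fasta = out_dir / "pair.fasta"
    with open(fasta, "w") as fh:
        fh.write(f">seq_a {desc}\n{''.join(seq_a)}\n")
        fh.write(f">seq_b {desc}\n{''.join(seq_b)}\n")
    truth = {"design": spec.design, "seed": spec.seed, "length": length,
             "n_substitutions": int(n_sub), "n_gap_columns": int(n_gaps)}
    _write_truth(out_dir, truth)
    return {"seq_a": "".join(seq_a), "seq_b": "".join(seq_b), "truth": truth,
            "files": ["pair.fasta", "truth.json"]}


def make_screen_fixture(spec: FixtureSpec, out_dir) -> dict:
    """Open-pollinated screen ear table with hidden knockout ground truth."""
    p = spec.parameters
    cfg = ScreenConfig(
        n_plants=p.get("n_plants", 6000),
        kernels_per_ear=p.get("kernels_per_ear", 300),
        r=p.get("r", 0.06),
        leak=p.get("leak", 0.0),
        knockout_fraction=p.get("knockout_fraction", 0.0),
        seed=spec.stream_seed(),
    )
    ears = simulate_open_pollinated_screen(cfg)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_tsv(ears, out_dir / "screen_ears.tsv", spec)
    truth = {"design": spec.design, "seed": spec.seed,
             **{k: v for k, v in cfg.__dict__.items()}}
    _write_truth(out_dir, truth)
    return {"ears": ears, "truth": truth,
            "files": ["screen_ears.tsv", "truth.json"]}


def make_reversion_fixture(spec: FixtureSpec, out_dir) -> dict:
    """mop1 reversion experiment: paired ear counts with reversion truth."""
    p = spec.parameters
    df = simulate_reversion_experiment(
        n_females=p.get("n_females", 36),
        reversion_prob=p.get("reversion_prob", 0.18),
        expression_model=tuple(p.get("expression_model", (0.05, 0.6, 0.5))),
        n_kernels=p.get("n_kernels", 300),
        seed=spec.stream_seed(),
        leak_band=tuple(p.get("leak_band", (0.0, 0.15))),
        mix_weight=p.get("mix_weight", 0.5),
    )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _write_tsv(df, out_dir / "reversion_ears.tsv", spec)
    truth = {"design": spec.design, "seed": spec.seed,
             "reversion_prob": p.get("reversion_prob", 0.18),
             "n_females": p.get("n_females", 36),
             "n_reverted_true": int(df["reverted"].sum())}
    _write_truth(out_dir, truth)
    return {"table": df, "truth": truth,
            "files": ["reversion_ears.tsv", "truth.json"]}


_MAKERS = {
    "mixed_pollination": make_mix_fixture,
    "screen": make_screen_fixture,
    "reversion": make_reversion_fixture,
    "qpcr": make_qpcr_fixture,
    "seqpair": make_seqpair_fixture,
}


def make_fixture(spec: FixtureSpec, out_dir) -> dict:
    """Dispatch a :class:`FixtureSpec` to its generator."""
    return _MAKERS[spec.design](spec, out_dir)
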