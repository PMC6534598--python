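"""Stochastic simulators of the three *Tcb1* experimental designs.

Three designs are modeled:

1. **Mixed pollination with three receivers.** Pollen from two donors — a
   ``tcb1; R1-sc`` maize line siring purple kernels and a test/tester line
   siring yellow kernels — is mixed and applied to (a) a *Tcb1-s* tester ear
   verifying the male function, (b) the test ear whose female barrier is in
   question, and (c) a neutral ``tcb1`` ear reading out the functional pollen
   ratio in the mix.  A calibrated per-kernel acceptance bias (60% ``tcb1`` :
   40% ``Tcb1-s`` on a neutral ear) models the competitive disadvantage of
   teosinte-haplotype pollen.

2. **Open-pollinated mutagenesis screen.** A block of *Tcb1-s Su1 / tcb1
   su1* repulsion heterozygotes sharing one pollen cloud; barrier ears
   segregate sugary kernels at r/2 (~3%), barrier-less knockout ears at 25%.

3. **mop1 reversion test.** Silenced loss-of-function females crossed by a
   standard pollen mix; a fraction revert to above-threshold *PME38*
   expression and mount a partial barrier.

Kernel sires are independent multinomial draws: no silk-position or
pollen-depletion effects.  Acceptance bias multiplies the barrier rule —
bias models pollen competition, the barrier models rejection.  All
randomness flows through a seeded :class:`numpy.random.Generator`; a fixed
seed gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cross_model import (
    DEFAULT_LEAK,
    DEFAULT_R,
    Gamete,
    PlantGenotype,
    gamete_frequencies,
    pollen_acceptance,
)

__all__ = [
    "DEFAULT_ACCEPTANCE_BIAS",
    "EarCount",
    "PollenPool",
    "ScreenConfig",
    "simulate_mixed_pollination",
    "simulate_open_pollinated_screen",
    "simulate_reversion_experiment",
    "estimate_leak_and_bias",
    "ears_to_frame",
    "read_ear_table",
    "write_ear_table",
]

#: Relative per-kernel siring weight by pollen haplotype class on a neutral
#: ear: 60% tcb1 : 40% Tcb1-s for an equal mix.
DEFAULT_ACCEPTANCE_BIAS: dict[str, float] = {"tcb1": 0.6, "Tcb1-s": 0.4}


@dataclass(frozen=True)
class EarCount:
    """Kernel counts for one ear, split into donor-identifiable classes.

    ``n_purple`` counts kernels sired by *R1-sc* pollen, ``n_yellow`` those
    sired by *r1* pollen, ``n_sugary`` the *su1/su1* homozygotes.
    """

    ear_id: str
    n_purple: int
    n_yellow: int
    n_sugary: int
    n_total: int

    def __post_init__(self) -> None:
        counts = (self.n_purple, self.n_yellow, self.n_sugary, self.n_total)
        if any(c < 0 for c in counts):
            raise ValueError("kernel counts must be nonnegative")
        if self.n_purple + self.n_yellow != self.n_total:
            raise ValueError("purple + yellow must equal total kernels")
        if self.n_sugary > self.n_total:
            raise ValueError("sugary count exceeds total")


@dataclass
class PollenPool:
    """A weighted mix of pollen donors plus the per-class acceptance bias."""

    donors: list[tuple[PlantGenotype, float]]
    acceptance_bias: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ACCEPTANCE_BIAS)
    )

    def __post_init__(self) -> None:
        if not self.donors:
            raise ValueError("pollen pool needs at least one donor")
        if any(w <= 0 for _, w in self.donors):
            raise ValueError("mixing weights must be positive")
        if any(w <= 0 for w in self.acceptance_bias.values()):
            raise ValueError("bias weights must be positive")

    def gametes(self) -> list[tuple[int, Gamete, float]]:
        """(donor index, gamete, mix-weighted probability) triples."""
        total = sum(w for _, w in self.donors)
        out = []
        for i, (donor, w) in enumerate(self.donors):
            for g, p in gamete_frequencies(donor).items():
                out.append((i, g, p * w / total))
        return out


@dataclass
class ScreenConfig:
    """Configuration of the open-pollinated knockout screen.

    ``leak`` defaults to 0 — the 3% expectation for barrier ears assumes
    complete rejection of incompatible pollen.
    """

    n_plants: int = 6000
    kernels_per_ear: int = 300
    r: float = DEFAULT_R
    leak: float = 0.0
    knockout_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_plants <= 0 or self.kernels_per_ear <= 0:
            raise ValueError("n_plants and kernels_per_ear must be positive")
        if not 0.0 <= self.knockout_fraction <= 1.0:
            raise ValueError("knockout_fraction must be a probability")


def _bias_weight(gamete: Gamete, bias: Mapping[str, float]) -> float:
    """Per-kernel competition weight of a pollen grain.

    Exact haplotype names take precedence; otherwise grains fall back to the
    male-functional ("Tcb1-s") or null ("tcb1") class weight.
    """
    for h in gamete.haplotypes:
        if h.name in bias:
            return bias[h.name]
    return bias["Tcb1-s"] if gamete.male_functional else bias["tcb1"]


def _ovule_su1_probability(female: PlantGenotype) -> float:
    """Probability an ovule carries su1 (ovules are never barrier-selected)."""
    return sum(
        p for g, p in gamete_frequencies(female).items() if g.allele("su1") == "su1"
    )


def _sire_one_ear(
    ear_id: str,
    female: PlantGenotype,
    pool: PollenPool,
    n_kernels: int,
    leak: float,
    rng: np.random.Generator,
    threshold: float = 0.5,
) -> tuple[EarCount, np.ndarray]:
    """Draw kernel sires for one ear; returns counts + per-gamete-class tally."""
    entries = pool.gametes()
    weights = np.array(
        [
            p * _bias_weight(g, pool.acceptance_bias)
            * pollen_acceptance(female, g, leak, threshold)
            for _, g, p in entries
        ]
    )
    total = weights.sum()
    if total == 0.0:
        empty = EarCount(ear_id, 0, 0, 0, 0)
        return empty, np.zeros(len(entries), dtype=np.int64)
    counts = rng.multinomial(n_kernels, weights / total)
    n_purple = sum(
        int(c) for c, (_, g, _) in zip(counts, entries) if g.allele("r1") == "R1-sc"
    )
    # kernel is sugary iff the sire carried su1 and the ovule is su1
    n_su1_pollen = sum(
        int(c) for c, (_, g, _) in zip(counts, entries) if g.allele("su1") == "su1"
    )
    n_sugary = int(rng.binomial(n_su1_pollen, _ovule_su1_probability(female)))
    ear = EarCount(ear_id, n_purple, n_kernels - n_purple, n_sugary, n_kernels)
    return ear, counts


def simulate_mixed_pollination(
    test_female: PlantGenotype,
    donor_a: PlantGenotype,
    donor_b: PlantGenotype,
    mix_weight: float = 0.5,
    n_kernels: int = 300,
    leak: float = DEFAULT_LEAK,
    seed: int = 0,
    acceptance_bias: Mapping[str, float] | None = None,
    tester_female: PlantGenotype | None = None,
    neutral_female: PlantGenotype | None = None,
) -> dict[str, EarCount]:
    """Run the three-receiver mixed pollination design.

    ``mix_weight`` is the fraction of donor A pollen in the mix.  Donor A is
    conventionally the ``tcb1; R1-sc`` line (purple kernels) and donor B the
    test/tester line carrying ``r1`` (yellow kernels); the two donors must be
    distinguishable at *r1* or the design is unscoreable.

    Returns ears keyed ``"tester"`` (*Tcb1-s* receiver), ``"test"`` (the
    female under test) and ``"neutral"`` (``tcb1`` receiver).
    """
    if not 0.0 < mix_weight < 1.0:
        raise ValueError("mix_weight must be strictly between 0 and 1")
    if n_kernels <= 0:
        raise ValueError("n_kernels must be positive")
    if set(donor_a.r1_genotype) & set(donor_b.r1_genotype):
        raise ValueError(
            "donors share an r1 kernel-color allele; progeny cannot be "
            "assigned to donors"
        )
    pool = PollenPool(
        donors=[(donor_a, mix_weight), (donor_b, 1.0 - mix_weight)],
        acceptance_bias=dict(acceptance_bias or DEFAULT_ACCEPTANCE_BIAS),
    )
    tester = tester_female or PlantGenotype.homozygous("Tcb1-s")
    neutral = neutral_female or PlantGenotype.homozygous("tcb1")
    rng = np.random.default_rng(seed)
    ears: dict[str, EarCount] = {}
    for name, female in (("tester", tester), ("test", test_female),
                         ("neutral", neutral)):
        ears[name], _ = _sire_one_ear(name, female, pool, n_kernels, leak, rng)
    return ears


def simulate_open_pollinated_screen(cfg: ScreenConfig) -> pd.DataFrame:
    """Simulate the open-pollinated knockout screen.

    Every plant is a *Tcb1-s Su1 / tcb1 su1* repulsion heterozygote; a
    fraction ``knockout_fraction`` of ears has lost the female barrier
    (knockouts keep the male gene, so the shared pollen cloud is unchanged).
    Kernels per ear are drawn from the accepted pollen distribution; the
    hidden ground-truth barrier status is emitted for scoring.

    Returns a DataFrame with columns ``ear_id, n_kernels, n_sugary,
    sugary_fraction, barrier`` (truth) and the seed recorded in ``attrs``.
    """
    rng = np.random.default_rng(cfg.seed)
    parent = PlantGenotype.repulsion_het(r=cfg.r)
    pollen = gamete_frequencies(parent)
    ovule_su1 = _ovule_su1_probability(parent)

    def sugary_prob(barrier: bool) -> float:
        leak = cfg.leak if barrier else 1.0
        w = {g: p * (1.0 if g.male_functional else leak) for g, p in pollen.items()}
        total = sum(w.values())
        p_su1 = sum(p for g, p in w.items() if g.allele("su1") == "su1") / total
        return p_su1 * ovule_su1

    barrier_truth = rng.random(cfg.n_plants) >= cfg.knockout_fraction
    p_by_status = {True: sugary_prob(True), False: sugary_prob(False)}
    probs = np.where(barrier_truth, p_by_status[True], p_by_status[False])
    n_sugary = rng.binomial(cfg.kernels_per_ear, probs)
    df = pd.DataFrame(
        {
            "ear_id": [f"ear{i:05d}" for i in range(cfg.n_plants)],
            "n_kernels": cfg.kernels_per_ear,
            "n_sugary": n_sugary,
            "sugary_fraction": n_sugary / cfg.kernels_per_ear,
            "barrier": barrier_truth,
        }
    )
    df.attrs["seed"] = cfg.seed
    df.attrs["config"] = asdict(cfg)
    return df


def simulate_reversion_experiment(
    n_females: int = 36,
    reversion_prob: float = 0.18,
    expression_model: tuple[float, float, float] = (0.05, 0.6, 0.5),
    n_kernels: int = 300,
    seed: int = 0,
    leak_band: tuple[float, float] = (0.0, 0.15),
    mix_weight: float = 0.5,
    acceptance_bias: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Simulate the *mop1* reversion test on silenced loss-of-function females.

    Each female is an epigenetically silenced *tcb1-f* homozygote in a *mop1*
    background.  With probability ``reversion_prob`` her *PME38* expression
    reverts from the silenced base level to the reverted level of
    ``expression_model = (base, reverted, threshold)``; a reverted female
    mounts a partial barrier whose leak is drawn uniformly from
    ``leak_band``.  Non-reverted females stay below threshold and behave as
    barrier-less ``tcb1``.

    Each female gets a test ear (herself) and a control ``tcb1`` ear, both
    pollinated by the same ``tcb1; R1-sc`` + ``Tcb1-s; r1`` mix.  Returns one
    row per female with both ears' counts and the ground truth.
    """
    if not 0.0 <= reversion_prob <= 1.0:
        raise ValueError("reversion_prob must be a probability")
    base, reverted_level, threshold = expression_model
    rng = np.random.default_rng(seed)
    bias = dict(acceptance_bias or DEFAULT_ACCEPTANCE_BIAS)
    donor_a = PlantGenotype.homozygous("tcb1", r1="R1-sc")  # purple sire
    donor_b = PlantGenotype.homozygous("Tcb1-s", r1="r1-r")  # yellow sire
    pool = PollenPool(donors=[(donor_a, mix_weight), (donor_b, 1.0 - mix_weight)],
                      acceptance_bias=bias)
    control_female = PlantGenotype.homozygous("tcb1")
    rows = []
    for i in range(n_females):
        reverted = bool(rng.random() < reversion_prob)
        level = reverted_level if reverted else base
        leak = float(rng.uniform(*leak_band)) if reverted else 1.0
        female = PlantGenotype.homozygous("Tcb1-f", expression_level=level)
        test_ear, _ = _sire_one_ear(f"f{i:03d}-test", female, pool,
                                    n_kernels, leak, rng, threshold)
        ctrl_ear, _ = _sire_one_ear(f"f{i:03d}-ctrl", control_female, pool,
                                    n_kernels, 1.0, rng)
        rows.append({
            "female_id": f"f{i:03d}",
            "reverted": reverted,
            "expression_level": level,
            "leak": leak if reverted else np.nan,
            "test_purple": test_ear.n_purple, "test_yellow": test_ear.n_yellow,
            "ctrl_purple": ctrl_ear.n_purple, "ctrl_yellow": ctrl_ear.n_yellow,
            "n_kernels": n_kernels,
        })
    df = pd.DataFrame(rows)
    df.attrs["seed"] = seed
    df.attrs["threshold"] = threshold
    return df


def estimate_leak_and_bias(
    test: EarCount,
    neutral: EarCount,
    mix_weight: float = 0.5,
) -> dict[str, float]:
    """Method-of-moments recovery of leak and acceptance bias from two ears.

    On the neutral ear the purple:yellow odds equal
    ``(mix_weight * bias_tcb1) / ((1-mix_weight) * bias_Tcb1s)``; on a
    barrier-active test ear the same odds are multiplied by the leak.  A
    Haldane 0.5 correction is applied to zero cells.
    """
    def odds(ear: EarCount) -> float:
        p, y = ear.n_purple, ear.n_yellow
        if p == 0 or y == 0:
            p, y = p + 0.5, y + 0.5
        return p / y

    odds_neutral = odds(neutral)
    bias_ratio = odds_neutral * (1.0 - mix_weight) / mix_weight
    return {
        "bias_tcb1": bias_ratio / (1.0 + bias_ratio),
        "bias_Tcb1-s": 1.0 / (1.0 + bias_ratio),
        "leak": odds(test) / odds_neutral,
    }


# ---------------------------------------------------------------------------
# Ear-count table I/O

_EAR_COLUMNS = ["ear_id", "receiver_class", "n_purple", "n_yellow",
                "n_sugary", "n_total"]


def ears_to_frame(ears: Mapping[str, EarCount]) -> pd.DataFrame:
    rows = [
        {"ear_id": e.ear_id, "receiver_class": name, "n_purple": e.n_purple,
         "n_yellow": e.n_yellow, "n_sugary": e.n_sugary, "n_total": e.n_total}
        for name, e in ears.items()
    ]
    return pd.DataFrame(rows, columns=_EAR_COLUMNS)


def write_ear_table(ears: Mapping[str, EarCount], path) -> None:
    ears_to_frame(ears).to_csv(path, sep="\t", index=False)


def read_ear_table(path) -> dict[str, EarCount]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out: dict[str, EarCount] = {}
    for row in df.itertuples(index=False):
        out[str(row.receiver_class)] = EarCount(
            str(row.ear_id), int(row.n_purple), int(row.n_yellow),
            int(row.n_sugary), int(row.n_total),
        )
    return out
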