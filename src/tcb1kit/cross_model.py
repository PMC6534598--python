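"""Deterministic genetic model of the maize/teosinte *Tcb1* locus.

The *Tcb1* locus on the short arm of chromosome 4 carries two tightly linked
genes: a pistil-expressed female barrier gene (*Tcb1-f*, a PME38 homolog) and
a pollen-expressed male gene (*Tcb1-m*).  Four haplotypes occur in the field:

========  ===============  =================
name      male gene        female gene
========  ===============  =================
Tcb1-s    functional       functional
Tcb1-m    functional       absent/silent
Tcb1-f    absent/silent    functional
tcb1      absent           absent
========  ===============  =================

A silk whose genotype carries an expressed female barrier gene rejects pollen
that lacks a functional male gene.  The barrier acts on the haploid pollen
grain (gametophytic incompatibility): a diploid donor heterozygous for
``Tcb1-s`` and ``tcb1`` sheds a 50:50 mix of compatible and incompatible
grains.  Heterodiploid pollen, which carries two haplotypes through a
chromosome-4 duplication, is accepted whenever *any* of its haplotypes is
male-functional (the male function is dominant over the null).

Ovules are never subject to barrier selection; only pollen competes.  This is
a stated model assumption: the barrier acts in the silk on growing pollen
tubes, before fertilization.

The locus is linked to the endosperm marker *sugary1* (*su1*, ~6 cM away),
which lets pollen-pool composition be read off an ear: kernels are sugary only
when homozygous *su1/su1*.  The unlinked color marker *R1-sc* (purple kernels)
versus *r1* (yellow/white) distinguishes pollen donors in mixed pollinations
and assorts independently of chromosome 4.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "HAPLOTYPE_NAMES",
    "Haplotype",
    "Gamete",
    "PlantGenotype",
    "haplotype",
    "gamete_frequencies",
    "pollen_acceptance",
    "barrier_active",
    "expected_marker_segregation",
    "read_genotype_table",
]

#: (male_functional, female_functional) per haplotype name.
_HAPLOTYPE_FLAGS: dict[str, tuple[bool, bool]] = {
    "Tcb1-s": (True, True),
    "Tcb1-m": (True, False),
    "Tcb1-f": (False, True),
    "tcb1": (False, False),
}

HAPLOTYPE_NAMES = tuple(_HAPLOTYPE_FLAGS)

#: Default recombination fraction between the Tcb1 locus and su1 (~6 cM).
DEFAULT_R = 0.06

#: Default residual siring rate of incompatible pollen on a barrier silk,
#: inside the observed 0-7% band.
DEFAULT_LEAK = 0.03


@dataclass(frozen=True)
class Haplotype:
    """One chromosome-4 haplotype at the *Tcb1* locus.

    ``expression_level`` is the silk transcript level of the female gene,
    relative to a reference gene (tubulin); it only matters when
    ``female_functional`` is true.  Silenced lineages (*tcb1-f::sl1/sl2*) and
    *mop1* revertants are represented as expression changes on a
    female-functional allele, with no sequence change.
    """

    name: str
    male_functional: bool
    female_functional: bool
    expression_level: float = 1.0

    def __post_init__(self) -> None:
        if self.name not in _HAPLOTYPE_FLAGS:
            raise ValueError(
                f"unknown haplotype {self.name!r}; expected one of {HAPLOTYPE_NAMES}"
            )
        if self.expression_level < 0:
            raise ValueError("expression_level must be nonnegative")


def haplotype(name: str, expression_level: float = 1.0) -> Haplotype:
    """Build a :class:`Haplotype` with the canonical functionality flags."""
    try:
        male, female = _HAPLOTYPE_FLAGS[name]
    except KeyError:
        raise ValueError(
            f"unknown haplotype {name!r}; expected one of {HAPLOTYPE_NAMES}"
        ) from None
    return Haplotype(name, male, female, expression_level)


@dataclass(frozen=True)
class Gamete:
    """A pollen grain (or ovule): haplotype(s) plus linked-marker alleles.

    ``haplotypes`` has size 1 for normal haploid pollen and size 2 for
    heterodiploid pollen produced by a chromosome-4 duplication carrier.
    ``markers`` maps a marker locus (``"su1"``, ``"r1"``) to the allele
    carried (``"Su1"``/``"su1"``, ``"R1-sc"``/``"r1-r"``).
    """

    haplotypes: tuple[Haplotype, ...]
    markers: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not 1 <= len(self.haplotypes) <= 2:
            raise ValueError("a gamete carries one or two Tcb1 haplotypes")

    @property
    def marker_map(self) -> dict[str, str]:
        return dict(self.markers)

    def allele(self, locus: str) -> str | None:
        return self.marker_map.get(locus)

    @property
    def male_functional(self) -> bool:
        return any(h.male_functional for h in self.haplotypes)


def _gamete(haps: Iterable[Haplotype], **markers: str) -> Gamete:
    return Gamete(tuple(haps), tuple(sorted(markers.items())))


@dataclass(frozen=True)
class PlantGenotype:
    """A diploid plant: two phased (haplotype, su1 allele) chromosomes.

    ``phase`` is ``"repulsion"`` when the functional *Tcb1* haplotype is in
    cis with ``Su1`` (so only recombinant gametes combine the barrier
    haplotype with ``su1``), ``"coupling"`` otherwise.  ``r`` is the
    recombination fraction between *tcb1* and *su1*.  The *r1* color locus is
    on a different chromosome and assorts independently.
    """

    chrom4: tuple[tuple[Haplotype, str], tuple[Haplotype, str]]
    r1_genotype: tuple[str, str] = ("r1-r", "r1-r")
    r: float = DEFAULT_R
    mop1: str = "wildtype"
    duplication_transmission: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.r <= 0.5:
            raise ValueError(f"recombination fraction r={self.r} outside [0, 0.5]")
        for _, su1_allele in self.chrom4:
            if su1_allele not in ("Su1", "su1"):
                raise ValueError(f"bad su1 allele {su1_allele!r}")
        for a in self.r1_genotype:
            if a not in ("R1-sc", "r1-r"):
                raise ValueError(f"bad r1 allele {a!r}")
        if self.mop1 not in ("wildtype", "mutant"):
            raise ValueError(f"bad mop1 state {self.mop1!r}")

    @property
    def haplotypes(self) -> tuple[Haplotype, Haplotype]:
        return self.chrom4[0][0], self.chrom4[1][0]

    @property
    def phase(self) -> str:
        """Repulsion iff a female- or male-functional haplotype sits with Su1."""
        for hap, su1_allele in self.chrom4:
            if (hap.male_functional or hap.female_functional) and su1_allele == "Su1":
                return "repulsion"
        return "coupling"

    @classmethod
    def homozygous(cls, name: str, expression_level: float = 1.0,
                   su1: str = "Su1", r1: str = "r1-r", **kw) -> "PlantGenotype":
        h = haplotype(name, expression_level)
        return cls(chrom4=((h, su1), (h, su1)), r1_genotype=(r1, r1), **kw)

    @classmethod
    def repulsion_het(cls, functional: str = "Tcb1-s", expression_level: float = 1.0,
                      r: float = DEFAULT_R, **kw) -> "PlantGenotype":
        """The mutagenesis-screen genotype: functional Su1 / tcb1 su1."""
        return cls(
            chrom4=((haplotype(functional, expression_level), "Su1"),
                    (haplotype("tcb1"), "su1")),
            r=r, **kw,
        )


def gamete_frequencies(parent: PlantGenotype) -> dict[Gamete, float]:
    """Gamete distribution of a diploid parent under two-locus recombination.

    For chromosome 4 the parental (non-recombinant) classes each occur with
    probability (1-r)/2 and the recombinant classes with r/2.  The unlinked
    *r1* locus assorts independently, so each chromosome-4 class is split
    evenly across the parent's *r1* alleles.

    Returns a dict mapping :class:`Gamete` to probability; probabilities sum
    to 1 for every valid genotype and every r.
    """
    (h1, m1), (h2, m2) = parent.chrom4
    chrom4_classes = [
        ((h1, m1), (1.0 - parent.r) / 2.0),
        ((h2, m2), (1.0 - parent.r) / 2.0),
        ((h1, m2), parent.r / 2.0),
        ((h2, m1), parent.r / 2.0),
    ]
    r1_alleles = parent.r1_genotype
    out: dict[Gamete, float] = {}
    for (hap, su1_allele), p4 in chrom4_classes:
        if p4 == 0.0:
            continue
        for r1_allele in r1_alleles:
            g = _gamete([hap], su1=su1_allele, r1=r1_allele)
            out[g] = out.get(g, 0.0) + p4 / len(r1_alleles)
    return out


def barrier_active(female: PlantGenotype, threshold: float = 0.5) -> bool:
    """Whether the silk mounts a pollen-rejection barrier.

    True iff some allele is female-functional with silk expression at or
    above ``threshold``.  Silenced lineages whose *PME38* transcript falls
    below the threshold produce no detectable barrier even though the coding
    sequence is intact.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return any(
        h.female_functional and h.expression_level >= threshold
        for h in female.haplotypes
    )


def pollen_acceptance(
    female: PlantGenotype,
    pollen: Gamete,
    leak: float = DEFAULT_LEAK,
    threshold: float = 0.5,
) -> float:
    """Probability the silk accepts a pollen grain.

    If the female barrier is inactive every grain is accepted.  If active,
    grains carrying any male-functional haplotype are accepted with
    probability 1 (heterodiploid rescue: the male function is dominant), and
    incompatible grains sire kernels only at the residual ``leak`` rate.
    """
    if not 0.0 <= leak <= 1.0:
        raise ValueError("leak must be a probability")
    if not barrier_active(female, threshold):
        return 1.0
    if pollen.male_functional:
        return 1.0
    return leak


def expected_marker_segregation(barrier: bool, r: float) -> float:
    """Expected su1/su1 kernel fraction in the open-pollinated screen block.

    In a block of *Tcb1-s Su1 / tcb1 su1* repulsion heterozygotes the pollen
    cloud carries ``su1`` with probability 1/2.  A barrier ear accepts only
    the *Tcb1-s* pollen class, of which the recombinant fraction r carries
    ``su1``; the ovule is ``su1`` with probability 1/2 (ovules unselected),
    giving r/2 sugary kernels.  Without a barrier the fraction is 1/4
    regardless of r.
    """
    if not 0.0 <= r <= 0.5:
        raise ValueError(f"recombination fraction r={r} outside [0, 0.5]")
    return r / 2.0 if barrier else 0.25


# ---------------------------------------------------------------------------
# Genotype table I/O

_GENOTYPE_COLUMNS = [
    "plant_id", "hap1", "hap2", "su1_1", "su1_2", "r", "mop1",
    "expression_1", "expression_2",
]


def read_genotype_table(path) -> dict[str, PlantGenotype]:
    """Read a TSV of plant genotypes (one row per plant).

    Columns: plant_id, hap1, hap2 (haplotype names validated bit-exactly
    against the four-name vocabulary), su1_1, su1_2 (phased su1 alleles),
    r, mop1, expression_1, expression_2.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(_GENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"genotype table missing columns: {sorted(missing)}")
    plants: dict[str, PlantGenotype] = {}
    for row in df.itertuples(index=False):
        plants[str(row.plant_id)] = PlantGenotype(
            chrom4=(
                (haplotype(row.hap1, float(row.expression_1)), row.su1_1),
                (haplotype(row.hap2, float(row.expression_2)), row.su1_2),
            ),
            r=float(row.r),
            mop1=row.mop1,
        )
    return plants


def write_genotype_table(plants: Mapping[str, PlantGenotype], path) -> None:
    rows = []
    for pid, p in plants.items():
        (h1, m1), (h2, m2) = p.chrom4
        rows.append({
            "plant_id": pid, "hap1": h1.name, "hap2": h2.name,
            "su1_1": m1, "su1_2": m2, "r": p.r, "mop1": p.mop1,
            "expression_1": h1.expression_level, "expression_2": h2.expression_level,
        })
    pd.DataFrame(rows, columns=_GENOTYPE_COLUMNS).to_csv(path, sep="\t", index=False)
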