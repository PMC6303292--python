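"""Synthetic genotype tables with planted, fully known structure.

The generator plants three haplotypic families (Y3_A/Y3_B/Y3_C) whose
founder haplotypes honour the diagnostic band rules, a configurable
inventory of shared within-family variants with exact multiplicities, a
per-population composition plan, and seeded singleton haplotypes (one
extra Poisson number of stepwise-mutation steps away from the family
founder). Every generated row is recorded in a ground-truth ledger
(true family, source haplotype, mutational distance to the founder), so
classification, census, diversity and rho estimates can be checked
against known truth.

The ``paper_like_preset`` emulates the structure reported for the real
intercontinental zebu survey: 22 populations across Asia, Africa and
the Americas, 248 males, 47 distinct haplotypes of which 29 singletons,
family sample counts (186, 24, 38) and haplotype richness (26, 12, 9),
a modal haplotype carried by 55 males, a South-Asian/Yemeni Y3_C
central haplotype carried by 23, Y3_B confined to West Africa, and 19
microsatellite alleles across the six loci.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .haplotypes import HaplotypeTable, table_from_dataframe
from .panel import MarkerPanel, zebu_panel

SINGLETON = "singleton"


@dataclass
class PopulationSpec:
    name: str
    region: str
    # (item, count): item is an inventory haplotype name, or
    # ("singleton", family) for a fresh one-off haplotype per row
    composition: list[tuple[object, int]]

    @property
    def size(self) -> int:
        return sum(c for _, c in self.composition)


@dataclass
class GeneratorSpec:
    """Everything needed to generate one table (see module docstring)."""

    panel: MarkerPanel
    founders: dict[str, tuple[dict[str, tuple[int, ...]], dict[str, int]]]
    inventory: dict[str, tuple[str, dict[str, int]]]  # name -> (family, allele edits)
    populations: list[PopulationSpec]
    allele_domains: dict[str, tuple[int, ...]]
    jitter_lambda: float = 0.4
    frozen_loci: dict[str, frozenset] = field(default_factory=dict)
    band_flip_prob: float = 0.0  # off by default; stress-tests classification
    star: bool = False  # unbounded signed jitter (planted star phylogeny)

    def __post_init__(self) -> None:
        for name, (family, edits) in self.inventory.items():
            if family not in self.founders:
                raise ValueError(f"inventory {name!r} references unknown family")
            for locus, allele in edits.items():
                if locus not in self.panel.msat_loci:
                    raise ValueError(f"edit at unknown locus {locus!r}")
                if not self.star and allele not in self.allele_domains[locus]:
                    raise ValueError(f"allele {allele} outside domain of {locus!r}")
        for pop in self.populations:
            for item, count in pop.composition:
                if count < 0:
                    raise ValueError("negative count in composition")
                if isinstance(item, tuple):
                    if item[0] != SINGLETON or item[1] not in self.founders:
                        raise ValueError(f"bad composition item {item!r}")
                elif item not in self.inventory:
                    raise ValueError(f"unknown inventory item {item!r}")

    @property
    def total_size(self) -> int:
        return sum(p.size for p in self.populations)

    def planted_multiplicities(self) -> dict[str, int]:
        """Total planted copies of every inventory haplotype."""
        mult: dict[str, int] = {name: 0 for name in self.inventory}
        for pop in self.populations:
            for item, count in pop.composition:
                if not isinstance(item, tuple):
                    mult[item] += count
        return mult


def _inventory_alleles(spec: GeneratorSpec, name: str) -> dict[str, int]:
    family, edits = spec.inventory[name]
    alleles = dict(spec.founders[family][1])
    alleles.update(edits)
    return alleles


def _ladder_distance(spec: GeneratorSpec, family: str, alleles: dict) -> int:
    """Stepwise-mutation distance from the family founder (ladder steps
    within domains; raw repeat steps in star mode)."""
    founder = spec.founders[family][1]
    d = 0
    for locus, a in alleles.items():
        if spec.star:
            unit = spec.panel.infer_repeat_unit(locus, (a, founder[locus]))
            d += abs(a - founder[locus]) // unit
        else:
            ladder = list(spec.allele_domains[locus])
            d += abs(ladder.index(a) - ladder.index(founder[locus]))
    return d


def _jitter_singleton(
    spec: GeneratorSpec, family: str, rng: np.random.Generator, used: set
) -> tuple[dict[str, int], int]:
    """Fresh haplotype: founder + (1 + Poisson) SMM steps at jitterable
    loci, reflected at domain boundaries; redrawn until unseen."""
    frozen = spec.frozen_loci.get(family, frozenset())
    loci = [l for l in spec.panel.msat_loci if l not in frozen]
    founder = spec.founders[family][1]
    for _ in range(1000):
        alleles = dict(founder)
        n_steps = 1 + int(rng.poisson(spec.jitter_lambda))
        for _ in range(n_steps):
            locus = loci[int(rng.integers(len(loci)))]
            step = 1 if rng.random() < 0.5 else -1
            if spec.star:
                unit = spec.panel.repeat_units.get(locus, 2)
                alleles[locus] += step * unit
            else:
                ladder = list(spec.allele_domains[locus])
                i = ladder.index(alleles[locus])
                j = i + step
                if j < 0 or j >= len(ladder):
                    j = i - step  # reflect at the boundary
                alleles[locus] = ladder[j]
        if spec.star:  # star mode: coinciding tips are legitimate
            return alleles, n_steps
        key = tuple(sorted(alleles.items()))
        if key not in used:
            used.add(key)
            return alleles, n_steps
    raise RuntimeError("could not draw a distinct singleton haplotype")


def generate(spec: GeneratorSpec, seed: int) -> tuple[HaplotypeTable, pd.DataFrame]:
    """Generate a genotype table and its ground-truth ledger.

    Deterministic given ``seed``; distinct seeds give distinct tables
    (singleton draws and row order are randomised).
    """
    rng = np.random.Generator(np.random.PCG64(seed))
    used = {
        tuple(sorted(_inventory_alleles(spec, name).items()))
        for name in spec.inventory
    }
    rows, truth = [], []
    idx = 0
    for pop in spec.populations:
        for item, count in pop.composition:
            for _ in range(count):
                idx += 1
                sid = f"S{idx:04d}"
                if isinstance(item, tuple):
                    family = item[1]
                    alleles, n_steps = _jitter_singleton(spec, family, rng, used)
                    source = SINGLETON
                else:
                    family = spec.inventory[item][0]
                    alleles = _inventory_alleles(spec, item)
                    n_steps = _ladder_distance(spec, family, alleles)
                    source = item
                bands = {m: set(bs) for m, bs in spec.founders[family][0].items()}
                if spec.band_flip_prob > 0:
                    for marker, labels in spec.panel.imm_markers.items():
                        for b in labels:
                            if rng.random() < spec.band_flip_prob:
                                bands[marker] ^= {b}
                row = {"sample_id": sid, "population": pop.name,
                       "region": pop.region}
                for marker, labels in spec.panel.imm_markers.items():
                    for b in labels:
                        row[f"{marker}_b{b}"] = int(b in bands[marker])
                row.update(alleles)
                rows.append(row)
                truth.append(
                    {
                        "sample_id": sid,
                        "population": pop.name,
                        "region": pop.region,
                        "family": family,
                        "source": source,
                        "n_steps": n_steps,
                        "founder_distance": _ladder_distance(spec, family, alleles),
                    }
                )
    order = rng.permutation(len(rows))
    df = pd.DataFrame([rows[i] for i in order])
    ledger = pd.DataFrame([truth[i] for i in order])
    return table_from_dataframe(df, spec.panel), ledger


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

ALLELE_DOMAINS = {
    "INRA189": (98, 100, 102, 104),
    "UMN0103a": (139, 141, 143),
    "UMN0103b": (144, 146, 148),
    "UMN0307": (149, 151, 153),
    "BM861": (156, 158, 160),
    "BYM1": (102, 104, 106),
}

FOUNDERS = {
    "Y3_A": (
        {"UMN2405": (101, 103, 105, 107, 109, 123, 125, 129),
         "UMN2303": (118, 120, 122, 130)},
        {"INRA189": 100, "UMN0103a": 141, "UMN0103b": 146, "UMN0307": 149,
         "BM861": 158, "BYM1": 104},
    ),
    "Y3_B": (
        {"UMN2405": (101, 103, 105, 107, 111, 123, 125, 129),
         "UMN2303": (118, 120, 122, 126, 127, 128, 130)},
        {"INRA189": 102, "UMN0103a": 141, "UMN0103b": 146, "UMN0307": 149,
         "BM861": 156, "BYM1": 104},
    ),
    "Y3_C": (
        {"UMN2405": (101, 103, 113, 115, 117, 119, 121),
         "UMN2303": (118, 120, 122, 124, 132, 134)},
        {"INRA189": 98, "UMN0103a": 139, "UMN0103b": 148, "UMN0307": 153,
         "BM861": 160, "BYM1": 106},
    ),
}

# shared haplotype inventory: name -> (family, allele edits off the founder)
INVENTORY = {
    "A1": ("Y3_A", {}),
    "A2": ("Y3_A", {"INRA189": 102}),
    "A3": ("Y3_A", {"BYM1": 106}),
    "A4": ("Y3_A", {"UMN0103a": 143}),
    "A5": ("Y3_A", {"BM861": 160}),
    "A6": ("Y3_A", {"UMN0103b": 144}),
    "A7": ("Y3_A", {"UMN0307": 151}),
    "A8": ("Y3_A", {"INRA189": 98, "UMN0103a": 143}),
    "A9": ("Y3_A", {"UMN0103b": 148, "BYM1": 102}),
    "A10": ("Y3_A", {"BYM1": 102}),
    "A11": ("Y3_A", {"UMN0103a": 139}),
    "A12": ("Y3_A", {"INRA189": 104, "BM861": 156}),
    "A13": ("Y3_A", {"UMN0307": 153}),
    "B1": ("Y3_B", {}),
    "C1": ("Y3_C", {}),
    "C2": ("Y3_C", {"BYM1": 104}),
    "C3": ("Y3_C", {"BM861": 158}),
    "C4": ("Y3_C", {"INRA189": 100}),
}

_S = SINGLETON
# 22 populations, 248 males; Y3_B confined to West Africa, Y3_C centred
# on South India / Yemen with traces eastwards and in East Africa
PAPER_COMPOSITION = [
    ("Nelore_BR", "America", [("A2", 42), ((_S, "Y3_A"), 2)]),
    ("Argentino_AR", "America", [("A3", 13), ((_S, "Y3_A"), 4)]),
    ("Kankrej_IN", "India-North", [("A1", 13), ((_S, "Y3_A"), 4)]),
    ("Tharparkar_IN", "India-North", [("A3", 11), ((_S, "Y3_A"), 1)]),
    ("Sahiwal_PK", "India-North", [("A2", 9), ("A4", 3)]),
    ("Hallikar_IN", "India-South",
     [("C1", 8), ("C2", 2), ((_S, "Y3_C"), 2), ("A2", 1)]),
    ("Ongole_IN", "India-South", [("C1", 6), ("C3", 3), ("A2", 3)]),
    ("Kangayam_IN", "India-South", [("A7", 5), ("C2", 2)]),
    ("Siri_BT", "India-Northeast", [("A8", 5), ("C4", 1)]),
    ("Kherigarh_IN", "India-Northeast", [("A9", 4), ("C4", 2)]),
    ("KazakhZebu_KZ", "Central-Asia",
     [("A10", 4), ("A11", 3), ((_S, "Y3_C"), 1)]),
    ("KirghizZebu_KG", "Central-Asia", [("A12", 3), ("A13", 2)]),
    ("Yemeni_YE", "Near-East", [("C1", 7), ((_S, "Y3_C"), 1)]),
    ("Boran_KE", "East-Africa", [("A6", 8), ("C1", 1), ((_S, "Y3_C"), 1)]),
    ("Butana_SD", "East-Africa", [("A4", 6), ("C1", 1)]),
    ("RayaAzebo_ET", "East-Africa",
     [("A5", 3), ("A6", 1), ("A7", 1), ((_S, "Y3_A"), 1)]),
    ("Bororo_ML", "West-Africa", [("A1", 5), ("B1", 3), ((_S, "Y3_B"), 2)]),
    ("Goudali_NG", "West-Africa",
     [("B1", 3), ((_S, "Y3_B"), 1), ("A1", 1), ((_S, "Y3_A"), 1)]),
    ("ZebuPeul_BF", "West-Africa",
     [("B1", 4), ((_S, "Y3_B"), 4), ("A1", 2)]),
    ("SokotoGudali_NG", "West-Africa",
     [("A1", 10), ("B1", 1), ((_S, "Y3_B"), 2)]),
    ("MBororo_CF", "West-Africa", [("B1", 2)]),
    ("Maure_ML", "West-Africa", [("A4", 15), ((_S, "Y3_B"), 2)]),
]

# planted structure the preset promises (used by tests and examples)
PRESET_EXPECTATIONS = {
    "n_samples": 248,
    "n_populations": 22,
    "n_haplotypes": 47,
    "n_singletons": 29,
    "modal_multiplicity": 55,
    "y3c_central_multiplicity": 23,
    "n_msat_alleles": 19,
    "family_samples": {"Y3_A": 186, "Y3_B": 24, "Y3_C": 38},
    "family_haplotypes": {"Y3_A": 26, "Y3_B": 12, "Y3_C": 9},
}


def paper_like_preset() -> GeneratorSpec:
    """Spec emulating the published survey structure (see module docs)."""
    pops = [PopulationSpec(n, r, comp) for n, r, comp in PAPER_COMPOSITION]
    return GeneratorSpec(
        panel=zebu_panel(),
        founders=FOUNDERS,
        inventory=INVENTORY,
        populations=pops,
        allele_domains=ALLELE_DOMAINS,
        jitter_lambda=0.4,
        frozen_loci={"Y3_C": frozenset({"UMN0307"})},
    )


def single_family_spec(
    family: str = "Y3_A",
    n: int = 30,
    n_singletons: int = 5,
    population: str = "Pop1",
    region: str = "Region1",
) -> GeneratorSpec:
    """One population, one family: founder copies plus singletons."""
    comp = [(family_founder_name(family), n - n_singletons)]
    if n_singletons:
        comp.append(((SINGLETON, family), n_singletons))
    return GeneratorSpec(
        panel=zebu_panel(),
        founders=FOUNDERS,
        inventory={family_founder_name(family): (family, {})},
        populations=[PopulationSpec(population, region, comp)],
        allele_domains=ALLELE_DOMAINS,
        frozen_loci={"Y3_C": frozenset({"UMN0307"})},
    )


def family_founder_name(family: str) -> str:
    return {"Y3_A": "A1", "Y3_B": "B1", "Y3_C": "C1"}[family]


def star_spec(
    n: int = 180, lam: float = 0.8, family: str = "Y3_A"
) -> GeneratorSpec:
    """Planted star phylogeny: every sampled male is an independent
    singleton lying 1 + Poisson(lam - 1) ... precisely: each row takes
    ``1 + Poisson(lam)`` unbounded SMM steps from the founder, so the
    analytic expected founder distance is available from the ledger and
    the planted rho equals the mean recorded distance."""
    return GeneratorSpec(
        panel=zebu_panel(),
        founders=FOUNDERS,
        inventory={family_founder_name(family): (family, {})},
        populations=[
            PopulationSpec("StarPop", "Star", [((SINGLETON, family), n)])
        ],
        allele_domains=ALLELE_DOMAINS,
        jitter_lambda=lam,
        star=True,
    )
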