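"""Marker panel description for Y-chromosome haplotyping.

A panel combines two kinds of Y-specific markers:

* Interspersed Multilocus Microsatellites (IMMs) — dominant markers typed
  as a presence/absence profile over a fixed, ordered list of band labels.
* Y-specific microsatellites — codominant loci typed as integer allele
  sizes (fragment lengths); one physical marker may contribute more than
  one locus (UMN0103 is typed at two loci).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


@dataclass(frozen=True)
class MarkerPanel:
    """Immutable description of the markers making up a haplotype.

    Parameters
    ----------
    imm_markers
        Mapping of IMM marker name to its ordered tuple of band labels
        (integers, typically fragment sizes in bp).
    msat_loci
        Ordered tuple of microsatellite locus names.
    repeat_units
        Optional per-locus repeat unit (bp per mutational step). Loci
        absent from the mapping have their unit inferred from the data
        (GCD of pairwise allele differences) when distances are computed.
    """

    imm_markers: dict[str, tuple[int, ...]]
    msat_loci: tuple[str, ...]
    repeat_units: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for marker, bands in self.imm_markers.items():
            if len(set(bands)) != len(bands):
                raise ValueError(f"duplicate band labels for IMM {marker!r}")
        if len(set(self.msat_loci)) != len(self.msat_loci):
            raise ValueError("duplicate microsatellite locus names")
        overlap = set(self.imm_markers) & set(self.msat_loci)
        if overlap:
            raise ValueError(f"names used both as IMM and microsatellite: {overlap}")

    # -- column layout ----------------------------------------------------
    @property
    def band_columns(self) -> list[str]:
        """Flat list of presence/absence column names, panel order."""
        return [
            f"{marker}_b{band}"
            for marker, bands in self.imm_markers.items()
            for band in bands
        ]

    @property
    def columns(self) -> list[str]:
        """All genotype columns a table for this panel must carry."""
        return self.band_columns + list(self.msat_loci)

    @property
    def n_markers(self) -> int:
        """Number of typed markers: IMMs count once each (whole profile)."""
        return len(self.imm_markers) + len(self.msat_loci)

    def band_index(self) -> dict[str, tuple[str, int]]:
        """Map each band column name back to (marker, band label)."""
        return {
            f"{marker}_b{band}": (marker, band)
            for marker, bands in self.imm_markers.items()
            for band in bands
        }

    def infer_repeat_unit(self, locus: str, alleles) -> int:
        """Repeat unit for ``locus``: explicit if configured, else the GCD
        of pairwise differences among the observed integer ``alleles``."""
        if locus in self.repeat_units:
            return self.repeat_units[locus]
        sizes = sorted({int(a) for a in alleles})
        if len(sizes) < 2:
            return 1
        g = 0
        for a, b in zip(sizes, sizes[1:]):
            g = math.gcd(g, b - a)
        return max(g, 1)


def zebu_panel() -> MarkerPanel:
    """Default panel used throughout: the 2 IMMs (UMN2405, UMN2303) and six
    Y-specific microsatellite loci, with UMN0103 typed at two loci.

    Band lists cover the diagnostic UMN2303 bands (124, 126, 127, 128)
    used for haplotypic-family classification plus a backbone of shared
    bands on both IMMs.
    """
    return MarkerPanel(
        imm_markers={
            "UMN2405": (101, 103, 105, 107, 109, 111, 113, 115,
                        117, 119, 121, 123, 125, 129),
            "UMN2303": (118, 120, 122, 124, 126, 127, 128, 130, 132, 134),
        },
        msat_loci=(
            "INRA189",
            "UMN0103a",
            "UMN0103b",
            "UMN0307",
            "BM861",
            "BYM1",
        ),
        repeat_units={
            "INRA189": 2,
            "UMN0103a": 2,
            "UMN0103b": 2,
            "UMN0307": 2,
            "BM861": 2,
            "BYM1": 2,
        },
    )
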