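"""Haplotype assembly and haplotypic-family classification.

Per-individual genotypes (IMM band profiles + microsatellite alleles) are
combined into haplotypes; identical profiles collapse onto one haplotype
whose multiplicity is the number of carrier males. Haplotypes are then
classified into the three zebu haplotypic families:

* ``Y3_B`` — carries any of bands 126/127/128 on IMM UMN2303;
* ``Y3_C`` — lacks allele 149 at microsatellite UMN0307 *and* carries
  band 124 on UMN2303;
* ``Y3_A`` — everything else (the cosmopolitan majority family).

The rules are applied in that order, so a haplotype matching both the
Y3_B and Y3_C signatures is called Y3_B.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .panel import MarkerPanel

logger = logging.getLogger(__name__)

FAMILIES = ("Y3_A", "Y3_B", "Y3_C")

Y3B_BANDS = frozenset({126, 127, 128})
Y3C_BAND = 124
Y3C_MARKER = "UMN2303"
Y3C_LOCUS = "UMN0307"
Y3C_ABSENT_ALLELE = 149

META_COLUMNS = ("sample_id", "population", "region")


@dataclass
class HaplotypeTable:
    """Per-individual marker profiles with population/region labels.

    ``data`` holds one row per sampled male: the metadata columns
    ``sample_id``/``population``/``region``, one 0/1 column per IMM band
    (``<marker>_b<band>``) and one integer column per microsatellite
    locus. ``flagged`` marks rows with any missing call; such rows are
    retained on read but excluded from haplotype building.
    """

    panel: MarkerPanel
    data: pd.DataFrame
    flagged: pd.Series  # bool per row, aligned with ``data``

    def __len__(self) -> int:
        return len(self.data)

    @property
    def populations(self) -> list[str]:
        return sorted(self.data["population"].unique())

    def complete(self) -> "HaplotypeTable":
        """Table restricted to rows without missing calls."""
        keep = ~self.flagged
        n_drop = int(self.flagged.sum())
        if n_drop:
            logger.info("excluding %d rows with missing marker calls", n_drop)
        sub = self.data.loc[keep].reset_index(drop=True)
        return HaplotypeTable(self.panel, sub, pd.Series(False, index=sub.index))


@dataclass(frozen=True)
class Haplotype:
    """One distinct marker profile and its carriers.

    ``bands`` maps each IMM marker to the ordered tuple of band labels
    present; ``alleles`` maps each microsatellite locus to its integer
    allele. The canonical tuple (``key``) makes equality independent of
    input row order.
    """

    hap_id: str
    bands: dict[str, tuple[int, ...]]
    alleles: dict[str, int]
    multiplicity: int
    populations: tuple[str, ...]

    @property
    def key(self) -> tuple:
        return canonical_key(self.bands, self.alleles)


def canonical_key(bands: dict[str, tuple[int, ...]], alleles: dict[str, int]) -> tuple:
    """Order-independent canonical tuple for one marker profile."""
    return (
        tuple((m, tuple(sorted(bs))) for m, bs in sorted(bands.items())),
        tuple(sorted(alleles.items())),
    )


def read_genotype_table(
    path: str | Path,
    panel: MarkerPanel,
    *,
    sep: str | None = None,
) -> HaplotypeTable:
    """Read a delimited genotype table into a :class:`HaplotypeTable`.

    The file must carry the metadata columns ``sample_id``, ``population``
    and ``region`` plus every genotype column of ``panel``. Band columns
    may contain only 0, 1 or missing; microsatellite columns integers or
    missing. Rows with any missing call are kept but flagged.

    Raises
    ------
    ValueError
        If a panel column is absent, an unexpected genotype column is
        present, or a band cell is neither binary nor missing (the error
        names the offending row and column).
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path)  # thin convertor; needs openpyxl
    else:
        df = pd.read_csv(path, sep=sep)
    return table_from_dataframe(df, panel)


def table_from_dataframe(df: pd.DataFrame, panel: MarkerPanel) -> HaplotypeTable:
    """Validate a raw genotype DataFrame against ``panel`` (see
    :func:`read_genotype_table` for the contract)."""
    df = df.copy()
    missing_meta = [c for c in META_COLUMNS if c not in df.columns]
    if missing_meta:
        raise ValueError(f"missing metadata columns: {missing_meta}")
    missing_cols = [c for c in panel.columns if c not in df.columns]
    if missing_cols:
        raise ValueError(f"missing panel columns: {missing_cols}")
    unknown = [
        c for c in df.columns if c not in panel.columns and c not in META_COLUMNS
    ]
    if unknown:
        raise ValueError(f"unknown marker columns: {unknown}")
    if (df["population"].astype(str).str.len() == 0).any():
        raise ValueError("empty population labels")

    flagged = pd.Series(False, index=df.index)
    for col in panel.band_columns:
        vals = df[col]
        missing = vals.isna()
        bad = ~missing & ~vals.isin([0, 1, "0", "1", 0.0, 1.0])
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"non-binary band value {vals[row]!r} at row {row}, column {col!r}"
            )
        flagged |= missing
        df[col] = vals.where(missing, vals.astype(float).astype("Int64"))
    for col in panel.msat_loci:
        vals = pd.to_numeric(df[col], errors="coerce")
        flagged |= vals.isna()
        df[col] = vals.astype("Int64")
    df = df.reset_index(drop=True)
    flagged = flagged.reset_index(drop=True)
    return HaplotypeTable(panel, df, flagged)


def write_genotype_table(table: HaplotypeTable, path: str | Path) -> None:
    """Write a table back to CSV (columns in panel order)."""
    cols = list(META_COLUMNS) + table.panel.columns
    table.data[cols].to_csv(path, index=False)


def _row_profile(row: pd.Series, panel: MarkerPanel):
    bands: dict[str, tuple[int, ...]] = {}
    for marker, labels in panel.imm_markers.items():
        bands[marker] = tuple(b for b in labels if int(row[f"{marker}_b{b}"]) == 1)
    alleles = {locus: int(row[locus]) for locus in panel.msat_loci}
    return bands, alleles


def build_haplotypes(table: HaplotypeTable) -> list[Haplotype]:
    """Collapse rows onto distinct haplotypes.

    Rows flagged as missing must be removed first (``table.complete()``);
    their presence is an error. Haplotypes are sorted by descending
    multiplicity then by canonical tuple and labelled ``H1``, ``H2``, …
    deterministically, so the output is invariant under row permutation.
    """
    if table.flagged.any():
        raise ValueError(
            "table contains flagged rows with missing calls; call "
            ".complete() (or impute) before building haplotypes"
        )
    groups: dict[tuple, dict] = {}
    for _, row in table.data.iterrows():
        bands, alleles = _row_profile(row, table.panel)
        key = canonical_key(bands, alleles)
        rec = groups.setdefault(
            key, {"bands": bands, "alleles": alleles, "count": 0, "pops": set()}
        )
        rec["count"] += 1
        rec["pops"].add(str(row["population"]))
    ordered = sorted(groups.items(), key=lambda kv: (-kv[1]["count"], kv[0]))
    haps = [
        Haplotype(
            hap_id=f"H{i + 1}",
            bands=rec["bands"],
            alleles=rec["alleles"],
            multiplicity=rec["count"],
            populations=tuple(sorted(rec["pops"])),
        )
        for i, (_, rec) in enumerate(ordered)
    ]
    assert sum(h.multiplicity for h in haps) == len(table)
    return haps


def classify_family(hap: Haplotype) -> str:
    """Assign one haplotype to Y3_A / Y3_B / Y3_C by the band rules."""
    u2303 = set(hap.bands.get(Y3C_MARKER, ()))
    if u2303 & Y3B_BANDS:
        return "Y3_B"
    if hap.alleles.get(Y3C_LOCUS) != Y3C_ABSENT_ALLELE and Y3C_BAND in u2303:
        return "Y3_C"
    return "Y3_A"


@dataclass
class FamilyAssignment:
    """Haplotype-id → family mapping with provenance.

    ``source`` is ``"band-rule"`` when produced by :func:`assign_families`
    and ``"override"`` for entries replaced from a user-supplied mapping
    (supported because the published family definitions are diagnostic
    rules summarising a phylogeny, not the phylogeny itself).
    """

    families: dict[str, str]
    source: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, hap_id: str) -> str:
        return self.families[hap_id]


def assign_families(
    haps: list[Haplotype],
    overrides: dict[str, str] | None = None,
) -> FamilyAssignment:
    """Classify every haplotype; ``overrides`` (hap_id → family) wins."""
    fam = {h.hap_id: classify_family(h) for h in haps}
    src = {hid: "band-rule" for hid in fam}
    for hid, f in (overrides or {}).items():
        if f not in FAMILIES:
            raise ValueError(f"unknown family {f!r} for {hid}")
        fam[hid] = f
        src[hid] = "override"
    return FamilyAssignment(fam, src)


def family_census(
    assignment: FamilyAssignment, haps: list[Haplotype]
) -> pd.DataFrame:
    """Per-family haplotype and sample counts with fractions.

    Returns a DataFrame indexed by family with columns ``n_haplotypes``,
    ``n_samples``, ``frac_haplotypes``, ``frac_samples``; families absent
    from the data appear with zeros.
    """
    missing = [h.hap_id for h in haps if h.hap_id not in assignment.families]
    if missing:
        raise ValueError(f"haplotypes without family assignment: {missing}")
    rows = {f: {"n_haplotypes": 0, "n_samples": 0} for f in FAMILIES}
    for h in haps:
        f = assignment[h.hap_id]
        rows[f]["n_haplotypes"] += 1
        rows[f]["n_samples"] += h.multiplicity
    census = pd.DataFrame.from_dict(rows, orient="index")
    tot_h = census["n_haplotypes"].sum()
    tot_s = census["n_samples"].sum()
    census["frac_haplotypes"] = census["n_haplotypes"] / max(tot_h, 1)
    census["frac_samples"] = census["n_samples"] / max(tot_s, 1)
    return census


def haplotypes_to_frame(
    haps: list[Haplotype], assignment: FamilyAssignment | None = None
) -> pd.DataFrame:
    """Tabular summary of haplotypes (id, profile, multiplicity, family)."""
    recs = []
    for h in haps:
        rec = {
            "hap_id": h.hap_id,
            "multiplicity": h.multiplicity,
            "populations": ";".join(h.populations),
        }
        for marker, bs in h.bands.items():
            rec[marker] = ";".join(map(str, bs))
        rec.update(h.alleles)
        if assignment is not None:
            rec["family"] = assignment[h.hap_id]
        recs.append(rec)
    return pd.DataFrame(recs)
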