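"""Nei diversity estimators, between-population identity, and its PCA.

Haplotype diversity uses the unbiased estimator

    h = n (1 - sum_i p_i^2) / (n - 1)

with sampling variance

    V(h) = 2 / (n (n-1)) * { 2 (n-2) [ sum p_i^3 - (sum p_i^2)^2 ]
                             + sum p_i^2 - (sum p_i^2)^2 }

(Nei's classical formulas for haplotype/gene diversity and its variance).
Gene diversity applies the same estimator per locus and averages over
loci. Between-population identity is the locus-average of the shared
allele-frequency product sum_i x_ij * y_ij; its complement (1 - identity)
is summarised by classical PCoA (double-centred eigendecomposition).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .haplotypes import HaplotypeTable, build_haplotypes
from .panel import MarkerPanel


@dataclass(frozen=True)
class DiversityEstimate:
    h: float
    V_h: float
    gene_diversity: float = float("nan")

    @property
    def SE_h(self) -> float:
        return float(np.sqrt(self.V_h))


@dataclass
class PopulationFrequencies:
    """Per-locus allele frequency vectors for one population.

    ``freqs`` maps locus name → {allele label: frequency}; every vector
    sums to 1. The locus registry (the set of locus names) must be shared
    across populations entering the same identity matrix. IMM bands enter
    either as one biallelic presence/absence locus per band (``imm =
    'bands'``) or as one multi-allelic locus per IMM marker whose alleles
    are whole band profiles (``imm = 'profile'``).
    """

    name: str
    n: int
    freqs: dict[str, dict[object, float]]

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("population sample size must be >= 1")
        for locus, vec in self.freqs.items():
            tot = sum(vec.values())
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(f"frequencies at {locus!r} sum to {tot}, not 1")
            if any(v < 0 for v in vec.values()):
                raise ValueError(f"negative frequency at {locus!r}")

    @property
    def loci(self) -> tuple[str, ...]:
        return tuple(sorted(self.freqs))


# ---------------------------------------------------------------------------
# Nei estimators
# ---------------------------------------------------------------------------

def haplotype_diversity(counts, n: int | None = None) -> DiversityEstimate:
    """Unbiased haplotype diversity h and its variance V(h).

    Parameters
    ----------
    counts
        Multiplicity of each distinct haplotype in the sample.
    n
        Sample size; defaults to ``sum(counts)`` and must match it.
    """
    counts = np.asarray(list(counts), dtype=float)
    total = int(counts.sum())
    if n is None:
        n = total
    elif n != total:
        raise ValueError(f"n={n} does not match sum of counts={total}")
    if n < 2:
        raise ValueError("haplotype diversity requires a sample of n >= 2")
    p = counts / n
    s2 = float(np.sum(p**2))
    s3 = float(np.sum(p**3))
    h = n * (1.0 - s2) / (n - 1)
    v = 2.0 / (n * (n - 1)) * (2.0 * (n - 2) * (s3 - s2**2) + s2 - s2**2)
    return DiversityEstimate(h=h, V_h=max(v, 0.0))


def unbiased_gene_diversity(freq_vector, n: int) -> float:
    """Per-locus gene diversity n(1 - sum x_i^2)/(n-1)."""
    if n < 2:
        raise ValueError("gene diversity requires n >= 2")
    x = np.asarray(list(freq_vector), dtype=float)
    return float(n * (1.0 - np.sum(x**2)) / (n - 1))


def gene_diversity(pop: PopulationFrequencies) -> tuple[pd.Series, float]:
    """Per-locus and mean (over loci) gene diversity for one population."""
    per_locus = pd.Series(
        {
            locus: unbiased_gene_diversity(vec.values(), pop.n)
            for locus, vec in pop.freqs.items()
        }
    )
    return per_locus, float(per_locus.mean())


# ---------------------------------------------------------------------------
# Building frequencies from a genotype table
# ---------------------------------------------------------------------------

def _locus_calls(df: pd.DataFrame, panel: MarkerPanel, imm: str):
    """Yield (locus name, per-row hashable allele calls) for every locus."""
    for locus in panel.msat_loci:
        yield locus, [int(a) for a in df[locus]]
    if imm == "bands":
        for col in panel.band_columns:
            if df[col].nunique() > 1:  # only polymorphic bands are loci
                yield col, [int(v) for v in df[col]]
    elif imm == "profile":
        for marker, bands in panel.imm_markers.items():
            cols = [f"{marker}_b{b}" for b in bands]
            yield marker, [
                tuple(int(v) for v in row) for row in df[cols].itertuples(index=False)
            ]
    else:
        raise ValueError(f"imm mode must be 'bands' or 'profile', got {imm!r}")


def population_frequencies(
    table: HaplotypeTable,
    *,
    imm: str = "bands",
    min_n: int = 2,
) -> list[PopulationFrequencies]:
    """Allele frequencies per population, on a shared locus registry.

    Polymorphism (for the ``'bands'`` IMM mode) is judged on the whole
    table so all populations share one registry. Populations with fewer
    than ``min_n`` complete rows are dropped.
    """
    df = table.complete().data
    loci = dict(_locus_calls(df, table.panel, imm))
    out: list[PopulationFrequencies] = []
    for pop, idx in df.groupby("population").groups.items():
        pos = df.index.get_indexer(idx)
        n = len(pos)
        if n < min_n:
            continue
        freqs = {
            locus: {v: c / n for v, c in Counter(calls[i] for i in pos).items()}
            for locus, calls in loci.items()
        }
        out.append(PopulationFrequencies(str(pop), n, freqs))
    return out


def pooled_frequencies(
    table: HaplotypeTable, *, imm: str = "bands", name: str = "pooled"
) -> PopulationFrequencies:
    """All complete rows treated as one population."""
    df = table.complete().data
    n = len(df)
    freqs = {
        locus: {v: c / n for v, c in Counter(calls).items()}
        for locus, calls in _locus_calls(df, table.panel, imm)
    }
    return PopulationFrequencies(name, n, freqs)


def diversity_table(table: HaplotypeTable, *, imm: str = "bands") -> pd.DataFrame:
    """Per-population n, haplotype diversity (with SE) and gene diversity.

    The locus registry (which loci/bands count as polymorphic) is judged
    on the whole table, so per-population gene diversities are averages
    over a shared locus set and comparable across populations.
    """
    complete = table.complete()
    pfs = {pf.name: pf for pf in population_frequencies(table, imm=imm)}
    rows = []
    for pop in complete.populations:
        if pop not in pfs:
            continue
        sub_df = complete.data[complete.data["population"] == pop].reset_index(
            drop=True
        )
        sub = HaplotypeTable(table.panel, sub_df, pd.Series(False, index=sub_df.index))
        haps = build_haplotypes(sub)
        est = haplotype_diversity([h.multiplicity for h in haps])
        _, gd = gene_diversity(pfs[pop])
        rows.append(
            {"population": pop, "n": len(sub_df), "h": est.h, "SE_h": est.SE_h,
             "gene_diversity": gd}
        )
    return pd.DataFrame(rows)


def overall_diversity(
    table: HaplotypeTable, *, mode: str = "population-mean", imm: str = "bands"
) -> dict[str, float]:
    """Overall gene and haplotype diversity.

    ``mode='population-mean'`` averages per-population estimates
    (populations with n < 2 excluded); ``mode='pooled'`` treats all rows
    as one sample.
    """
    if mode == "population-mean":
        tab = diversity_table(table, imm=imm)
        return {
            "gene_diversity": float(tab["gene_diversity"].mean()),
            "haplotype_diversity": float(tab["h"].mean()),
        }
    if mode == "pooled":
        complete = table.complete()
        haps = build_haplotypes(complete)
        est = haplotype_diversity([h.multiplicity for h in haps])
        _, gd = gene_diversity(pooled_frequencies(table, imm=imm))
        return {"gene_diversity": gd, "haplotype_diversity": est.h}
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Identity matrix and its PCA
# ---------------------------------------------------------------------------

def pair_identity(a: PopulationFrequencies, b: PopulationFrequencies) -> float:
    """Locus-average of sum_i x_ij * y_ij over the shared registry."""
    if a.loci != b.loci:
        raise ValueError(
            f"locus registries differ between {a.name!r} and {b.name!r}"
        )
    vals = []
    for locus in a.loci:
        xa, xb = a.freqs[locus], b.freqs[locus]
        vals.append(sum(xa[al] * xb.get(al, 0.0) for al in xa))
    return float(np.mean(vals))


def identity_matrix(pops: list[PopulationFrequencies]) -> pd.DataFrame:
    """Symmetric between-population genetic identity matrix."""
    if len(pops) < 2:
        raise ValueError("identity matrix needs at least 2 populations")
    names = [p.name for p in pops]
    m = np.zeros((len(pops), len(pops)))
    for i, a in enumerate(pops):
        for j in range(i, len(pops)):
            m[i, j] = m[j, i] = pair_identity(a, pops[j])
    return pd.DataFrame(m, index=names, columns=names)


def identity_pca(M: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical PCoA of the complement (1 - identity) matrix.

    The complement is double-centred (B = -1/2 J D J) and
    eigendecomposed; component scores are eigvec * sqrt(eigval) for
    positive eigenvalues and percent variance is taken over the positive
    eigenvalues only (negative eigenvalues from a non-Euclidean input are
    reported as 0%).

    Returns (scores DataFrame with columns PC1…, percent-variance array
    summing to 100).
    """
    if M.shape[0] < 3:
        raise ValueError("PCA of the identity complement needs >= 3 populations")
    D = 1.0 - M.to_numpy(dtype=float)
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-12
    percents = np.where(pos, eigval, 0.0)
    percents = 100.0 * percents / percents.sum()
    k = int(pos.sum())
    scores = eigvec[:, :k] * np.sqrt(eigval[:k])
    cols = [f"PC{i + 1}" for i in range(k)]
    return pd.DataFrame(scores, index=M.index, columns=cols), percents
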