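"""ABC model choice: summary statistics, rejection, GLM densities, PODS.

The four summary statistics (computed over the 8 Y loci of a pooled
sample) are:

* ``K_sd``   — SD over loci of the number of distinct alleles,
* ``H_mean`` — mean over loci of unbiased gene diversity n(1-Σp²)/(n-1),
* ``H_sd``   — SD over loci of that per-locus diversity,
* ``Ht_mean``— mean total (pooled-sample) gene diversity; identical to
  ``H_mean`` for a single pooled sample, kept as a separate statistic so
  grouped samples can be analysed with the same machinery.

Rejection retains the closest fraction of simulations under Euclidean
distance on statistics standardised by the simulated pool's SDs. The
marginal density of the observed statistics under each scenario follows
the ABC-GLM construction: a linear regression of statistics on
parameters over the retained simulations with multivariate-normal
residuals, the density being the average fitted-normal density over the
retained parameter draws. Posterior model probabilities assume equal
model priors; Bayes factors are density ratios. A rejection-count
estimator (each model's share of a globally retained set) is reported
alongside as a cross-check, and pseudo-observed datasets (PODS) quantify
misclassification rates and false-positive posterior probabilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .coalescent import ALL_LOCI, PriorSpec, SimulatedDataset, simulate_batch
from .diversity import pooled_frequencies, unbiased_gene_diversity
from .haplotypes import HaplotypeTable

logger = logging.getLogger(__name__)

STAT_NAMES = ("K_sd", "H_mean", "H_sd", "Ht_mean")
RETENTION_FRACTION = 0.005  # the analysis default


def _locus_stats(columns: list[np.ndarray], n: int) -> tuple[np.ndarray, np.ndarray]:
    ks, hs = [], []
    for col in columns:
        _, counts = np.unique(col, return_counts=True)
        ks.append(len(counts))
        hs.append(unbiased_gene_diversity(counts / n, n))
    return np.array(ks, dtype=float), np.array(hs, dtype=float)


def summary_stats(ds: SimulatedDataset | np.ndarray) -> np.ndarray:
    """The 4 summary statistics of one simulated (pooled) dataset."""
    geno = ds.genotypes if isinstance(ds, SimulatedDataset) else np.asarray(ds)
    n, n_loci = geno.shape
    if n < 2:
        raise ValueError("summary statistics require >= 2 samples")
    k, h = _locus_stats([geno[:, j] for j in range(n_loci)], n)
    return np.array([k.std(ddof=1), h.mean(), h.std(ddof=1), h.mean()])


def observed_summary_stats(table: HaplotypeTable) -> np.ndarray:
    """Summary statistics of an observed genotype table, pooled, with
    each IMM marker treated as one multi-allelic locus (its allele being
    the whole band profile) to match the simulated marker layout."""
    pf = pooled_frequencies(table, imm="profile")
    if len(pf.freqs) != len(ALL_LOCI):
        logger.warning(
            "observed table has %d loci, simulations have %d",
            len(pf.freqs), len(ALL_LOCI),
        )
    k = np.array([len(v) for v in pf.freqs.values()], dtype=float)
    h = np.array(
        [unbiased_gene_diversity(v.values(), pf.n) for v in pf.freqs.values()]
    )
    return np.array([k.std(ddof=1), h.mean(), h.std(ddof=1), h.mean()])


# ---------------------------------------------------------------------------
# Rejection
# ---------------------------------------------------------------------------

def rejection(
    observed: np.ndarray,
    sim_stats: np.ndarray,
    fraction: float = RETENTION_FRACTION,
    scale_sd: np.ndarray | None = None,
) -> np.ndarray:
    """Indices of the retained simulations (closest ceil(fraction*N)).

    Distances are Euclidean on statistics divided by ``scale_sd`` (the
    per-statistic SD of the simulated pool by default). Zero-variance
    statistics are dropped from the distance with a warning. Ties break
    by simulation index (stable sort).
    """
    sim_stats = np.asarray(sim_stats, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if sim_stats.ndim != 2 or len(sim_stats) == 0:
        raise ValueError("sim_stats must be a non-empty 2-D array")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    sd = sim_stats.std(axis=0, ddof=1) if scale_sd is None else np.asarray(scale_sd)
    keep = sd > 0
    if not keep.all():
        logger.warning(
            "dropping zero-variance statistics from the distance: %s",
            [STAT_NAMES[i] if i < len(STAT_NAMES) else i
             for i in np.flatnonzero(~keep)],
        )
    if not keep.any():
        raise ValueError("all statistics have zero variance in the pool")
    d = np.linalg.norm(
        (sim_stats[:, keep] - observed[keep]) / sd[keep], axis=1
    )
    n_keep = int(np.ceil(fraction * len(sim_stats)))
    return np.argsort(d, kind="stable")[:n_keep]


# ---------------------------------------------------------------------------
# ABC-GLM marginal density
# ---------------------------------------------------------------------------

def _independent_columns(x: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Greedy maximal subset of columns with non-degenerate variance and
    full rank (drops exact duplicates such as Ht_mean == H_mean)."""
    cols: list[int] = []
    for j in range(x.shape[1]):
        if x[:, j].std() <= tol:
            continue
        trial = x[:, cols + [j]]
        if np.linalg.matrix_rank(trial - trial.mean(0), tol=tol) == len(cols) + 1:
            cols.append(j)
    return np.array(cols, dtype=int)


def glm_marginal_density(
    retained_params: np.ndarray,
    retained_stats: np.ndarray,
    observed: np.ndarray,
) -> float:
    """ABC-GLM estimate of the marginal density at the observed stats.

    Fits stats = B·params + c + ε with ε ~ N(0, Σ) over the retained
    simulations and averages the fitted normal density at ``observed``
    over the retained parameter draws. Falls back to a Gaussian KDE of
    the retained statistics when the fit is singular.
    """
    theta = np.asarray(retained_params, dtype=float)
    s = np.asarray(retained_stats, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if theta.ndim == 1:
        theta = theta[:, None]
    if len(s) < 30:
        raise ValueError("need at least 30 retained simulations for the GLM")
    cols = _independent_columns(s)
    if cols.size == 0:
        raise ValueError("retained statistics are all degenerate")
    s_use, obs_use = s[:, cols], obs[cols]
    design = np.column_stack([np.ones(len(theta)), theta])
    coef, *_ = np.linalg.lstsq(design, s_use, rcond=None)
    fitted = design @ coef
    resid = s_use - fitted
    dof = max(len(s_use) - design.shape[1], 1)
    sigma = resid.T @ resid / dof
    try:
        mvn = sp_stats.multivariate_normal(
            mean=np.zeros(len(cols)), cov=sigma, allow_singular=False
        )
        dens = float(np.mean(mvn.pdf(obs_use - fitted)))
    except (np.linalg.LinAlgError, ValueError):
        logger.warning("singular GLM residual covariance; using KDE fallback")
        dens = float(sp_stats.gaussian_kde(s_use.T)(obs_use[:, None])[0])
    return max(dens, np.finfo(float).tiny)


# ---------------------------------------------------------------------------
# Model choice
# ---------------------------------------------------------------------------

@dataclass
class ModelChoiceResult:
    """Posterior support of each scenario given the observed statistics."""

    models: tuple[int, ...]
    densities: dict[int, float]
    posterior: dict[int, float]
    bayes_factors: pd.DataFrame
    rejection_share: dict[int, float]
    retained: dict[int, np.ndarray]
    fraction: float

    @property
    def best_model(self) -> int:
        return max(self.posterior, key=self.posterior.get)

    @property
    def best_model_by_rejection(self) -> int:
        return max(self.rejection_share, key=self.rejection_share.get)


def model_choice(
    observed: np.ndarray,
    sims: dict[int, tuple[np.ndarray, np.ndarray]],
    fraction: float = RETENTION_FRACTION,
) -> ModelChoiceResult:
    """Compare scenarios given observed statistics.

    ``sims`` maps model id → (params array, stats array) of equal length.
    Posterior probabilities are GLM densities normalised under equal
    model priors; the rejection-count estimator retains the globally
    closest fraction of the pooled simulations and reports each model's
    share.
    """
    models = tuple(sorted(sims))
    densities, retained = {}, {}
    for m in models:
        params, stats_m = sims[m]
        idx = rejection(observed, stats_m, fraction)
        retained[m] = idx
        densities[m] = glm_marginal_density(params[idx], stats_m[idx], observed)
    total = sum(densities.values())
    if total <= 0:
        raise ValueError(
            "all marginal densities are zero; increase the simulation budget"
        )
    posterior = {m: densities[m] / total for m in models}
    with np.errstate(over="ignore", divide="ignore"):
        bf = pd.DataFrame(
            [[densities[a] / densities[b] for b in models] for a in models],
            index=models,
            columns=models,
        )
    # global rejection-count estimator over the pooled simulations
    pooled = np.vstack([sims[m][1] for m in models])
    labels = np.concatenate(
        [np.full(len(sims[m][1]), m) for m in models]
    )
    gidx = rejection(observed, pooled, fraction)
    share = {
        m: float(np.mean(labels[gidx] == m)) for m in models
    }
    return ModelChoiceResult(
        models, densities, posterior, bf, share, retained, fraction
    )


# ---------------------------------------------------------------------------
# PODS cross-validation
# ---------------------------------------------------------------------------

@dataclass
class PodsReport:
    """Cross-validation of the model choice on pseudo-observed datasets."""

    confusion: pd.DataFrame  # rows: true model, cols: chosen; rows sum to 1
    winning_pp: pd.DataFrame  # columns: true_model, chosen_model, pp, correct
    max_false_positive_pp: pd.DataFrame  # rows true, cols chosen (off-diagonal)
    glm_rejection_agreement: float  # share of PODS where both pick one winner

    def false_positive_ceiling(self, chosen: int) -> float:
        """Highest PP ever awarded to ``chosen`` when it was not the
        generating model (the replayable 'PP never reached' argument)."""
        col = self.max_false_positive_pp[chosen]
        off = col[col.index != chosen].dropna()
        return float(off.max()) if len(off) else float("nan")


def pods_validate(
    sims: dict[int, tuple[np.ndarray, np.ndarray]],
    n_pods: int,
    fraction: float = RETENTION_FRACTION,
    seed: int = 0,
) -> PodsReport:
    """Leave-one-out PODS validation.

    For each model, ``n_pods`` simulations are drawn (without
    replacement) to serve as pseudo-observed datasets; each is removed
    from its own model's reference table before the model choice is
    re-run. Deterministic given ``seed``.
    """
    if n_pods < 20:
        raise ValueError("use at least 20 PODS per model")
    rng = np.random.Generator(np.random.PCG64(seed))
    models = tuple(sorted(sims))
    records = []
    agree = 0
    total = 0
    for true_m in models:
        params, stats_m = sims[true_m]
        pick = rng.choice(len(stats_m), size=n_pods, replace=False)
        for i in pick:
            obs = stats_m[i]
            mask = np.arange(len(stats_m)) != i
            sims_loo = dict(sims)
            sims_loo[true_m] = (params[mask], stats_m[mask])
            res = model_choice(obs, sims_loo, fraction)
            chosen = res.best_model
            records.append(
                {
                    "true_model": true_m,
                    "chosen_model": chosen,
                    "pp": res.posterior[chosen],
                    "correct": chosen == true_m,
                }
            )
            agree += chosen == res.best_model_by_rejection
            total += 1
    winning = pd.DataFrame(records)
    confusion = (
        winning.groupby("true_model")["chosen_model"]
        .value_counts(normalize=True)
        .unstack(fill_value=0.0)
        .reindex(index=models, columns=models, fill_value=0.0)
    )
    maxfp = pd.DataFrame(np.nan, index=models, columns=models)
    for (t, c), grp in winning.groupby(["true_model", "chosen_model"]):
        if t != c:
            maxfp.loc[t, c] = grp["pp"].max()
    return PodsReport(confusion, winning, maxfp, agree / total)


# ---------------------------------------------------------------------------
# Convenience: simulate reference tables
# ---------------------------------------------------------------------------

def _flatten_draw(draw: dict) -> np.ndarray:
    return np.concatenate(
        [np.ravel(draw["ne"]), np.ravel(draw["founder"]), np.ravel(draw["imm_rate"])]
    ).astype(float)


def reference_table(
    model_id: int,
    n_reps: int,
    seed: int,
    priors: PriorSpec | None = None,
    n_samples: int = 180,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate ``n_reps`` replicates of one scenario and return the
    (params, stats) arrays used by :func:`model_choice`."""
    params, stats_rows = [], []
    for ds in simulate_batch(model_id, n_reps, seed, priors, n_samples):
        params.append(_flatten_draw(ds.draw))
        stats_rows.append(summary_stats(ds))
    return np.array(params), np.array(stats_rows)
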