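"""Community-pattern statistics for sample x species abundance tables.

Implements the analyses used to compare simulated communities with
survey data: richness vs. environmental harshness, nestedness of
presence/absence matrices (NODF), rarefaction and species-abundance
distributions (Fisher log series and a truncated-Gaussian null),
dissimilarity-overlap analysis, Jensen-Shannon ordination, and the
additivity test for mixed-resource communities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial.distance import jensenshannon
from scipy.stats import norm
from statsmodels.nonparametric.smoothers_lowess import lowess as _lowess

from .scenarios import AbundanceTable

__all__ = [
    "richness_vs_harshness",
    "presence_absence",
    "PresenceAbsenceMatrix",
    "nodf",
    "subsample_reads",
    "FisherFit",
    "fit_fisher",
    "sad_fisher",
    "truncated_gaussian_null",
    "overlap_dissimilarity",
    "DOCResult",
    "doc_analysis",
    "js_distance_matrix",
    "pcoa",
    "additivity_r2",
    "additivity_r2_log",
]

MAX_JS_DISTANCE = np.sqrt(np.log(2.0))


# ---------------------------------------------------------------------------
# richness / harshness

def richness_vs_harshness(
    table: AbundanceTable, n_bins: int = 10, percentile: float = 99.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample (m_env, richness) pairs plus a binned percentile envelope.

    Only converged samples enter; the envelope is the given percentile
    of richness within equal-width harshness bins, mirroring the way
    survey analyses summarize peak richness against pH or temperature.
    """
    conv = table.converged()
    if conv.n_samples == 0:
        raise ValueError("no converged samples")
    points = conv.sample_meta[["m_env", "richness"]].copy()
    edges = np.linspace(points["m_env"].min(), points["m_env"].max(), n_bins + 1)
    edges[-1] += 1e-9
    which = np.digitize(points["m_env"], edges) - 1
    rows = []
    for b in range(n_bins):
        sel = points["richness"].to_numpy()[which == b]
        if sel.size:
            rows.append(
                {
                    "bin_center": 0.5 * (edges[b] + edges[b + 1]),
                    "richness_envelope": float(np.percentile(sel, percentile)),
                    "n": int(sel.size),
                }
            )
    return points, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nestedness

@dataclass
class PresenceAbsenceMatrix:
    """Binary taxa x samples matrix sorted by prevalence and richness."""

    values: np.ndarray          # taxa x samples, {0,1}
    row_order: np.ndarray       # original taxon indices, by prevalence desc
    col_order: np.ndarray       # original sample indices, by richness desc

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.isin(v, (0, 1)).all():
            raise ValueError("presence/absence entries must be 0 or 1")
        self.values = v.astype(int)


def presence_absence(table, threshold: float = 0.0) -> PresenceAbsenceMatrix:
    """Binarize an abundance table and sort rows/columns for nestedness display.

    Rows (taxa) are sorted by prevalence, columns (samples) by richness,
    both descending with ties broken by original index.  ``table`` may
    be an :class:`AbundanceTable` or a samples x taxa array/DataFrame.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if isinstance(table, AbundanceTable):
        values = table.values.to_numpy()
    else:
        values = np.asarray(pd.DataFrame(table), dtype=float)
    pa = (values > threshold).astype(int).T  # taxa x samples
    prevalence = pa.sum(axis=1)
    richness = pa.sum(axis=0)
    row_order = np.lexsort((np.arange(pa.shape[0]), -prevalence))
    col_order = np.lexsort((np.arange(pa.shape[1]), -richness))
    return PresenceAbsenceMatrix(
        values=pa[np.ix_(row_order, col_order)], row_order=row_order, col_order=col_order
    )


def nodf(pa: PresenceAbsenceMatrix | np.ndarray) -> float:
    """Nestedness score (NODF) of a binary matrix, in [0, 100].

    For every pair of rows (and of columns) whose marginal totals
    strictly decrease, the paired overlap is the percentage of the
    poorer row's presences also found in the richer row; equal marginal
    totals contribute zero.  NODF is the mean over all pairs.  Taxa
    never observed and empty samples carry no occupancy information and
    are dropped before scoring.
    """
    m = pa.values if isinstance(pa, PresenceAbsenceMatrix) else np.asarray(pa, dtype=int)
    if m.ndim != 2:
        raise ValueError("need a 2-D matrix")
    m = m[m.sum(axis=1) > 0][:, m.sum(axis=0) > 0]
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("degenerate matrix: need >=2 occupied rows and columns")

    def _pair_scores(mat: np.ndarray) -> list[float]:
        totals = mat.sum(axis=1)
        scores = []
        n = mat.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                hi, lo = (i, j) if totals[i] > totals[j] else (j, i)
                if totals[hi] == totals[lo] or totals[lo] == 0:
                    scores.append(0.0)
                else:
                    shared = int(np.sum(mat[hi] & mat[lo]))
                    scores.append(100.0 * shared / totals[lo])
        return scores

    scores = _pair_scores(m) + _pair_scores(m.T)
    return float(np.mean(scores))


# ---------------------------------------------------------------------------
# rarefaction and species abundance distributions

def subsample_reads(
    counts: np.ndarray, depth: int = 10_000, n_reps: int = 300, rng_seed=None
) -> np.ndarray:
    """Average abundance histogram over repeated rarefactions.

    Each replicate draws ``depth`` reads without replacement
    (multivariate hypergeometric).  Returns an array h where h[n] is
    the mean number of species observed with exactly n reads
    (index 0 unused).
    """
    counts = np.asarray(counts)
    if np.any(counts < 0) or not np.issubdtype(counts.dtype, np.integer):
        raise ValueError("counts must be non-negative integers")
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds total count {total}")
    rng = np.random.default_rng(rng_seed)
    hist = np.zeros(depth + 1)
    for _ in range(n_reps):
        sub = rng.multivariate_hypergeometric(counts, depth, method="marginals")
        h = np.bincount(sub[sub > 0], minlength=depth + 1)
        hist[: h.size] += h
    hist /= n_reps
    hist[0] = 0.0
    return hist


@dataclass(frozen=True)
class FisherFit:
    """Fisher log-series parameters fitted to (S_obs, N_obs)."""

    alpha: float
    x: float
    S_obs: float
    N_obs: float

    def __post_init__(self) -> None:
        S_back = -self.alpha * np.log(1.0 - self.x)
        N_back = self.alpha * self.x / (1.0 - self.x)
        if abs(S_back - self.S_obs) > 1e-9 * self.S_obs:
            raise ValueError("alpha and x do not reproduce S_obs")
        if abs(N_back - self.N_obs) > 1e-9 * self.N_obs:
            raise ValueError("alpha and x do not reproduce N_obs")


def fit_fisher(S_obs: float, N_obs: float) -> FisherFit:
    """Fit the Fisher log series s(n) = (alpha/n) x^n to totals (S, N).

    x solves N/S = x / ((1-x) (-ln(1-x))) by bracketed root-finding;
    alpha follows as -S / ln(1-x).
    """
    if not (0 < S_obs < N_obs):
        raise ValueError("need 0 < S_obs < N_obs for a Fisher fit")
    ratio = N_obs / S_obs

    def f(x: float) -> float:
        return x / ((1.0 - x) * (-np.log1p(-x))) - ratio

    x = brentq(f, 1e-15, 1.0 - 1e-15, xtol=1e-15, rtol=1e-15)
    alpha = -S_obs / np.log1p(-x)
    return FisherFit(alpha=alpha, x=x, S_obs=S_obs, N_obs=N_obs)


def sad_fisher(fit: FisherFit, n) -> np.ndarray:
    """Expected number of species with exactly n individuals."""
    n = np.asarray(n, dtype=float)
    return fit.alpha * fit.x**n / n


def truncated_gaussian_null(
    survival_fraction: float,
    S: int,
    N: int = 1000,
    n_iter: int = 10_000,
    rng_seed=None,
) -> np.ndarray:
    """Abundance histogram under the truncated-Gaussian null model.

    Invasion fitnesses are Gaussian with unit variance and a mean
    chosen so that P(fitness > 0) equals the observed survival
    fraction.  Each iteration draws S fitnesses, keeps the positive
    ones as relative abundances, samples N individuals multinomially,
    and histograms the counts; the returned array is the mean histogram
    (index n holds the mean number of species with n individuals).
    """
    if not (0.0 < survival_fraction < 1.0):
        raise ValueError("survival_fraction must lie in (0, 1)")
    mu = norm.ppf(survival_fraction)  # P(N(mu,1) > 0) = Phi(mu)
    rng = np.random.default_rng(rng_seed)
    hist = np.zeros(N + 1)
    for _ in range(n_iter):
        fitness = rng.normal(mu, 1.0, size=S)
        fitness = fitness[fitness > 0]
        if fitness.size == 0:
            continue
        p = fitness / fitness.sum()
        draws = rng.multinomial(N, p)
        h = np.bincount(draws[draws > 0], minlength=N + 1)
        hist[: h.size] += h
    hist /= n_iter
    hist[0] = 0.0
    return hist


# ---------------------------------------------------------------------------
# dissimilarity-overlap

def overlap_dissimilarity(
    N_mu: np.ndarray, N_nu: np.ndarray
) -> tuple[float, float, int]:
    """Overlap O, dissimilarity D and shared-species count for two samples.

    O is the mean, over the two samples, of the whole-sample relative
    abundance summed over the shared species.  D is the square root of
    the Jensen-Shannon divergence (natural log) between the two
    relative abundance profiles renormalized over the shared pool.  If
    the supports are disjoint, O = 0 and D is returned as NaN.
    """
    N_mu = np.asarray(N_mu, dtype=float)
    N_nu = np.asarray(N_nu, dtype=float)
    if N_mu.shape != N_nu.shape:
        raise ValueError("abundance vectors must be aligned")
    if np.any(N_mu < 0) or np.any(N_nu < 0):
        raise ValueError("abundances must be non-negative")
    tot_mu, tot_nu = N_mu.sum(), N_nu.sum()
    if tot_mu <= 0 or tot_nu <= 0:
        raise ValueError("both samples must have positive total abundance")
    shared = (N_mu > 0) & (N_nu > 0)
    S_dag = int(shared.sum())
    if S_dag == 0:
        return 0.0, float("nan"), 0
    O = 0.5 * (N_mu[shared].sum() / tot_mu + N_nu[shared].sum() / tot_nu)
    hat_mu = N_mu[shared] / N_mu[shared].sum()
    hat_nu = N_nu[shared] / N_nu[shared].sum()
    mean_shared = 0.5 * (hat_mu + hat_nu)

    def _kl(p: np.ndarray, m: np.ndarray) -> float:
        # x log(x/m) -> 0 as x -> 0 (guards underflow to exactly 0)
        pos = p > 0
        return float(np.sum(p[pos] * np.log(p[pos] / m[pos])))

    jsd = 0.5 * (_kl(hat_mu, mean_shared) + _kl(hat_nu, mean_shared))
    D = float(np.sqrt(max(jsd, 0.0)))
    return float(O), D, S_dag


@dataclass
class DOCResult:
    """Pairwise overlap/dissimilarity records plus a smoothed curve."""

    pairs: pd.DataFrame          # sample_mu, sample_nu, overlap, dissimilarity, shared
    curve: pd.DataFrame          # overlap grid with smoothed dissimilarity
    n_disjoint: int              # pairs excluded for empty shared pools
    seed: int | None


def doc_analysis(
    table,
    site_filter: str | None = None,
    n_pairs: int = 10_000,
    rng_seed=None,
    smoothing_fraction: float = 0.3,
) -> DOCResult:
    """Dissimilarity-overlap analysis over random sample pairs.

    Samples ``n_pairs`` unordered pairs uniformly without replacement
    (all pairs if fewer exist), computes (O, D) for each, and smooths D
    against O with locally-weighted linear regression (lowess).
    ``site_filter`` restricts to samples whose site metadata matches.
    """
    if isinstance(table, AbundanceTable):
        conv = table.converged()
        values = conv.values
        if site_filter is not None:
            keep = conv.sample_meta["site"] == site_filter
            values = values.loc[keep.to_numpy(bool)]
    else:
        values = pd.DataFrame(table)
        if site_filter is not None:
            raise ValueError("site_filter requires an AbundanceTable with metadata")
    n = len(values)
    if n < 2:
        raise ValueError("need at least two samples")
    all_pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    rng = np.random.default_rng(rng_seed)
    if n_pairs < len(all_pairs):
        idx = rng.choice(len(all_pairs), size=n_pairs, replace=False)
        chosen = [all_pairs[k] for k in idx]
    else:
        chosen = all_pairs
    arr = values.to_numpy()
    records = []
    n_disjoint = 0
    for i, j in chosen:
        O, D, S_dag = overlap_dissimilarity(arr[i], arr[j])
        if S_dag == 0:
            n_disjoint += 1
            continue
        records.append(
            {
                "sample_mu": values.index[i],
                "sample_nu": values.index[j],
                "overlap": O,
                "dissimilarity": D,
                "shared": S_dag,
            }
        )
    pairs = pd.DataFrame(records)
    if len(pairs) >= 2:
        sm = _lowess(
            pairs["dissimilarity"], pairs["overlap"], frac=smoothing_fraction,
            return_sorted=True,
        )
        curve = pd.DataFrame({"overlap": sm[:, 0], "dissimilarity_smoothed": sm[:, 1]})
    else:
        curve = pd.DataFrame(columns=["overlap", "dissimilarity_smoothed"])
    return DOCResult(pairs=pairs, curve=curve, n_disjoint=n_disjoint, seed=rng_seed)


# ---------------------------------------------------------------------------
# ordination

def js_distance_matrix(table, level: str = "species") -> pd.DataFrame:
    """Pairwise Jensen-Shannon distances between sample composition profiles.

    The distance is the square root of the Jensen-Shannon divergence
    (natural log) between relative-abundance profiles, optionally after
    aggregating species into families (level="family").
    """
    if isinstance(table, AbundanceTable):
        values = table.values
        if level == "family":
            fam = table.species_meta["family"]
            values = values.T.groupby(fam.to_numpy()).sum().T
        elif level != "species":
            raise ValueError("level must be 'species' or 'family'")
    else:
        values = pd.DataFrame(table)
    arr = values.to_numpy(dtype=float)
    if np.any(arr.sum(axis=1) <= 0):
        raise ValueError("every sample needs positive total abundance")
    rel = arr / arr.sum(axis=1, keepdims=True)
    n = rel.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jensenshannon(rel[i], rel[j], base=np.e)
    return pd.DataFrame(d, index=values.index, columns=values.index)


def pcoa(distances: pd.DataFrame | np.ndarray, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical metric scaling (principal coordinate analysis).

    Double-centers the squared distance matrix, eigendecomposes it, and
    returns coordinates along the top-k positive-eigenvalue axes scaled
    by the square roots of the eigenvalues, together with the full
    non-negative eigenvalue spectrum.
    """
    D = np.asarray(pd.DataFrame(distances), dtype=float)
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(evals.max(), 0) * 1e-12
    n_neg = int(np.sum(evals < -max(evals.max(), 0) * 1e-12))
    if n_neg:
        logging.getLogger(__name__).info(
            "pcoa: dropped %d negative eigenvalues (non-Euclidean distances)", n_neg
        )
    evals_pos, evecs_pos = evals[pos], evecs[:, pos]
    k_eff = min(k, evals_pos.size)
    coords = evecs_pos[:, :k_eff] * np.sqrt(evals_pos[:k_eff])
    index = (
        distances.index if isinstance(distances, pd.DataFrame) else pd.RangeIndex(n)
    )
    cols = [f"PC{i + 1}" for i in range(k_eff)]
    return pd.DataFrame(coords, index=index, columns=cols), evals_pos


# ---------------------------------------------------------------------------
# mixture additivity

def additivity_r2(
    N_mix: np.ndarray, N_1: np.ndarray, N_2: np.ndarray, a: float
) -> tuple[np.ndarray, float]:
    """Weighted-average prediction of a mixture community and its R^2.

    The prediction for species abundances on a (1-a, a) resource
    mixture is (1-a) N_1 + a N_2; R^2 = 1 - SS_res / SS_tot with SS_tot
    taken about the mean observed mixture abundance.
    """
    N_mix = np.asarray(N_mix, dtype=float)
    N_1 = np.asarray(N_1, dtype=float)
    N_2 = np.asarray(N_2, dtype=float)
    if not (N_mix.shape == N_1.shape == N_2.shape):
        raise ValueError("abundance vectors must be aligned")
    if not (0.0 <= a <= 1.0):
        raise ValueError("mixing fraction a must lie in [0, 1]")
    pred = (1.0 - a) * N_1 + a * N_2
    ss_tot = float(np.sum((N_mix - N_mix.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed mixture abundances have zero variance")
    ss_res = float(np.sum((N_mix - pred) ** 2))
    return pred, 1.0 - ss_res / ss_tot


def additivity_r2_log(
    N_mix: np.ndarray, N_1: np.ndarray, N_2: np.ndarray, a: float
) -> tuple[np.ndarray, float]:
    """Additivity R^2 on logarithmic abundances.

    Steady-state abundances span several decades, and the scatter of
    observed versus predicted mixture abundances is naturally assessed
    on log axes: R^2 is computed between log N_mix and
    log[(1-a) N_1 + a N_2] over the species with positive observed and
    predicted abundance.  This is the score used for quantitative
    comparison of mixture experiments; the linear-scale variant above
    is dominated entirely by the few most abundant species.
    """
    N_mix = np.asarray(N_mix, dtype=float)
    pred = (1.0 - a) * np.asarray(N_1, dtype=float) + a * np.asarray(N_2, dtype=float)
    if not (0.0 <= a <= 1.0):
        raise ValueError("mixing fraction a must lie in [0, 1]")
    pos = (N_mix > 0) & (pred > 0)
    if pos.sum() < 3:
        raise ValueError("too few co-occurring species for a log-scale R^2")
    lo = np.log(N_mix[pos])
    lp = np.log(pred[pos])
    ss_tot = float(np.sum((lo - lo.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("observed mixture abundances have zero log-variance")
    r2 = 1.0 - float(np.sum((lo - lp) ** 2)) / ss_tot
    return pred, r2
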