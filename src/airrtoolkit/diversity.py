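"""Repertoire diversity: closed-form indices, bootstrapped comparisons,
Hill-number rarefaction/extrapolation, and STARTRAC indices.

All entropies use natural logarithms.  Two distinct resampling schemes are
used and named accordingly: *downsampling* (without replacement, used to
equalise repertoire depth before comparing indices across groups) and the
*multinomial bootstrap* (with replacement from the empirical clone
frequencies, used for rarefaction confidence intervals).

Sample-size-based interpolation follows the standard Hill-number estimators:
richness (q=0) uses the exact hypergeometric expectation, Shannon diversity
(q=1) the expected-frequency-counts estimator, and Simpson diversity (q=2)
the unbiased closed form valid at every sample size.  Extrapolation beyond
the observed depth uses the Chao1-based asymptote for q=0 and, for q=1, a
mixture approaching the asymptotic entropy estimator of the
singleton/doubleton-corrected form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import (
    GridOutOfRange,
    GroupTooSmall,
    InvalidCounts,
    InvalidOrder,
    MissingLabel,
)

ALL_METRICS = ("shannon", "inv_simpson", "norm_entropy", "gini_simpson", "chao1")


def _as_counts(counts) -> np.ndarray:
    if isinstance(counts, dict):
        counts = list(counts.values())
    x = np.asarray(pd.Series(counts).to_numpy(), dtype=float)
    if x.size == 0:
        raise InvalidCounts("empty count vector")
    if np.any(x <= 0) or np.any(x != np.floor(x)):
        raise InvalidCounts("clone counts must be positive integers")
    return x


def diversity_indices(counts, metrics=ALL_METRICS) -> dict[str, float]:
    """Closed-form diversity indices of one clone count vector.

    With p_i = x_i / n: ``shannon`` is H = -sum p_i ln p_i; ``inv_simpson``
    is 1 / sum p_i^2; ``norm_entropy`` is H / ln S (0 when S = 1);
    ``gini_simpson`` is 1 - sum p_i^2; ``chao1`` is the bias-corrected
    richness estimate S + f1(f1 - 1) / (2 (f2 + 1)) from singleton and
    doubleton counts.
    """
    x = _as_counts(counts)
    n = x.sum()
    p = x / n
    S = x.size
    out: dict[str, float] = {}
    H = float(-np.sum(p * np.log(p)))
    simpson = float(np.sum(p**2))
    for m in metrics:
        if m == "shannon":
            out[m] = H
        elif m == "inv_simpson":
            out[m] = 1.0 / simpson
        elif m == "norm_entropy":
            out[m] = 0.0 if S == 1 else H / np.log(S)
        elif m == "gini_simpson":
            out[m] = 1.0 - simpson
        elif m == "chao1":
            f1 = int(np.sum(x == 1))
            f2 = int(np.sum(x == 2))
            out[m] = S + f1 * (f1 - 1) / (2.0 * (f2 + 1))
        else:
            raise ValueError(f"unknown metric {m!r}")
    return out


@dataclass
class DiversityResult:
    """Bootstrapped diversity summary for one group and metric."""

    group: str
    metric: str
    point: float
    boot_mean: float
    boot_sd: float
    n_boot: int
    n_downsample: int


def _expand_labels(counts: pd.Series) -> np.ndarray:
    """Cell-level clone indices from a clone count column."""
    nz = counts[counts > 0]
    return np.repeat(np.arange(nz.size), nz.to_numpy(dtype=int))


def bootstrapped_diversity(
    counts_by_group: pd.DataFrame,
    metrics=("shannon", "inv_simpson"),
    n_boot: int = 100,
    downsample_to="min",
    seed: int | None = None,
) -> pd.DataFrame:
    """Depth-equalised diversity across groups.

    Each replicate draws ``downsample_to`` cells *without replacement* from a
    group's cell-level clone labels (default: the smallest group's size) and
    recomputes the indices; the mean and standard deviation over ``n_boot``
    replicates are reported next to the full-depth point estimate.
    """
    sizes = counts_by_group.sum(axis=0)
    m = int(sizes.min()) if downsample_to == "min" else int(downsample_to)
    if m < 2:
        raise GroupTooSmall("downsampling target must be at least 2")
    if (sizes < m).any():
        small = list(sizes.index[sizes < m])
        raise GroupTooSmall(f"groups smaller than downsample target {m}: {small}")
    rng = np.random.default_rng(seed)
    rows = []
    for g in counts_by_group.columns:
        col = counts_by_group[g]
        labels = _expand_labels(col)
        point = diversity_indices(col[col > 0], metrics=metrics)
        boots = {met: np.empty(n_boot) for met in metrics}
        for b in range(n_boot):
            draw = rng.choice(labels, size=m, replace=False)
            sub = np.bincount(draw)
            vals = diversity_indices(sub[sub > 0], metrics=metrics)
            for met in metrics:
                boots[met][b] = vals[met]
        for met in metrics:
            rows.append(
                DiversityResult(
                    group=str(g),
                    metric=met,
                    point=point[met],
                    boot_mean=float(boots[met].mean()),
                    boot_sd=float(boots[met].std(ddof=1)) if n_boot > 1 else 0.0,
                    n_boot=n_boot,
                    n_downsample=m,
                ).__dict__
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hill-number rarefaction / extrapolation
# ---------------------------------------------------------------------------


def _log_choose(a, b):
    """log C(a, b) with gammaln; caller guarantees 0 <= b <= a."""
    return gammaln(a + 1.0) - gammaln(b + 1.0) - gammaln(a - b + 1.0)


def _hill_q0_interp(x: np.ndarray, n: int, m: int) -> float:
    """Exact expected richness of an m-subsample (hypergeometric)."""
    S = x.size
    ok = x <= n - m
    if not np.any(ok):
        return float(S)
    terms = np.exp(_log_choose(n - x[ok], m) - _log_choose(n, m))
    return float(S - terms.sum())


def _chao1_unseen(x: np.ndarray, n: int) -> float:
    f1 = int(np.sum(x == 1))
    f2 = int(np.sum(x == 2))
    if f1 == 0:
        return 0.0
    if f2 > 0:
        return (n - 1) / n * f1 * f1 / (2.0 * f2)
    return (n - 1) / n * f1 * (f1 - 1) / 2.0


def _hill_q0_extrap(x: np.ndarray, n: int, m: int) -> float:
    S = x.size
    f0 = _chao1_unseen(x, n)
    f1 = int(np.sum(x == 1))
    if f0 == 0.0:
        return float(S)
    mstar = m - n
    return float(S + f0 * (1.0 - (1.0 - f1 / (n * f0 + f1)) ** mstar))


def _entropy_asymptotic(x: np.ndarray, n: int) -> float:
    """Singleton/doubleton-corrected asymptotic Shannon entropy."""
    f1 = int(np.sum(x == 1))
    f2 = int(np.sum(x == 2))
    inv = np.concatenate([[0.0], 1.0 / np.arange(1, n)])  # inv[k] = 1/k
    cum = np.cumsum(inv)  # cum[k] = sum_{j<=k} 1/j
    # sum_{k=x_i}^{n-1} 1/k = cum[n-1] - cum[x_i - 1]
    part1 = float(np.sum(x / n * (cum[n - 1] - cum[(x - 1).astype(int)])))
    if f2 > 0:
        A = 2.0 * f2 / ((n - 1) * f1 + 2.0 * f2) if f1 > 0 else 1.0
    elif f1 > 0:
        A = 2.0 / ((n - 1) * (f1 - 1) + 2.0)
    else:
        A = 1.0
    if A >= 1.0 or f1 == 0:
        return part1
    r = np.arange(1, n)
    bracket = -np.log(A) - float(np.sum((1.0 - A) ** r / r))
    part2 = f1 / n * (1.0 - A) ** (1 - n) * bracket
    return part1 + max(part2, 0.0)


def _hill_q1(x: np.ndarray, n: int, m: int) -> float:
    if m >= n:
        p = x / n
        h_obs = float(-np.sum(p * np.log(p)))
        if m == n:
            return float(np.exp(h_obs))
        h_asy = max(_entropy_asymptotic(x, n), h_obs)
        h = n / m * h_obs + (m - n) / m * h_asy
        return float(np.exp(h))
    # interpolation: expected frequency counts of an m-subsample
    log_cnm = _log_choose(n, m)
    acc = 0.0
    uniq, mult = np.unique(x.astype(int), return_counts=True)
    for xv, w in zip(uniq, mult):
        k_lo = max(1, m - (n - xv))
        k_hi = min(m, xv)
        if k_hi < k_lo:
            continue
        k = np.arange(k_lo, k_hi + 1)
        logw = _log_choose(xv, k) + _log_choose(n - xv, m - k) - log_cnm
        frac = k / m
        acc += w * float(np.sum(-frac * np.log(frac) * np.exp(logw)))
    return float(np.exp(acc))


def _hill_q2(x: np.ndarray, n: int, m: int) -> float:
    s = float(np.sum(x * (x - 1.0)) / (n * (n - 1.0)))
    return 1.0 / (1.0 / m + (1.0 - 1.0 / m) * s)


def _hill_estimate(x: np.ndarray, n: int, m: int, q: int) -> float:
    if m == 1:
        return 1.0
    if q == 0:
        return _hill_q0_interp(x, n, m) if m <= n else _hill_q0_extrap(x, n, m)
    if q == 1:
        return _hill_q1(x, n, m)
    return _hill_q2(x, n, m)


def rarefaction_curve(
    counts,
    q: int = 0,
    m_grid=None,
    n_boot: int = 50,
    endpoint: int | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Hill-number rarefaction and extrapolation curve with bootstrap CIs.

    Parameters
    ----------
    counts
        Clone count vector (all entries >= 1).
    q
        Hill order: 0 (richness), 1 (Shannon diversity), 2 (Simpson).
    m_grid
        Sample sizes to evaluate; defaults to ~40 points spanning
        ``[1, endpoint]``.  Must lie within that interval.
    n_boot
        Multinomial bootstrap replicates for the percentile CI (0 disables).
    endpoint
        Largest extrapolation size; defaults to twice the observed depth.

    Returns
    -------
    pandas.DataFrame
        Columns ``m, estimate, lower, upper, regime`` where regime is
        ``interpolated`` (m < n), ``observed`` (m = n) or ``extrapolated``.
    """
    if q not in (0, 1, 2):
        raise InvalidOrder(f"Hill order must be 0, 1 or 2, got {q}")
    x = _as_counts(counts)
    n = int(x.sum())
    endpoint = int(endpoint) if endpoint is not None else 2 * n
    if m_grid is None:
        grid = np.unique(
            np.clip(np.round(np.linspace(1, endpoint, 40)).astype(int), 1, endpoint)
        )
    else:
        grid = np.asarray(sorted(set(int(m) for m in m_grid)))
        if grid.min() < 1 or grid.max() > endpoint:
            raise GridOutOfRange(
                f"m grid must lie in [1, {endpoint}], got "
                f"[{grid.min()}, {grid.max()}]"
            )
    est = np.array([_hill_estimate(x, n, m, q) for m in grid])
    lower = np.full(grid.size, np.nan)
    upper = np.full(grid.size, np.nan)
    if n_boot and n_boot > 0:
        rng = np.random.default_rng(seed)
        p = x / n
        boot = np.empty((n_boot, grid.size))
        for b in range(n_boot):
            xb = rng.multinomial(n, p)
            xb = xb[xb > 0].astype(float)
            boot[b] = [_hill_estimate(xb, n, m, q) for m in grid]
        lower = np.percentile(boot, 2.5, axis=0)
        upper = np.percentile(boot, 97.5, axis=0)
    regime = np.where(grid < n, "interpolated",
                      np.where(grid == n, "observed", "extrapolated"))
    out = pd.DataFrame(
        {"m": grid, "estimate": est, "lower": lower, "upper": upper,
         "regime": regime}
    )
    out.attrs["q"] = q
    out.attrs["n"] = n
    return out


# ---------------------------------------------------------------------------
# STARTRAC indices
# ---------------------------------------------------------------------------


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-np.sum(p * np.log(p)))


def startrac_indices(
    cells: pd.DataFrame,
    clone_col: str = "clone",
    cluster_col: str = "cluster",
    tissue_col: str = "tissue",
) -> pd.DataFrame:
    """Per-cluster clonal expansion, migration, and transition indices.

    For cluster j with clone-size distribution over N_j distinct clones,
    ``expa`` = 1 - H(p)/ln N_j (missing when N_j <= 1).  ``migr`` is the
    cell-count-weighted mean, over clones present in the cluster, of the
    entropy of each clone's cells across tissues; ``tran`` is the same with
    entropy across clusters.  Both are in nats, zero iff every clone in the
    cluster is tissue- (resp. cluster-) pure.
    """
    for col in (clone_col, cluster_col, tissue_col):
        if col not in cells.columns:
            raise MissingLabel(f"column {col!r} missing")
        if cells[col].isna().any():
            raise MissingLabel(f"column {col!r} has missing values")
    clone_tissue = pd.crosstab(cells[clone_col], cells[tissue_col])
    clone_cluster = pd.crosstab(cells[clone_col], cells[cluster_col])
    h_tissue = clone_tissue.apply(
        lambda r: _entropy(r.to_numpy(dtype=float)), axis=1
    )
    h_cluster = clone_cluster.apply(
        lambda r: _entropy(r.to_numpy(dtype=float)), axis=1
    )
    rows = []
    for clus in sorted(cells[cluster_col].astype(str).unique()):
        sub = cells[cells[cluster_col].astype(str) == clus]
        sizes = sub[clone_col].value_counts()
        nj = sizes.size
        if nj > 1:
            expa = 1.0 - _entropy(sizes.to_numpy(dtype=float)) / np.log(nj)
        else:
            expa = np.nan
        w = sizes
        migr = float((w * h_tissue[w.index]).sum() / w.sum())
        tran = float((w * h_cluster[w.index]).sum() / w.sum())
        rows.append({"cluster": clus, "expa": expa, "migr": migr, "tran": tran})
    return pd.DataFrame(rows, columns=["cluster", "expa", "migr", "tran"])
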