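"""Microbial ecology network construction.

Four interchangeable constructors build an undirected graph over taxa from an
abundance table:

``build_proxi``
    k-nearest-neighbour proximity graph under the distance
    ``d(u, v) = 1 - |pearson(u, v)|``.
``build_sparcc``
    basis-correlation estimation for compositional data (log-ratio variation
    matrix, sparsity-approximated basis variances, iterative exclusion of the
    most correlated pairs), thresholded on ``|rho|``.
``build_mb``
    neighbourhood selection: per-taxon L1-penalised regression of the clr
    abundance on all other taxa; OR/AND merge of the neighbourhoods.
``build_rmt``
    Pearson matrix on log abundances, hard threshold chosen automatically by a
    random-matrix criterion (smallest threshold at which the nearest-neighbour
    eigenvalue spacing distribution is consistent with the Poisson law).
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso

from .otu import OTUTable, prevalence_filter, to_relative_abundance

logger = logging.getLogger(__name__)

__all__ = [
    "pearson_matrix",
    "build_proxi",
    "build_sparcc",
    "sparcc_correlations",
    "build_mb",
    "build_rmt",
    "rmt_threshold",
    "write_edge_list",
    "read_edge_list",
]


def _empty_graph(taxa) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(taxa)
    return g


def pearson_matrix(
    table: OTUTable, log_transform: bool = False, pseudo_count: float = 1.0
) -> pd.DataFrame:
    """Taxon-taxon Pearson correlation matrix.

    With ``log_transform`` the values are natural-logged after replacing zeros
    with ``pseudo_count``. Constant columns get correlation 0 with every other
    taxon (logged) instead of propagating NaN; the diagonal stays 1.
    """
    if table.n_samples < 3:
        raise ValueError("correlation requires at least 3 samples")
    x = table.values.copy()
    if log_transform:
        if pseudo_count <= 0 and (x <= 0).any():
            raise ValueError("log transform needs pseudo_count > 0 or all-positive values")
        if pseudo_count > 0:
            x[x == 0] = pseudo_count
        x = np.log(x)
    sd = x.std(axis=0)
    constant = sd == 0
    if constant.any():
        logger.info("constant taxa given correlation 0: %s",
                    [t for t, c in zip(table.taxon_ids, constant) if c])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r = np.atleast_2d(r)
    r[np.isnan(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    return pd.DataFrame(r, index=table.taxon_ids, columns=table.taxon_ids)


# ---------------------------------------------------------------------------
# Proxi
# ---------------------------------------------------------------------------

def build_proxi(
    table: OTUTable, k_neighbors: int = 7, merge_rule: str = "union"
) -> nx.Graph:
    """k-nearest-neighbour proximity graph, distance ``1 - |r|``.

    Each taxon contributes edges to its ``k_neighbors`` closest taxa;
    under the default union rule an edge exists if either endpoint lists the
    other (mutual: both must). Distance ties break on taxon ID.
    """
    if table.n_taxa <= k_neighbors:
        raise ValueError("need more taxa than k_neighbors")
    if merge_rule not in ("union", "mutual"):
        raise ValueError(f"unknown merge_rule: {merge_rule!r}")
    r = pearson_matrix(table).to_numpy()
    dist = 1.0 - np.abs(r)
    taxa = table.taxon_ids
    pos = {t: i for i, t in enumerate(taxa)}
    neighbor_sets: dict[str, set[str]] = {}
    for i, t in enumerate(taxa):
        order = sorted((dist[i, j], taxa[j]) for j in range(len(taxa)) if j != i)
        neighbor_sets[t] = {u for _, u in order[:k_neighbors]}
    g = _empty_graph(taxa)
    for t, nbrs in neighbor_sets.items():
        for u in nbrs:
            if merge_rule == "union" or t in neighbor_sets[u]:
                g.add_edge(t, u, weight=float(abs(r[pos[t], pos[u]])))
    return g


# ---------------------------------------------------------------------------
# SparCC
# ---------------------------------------------------------------------------

def _smoothed_fractions(table: OTUTable, pseudo_count: float,
                        nominal_depth: float = 10_000.0) -> np.ndarray:
    """Relative abundances smoothed with ``pseudo_count`` units at a nominal
    depth, so the estimate depends only on each sample's composition."""
    frac = to_relative_abundance(table).values
    d = frac.shape[1]
    return (frac * nominal_depth + pseudo_count) / (nominal_depth + pseudo_count * d)


def sparcc_correlations(
    table: OTUTable,
    pseudo_count: float = 1.0,
    n_exclusion_iters: int = 10,
    exclusion_threshold: float = 0.1,
) -> pd.DataFrame:
    """Estimate basis correlations for compositional data.

    Implements the basis-variance procedure: variation matrix
    ``t_uv = var(log(f_u / f_v))``, the sparsity approximation turning row
    sums of ``t`` into a linear system for the basis variances ``omega``,
    and ``rho_uv = (omega_u + omega_v - t_uv) / (2 sqrt(omega_u omega_v))``.
    The most correlated pair with ``|rho|`` above ``exclusion_threshold`` is
    excluded and the system re-solved, up to ``n_exclusion_iters`` times.
    Falls back to clipped Pearson on log fractions if the system degenerates.
    """
    if table.n_taxa < 4:
        raise ValueError("the basis-variance system requires at least 4 taxa")
    f = _smoothed_fractions(table, pseudo_count)
    logf = np.log(f)
    d = f.shape[1]
    # variation matrix: var across samples of the pairwise log-ratios
    t = np.var(logf[:, :, None] - logf[:, None, :], axis=0, ddof=1)
    excluded = np.zeros((d, d), dtype=bool)
    rho = None
    for _ in range(n_exclusion_iters + 1):
        include = ~excluded
        np.fill_diagonal(include, False)
        m = include.astype(float)
        np.fill_diagonal(m, include.sum(axis=1) + 1.0)
        t_row = np.where(include, t, 0.0).sum(axis=1)
        try:
            omega = np.linalg.solve(m, t_row)
        except np.linalg.LinAlgError:
            omega = None
        if omega is None or (omega <= 0).any():
            logger.warning("basis-variance system degenerate; "
                           "falling back to Pearson on log fractions")
            r = np.corrcoef(logf, rowvar=False)
            r = np.clip(np.nan_to_num(r), -1.0, 1.0)
            np.fill_diagonal(r, 1.0)
            return pd.DataFrame(r, index=table.taxon_ids, columns=table.taxon_ids)
        denom = 2.0 * np.sqrt(np.outer(omega, omega))
        rho = (omega[:, None] + omega[None, :] - t) / denom
        rho = np.clip(rho, -1.0, 1.0)
        np.fill_diagonal(rho, 1.0)
        # exclude the strongest remaining pair, if any clears the threshold
        cand = np.abs(np.where(include, rho, 0.0))
        i, j = np.unravel_index(np.argmax(cand), cand.shape)
        if cand[i, j] <= exclusion_threshold:
            break
        excluded[i, j] = excluded[j, i] = True
    return pd.DataFrame(rho, index=table.taxon_ids, columns=table.taxon_ids)


def build_sparcc(
    table: OTUTable,
    pseudo_count: float = 1.0,
    n_exclusion_iters: int = 10,
    exclusion_threshold: float = 0.1,
    edge_threshold: float = 0.3,
) -> nx.Graph:
    """Network with an edge wherever the basis correlation ``|rho|`` clears
    ``edge_threshold``."""
    rho = sparcc_correlations(table, pseudo_count, n_exclusion_iters,
                              exclusion_threshold)
    return _threshold_graph(rho, edge_threshold)


def _threshold_graph(corr: pd.DataFrame, threshold: float) -> nx.Graph:
    taxa = list(corr.index)
    g = _empty_graph(taxa)
    r = corr.to_numpy()
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            if abs(r[i, j]) >= threshold:
                g.add_edge(taxa[i], taxa[j], weight=float(r[i, j]))
    return g


# ---------------------------------------------------------------------------
# MB neighbourhood selection
# ---------------------------------------------------------------------------

def _clr(table: OTUTable, pseudo_count: float) -> np.ndarray:
    x = table.values.copy()
    x[x == 0] = pseudo_count
    logx = np.log(x)
    return logx - logx.mean(axis=1, keepdims=True)


def mb_neighborhoods(table: OTUTable, lam: float,
                     pseudo_count: float = 1.0) -> dict[str, set[str]]:
    """L1-penalised neighbourhood of every taxon at one penalty value."""
    z = _clr(table, pseudo_count)
    z = (z - z.mean(axis=0))
    taxa = table.taxon_ids
    out: dict[str, set[str]] = {}
    for i, t in enumerate(taxa):
        others = [j for j in range(len(taxa)) if j != i]
        model = Lasso(alpha=lam, fit_intercept=False, max_iter=5000)
        model.fit(z[:, others], z[:, i])
        out[t] = {taxa[j] for j, c in zip(others, model.coef_) if c != 0.0}
    return out


def build_mb(
    table: OTUTable,
    lambda_grid=None,
    merge_rule: str = "OR",
    density_target: float = 0.05,
    pseudo_count: float = 1.0,
) -> nx.Graph:
    """Neighbourhood-selection network.

    The penalty is chosen per graph: the smallest lambda in the grid whose
    merged graph has edge density at most ``density_target`` (the densest
    graph under the cap); if even the largest lambda is too dense, that
    largest lambda is used with a warning.
    """
    if lambda_grid is None:
        lambda_grid = list(np.geomspace(0.01, 1.0, 10))
    lambda_grid = sorted(float(v) for v in lambda_grid)
    if not lambda_grid:
        raise ValueError("lambda_grid is empty")
    if merge_rule not in ("OR", "AND"):
        raise ValueError(f"unknown merge_rule: {merge_rule!r}")
    n = table.n_taxa
    max_edges = n * (n - 1) / 2
    chosen = None
    for lam in lambda_grid:
        nbrs = mb_neighborhoods(table, lam, pseudo_count)
        g = _merge_neighborhoods(nbrs, table.taxon_ids, merge_rule)
        if g.number_of_edges() / max_edges <= density_target:
            chosen = (lam, g)
            break
    if chosen is None:
        lam = lambda_grid[-1]
        logger.warning("no lambda met density target %.3g; using grid max %.3g",
                       density_target, lam)
        nbrs = mb_neighborhoods(table, lam, pseudo_count)
        chosen = (lam, _merge_neighborhoods(nbrs, table.taxon_ids, merge_rule))
    lam, g = chosen
    g.graph["lambda"] = lam
    return g


def _merge_neighborhoods(nbrs: dict[str, set[str]], taxa, merge_rule: str) -> nx.Graph:
    g = _empty_graph(taxa)
    for t, ns in nbrs.items():
        for u in ns:
            if merge_rule == "OR" or t in nbrs.get(u, set()):
                g.add_edge(t, u)
    return g


# ---------------------------------------------------------------------------
# RMT threshold selection
# ---------------------------------------------------------------------------

def _unfolded_spacings(eigs: np.ndarray, poly_degree: int = 5) -> np.ndarray:
    """Nearest-neighbour spacings after smoothed-staircase unfolding.

    The cumulative spectral staircase (eigenvalue -> rank) is smoothed with a
    low-degree polynomial; unfolded levels are the smoothed cumulative counts,
    whose spacings have mean about 1. Exactly degenerate levels are collapsed
    before fitting; negative fitted spacings are clipped to 0.
    """
    eigs = np.sort(eigs)
    n = len(eigs)
    counts = np.arange(1, n + 1, dtype=float)
    uniq, idx = np.unique(eigs, return_index=True)
    if len(uniq) < poly_degree + 2:
        return np.array([])
    cum = counts[np.r_[idx[1:] - 1, n - 1]]
    coeffs = np.polyfit(uniq, cum, deg=poly_degree)
    unfolded = np.polyval(coeffs, eigs)
    return np.clip(np.diff(np.sort(unfolded)), 0.0, None)


def _poisson_spacing_pvalue(spacings: np.ndarray, n_bins: int = 20) -> float:
    """Chi-square goodness of fit of spacings against the exponential law.

    Bins are equal-probability under Exp(1); their number adapts downward on
    small matrices so expected counts stay around 5 per bin.
    """
    s = spacings[np.isfinite(spacings)]
    s = s[s >= 0]
    if len(s) < 10:
        return 0.0
    n_bins = max(4, min(n_bins, len(s) // 5))
    mean = s.mean()
    if mean <= 0:
        return 0.0
    s = s / mean
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    edges = np.r_[0.0, -np.log1p(-qs), np.inf]
    observed, _ = np.histogram(s, bins=edges)
    expected = len(s) / n_bins
    chi2 = ((observed - expected) ** 2 / expected).sum()
    return float(stats.chi2.sf(chi2, df=n_bins - 1))


def rmt_threshold(
    corr: pd.DataFrame,
    grid=None,
    alpha: float = 0.05,
    n_bins: int = 20,
) -> float:
    """Smallest threshold at which the spacing distribution is Poisson-like.

    Scans thresholds ascending; at each, entries of the correlation matrix
    below the threshold (in absolute value) are zeroed, rows/columns that
    become isolated are dropped, eigenvalue spacings are unfolded and tested
    against the exponential law. The first threshold NOT rejected at
    ``alpha`` is returned; if all are rejected, the grid maximum (logged).
    """
    if grid is None:
        grid = np.arange(0.30, 0.9501, 0.01)
    r = corr.to_numpy().copy()
    np.fill_diagonal(r, 1.0)
    for thr in grid:
        masked = np.where(np.abs(r) >= thr, r, 0.0)
        np.fill_diagonal(masked, 1.0)
        off = masked - np.diag(np.diag(masked))
        keep = np.abs(off).sum(axis=1) > 0
        if keep.sum() < 10:
            continue
        sub = masked[np.ix_(keep, keep)]
        spac = _unfolded_spacings(np.linalg.eigvalsh(sub))
        if spac.size == 0:
            continue
        if _poisson_spacing_pvalue(spac, n_bins=n_bins) >= alpha:
            return float(thr)
    logger.warning("no threshold accepted by the spacing test; using grid max")
    return float(grid[-1])


def build_rmt(
    table: OTUTable,
    prevalence: float = 0.25,
    threshold_mode: str = "auto_rmt",
    fixed_threshold: float | None = None,
    pseudo_count: float = 1.0,
    grid=None,
    alpha: float = 0.05,
    n_bins: int = 20,
) -> nx.Graph:
    """Correlation-threshold network with a random-matrix-selected cutoff.

    Taxa present in fewer than ``prevalence`` of the samples are dropped
    first; correlations are Pearson on log abundances.
    """
    filtered = prevalence_filter(table, prevalence)
    if filtered.n_taxa < 10:
        raise ValueError("fewer than 10 taxa remain after the prevalence filter")
    corr = pearson_matrix(filtered, log_transform=True, pseudo_count=pseudo_count)
    if threshold_mode == "fixed":
        if fixed_threshold is None:
            raise ValueError("fixed mode requires fixed_threshold")
        thr = float(fixed_threshold)
    elif threshold_mode == "auto_rmt":
        thr = rmt_threshold(corr, grid=grid, alpha=alpha, n_bins=n_bins)
    else:
        raise ValueError(f"unknown threshold_mode: {threshold_mode!r}")
    g = _threshold_graph(corr, thr)
    g.graph["threshold"] = thr
    return g


# ---------------------------------------------------------------------------
# Edge-list I/O
# ---------------------------------------------------------------------------

def write_edge_list(g: nx.Graph, path: str | Path) -> None:
    """TSV edge list (taxon_a, taxon_b, weight); node set recoverable from a
    header comment listing isolated nodes."""
    with open(path, "w") as fh:
        isolated = [n for n in sorted(g.nodes) if g.degree(n) == 0]
        fh.write("# isolated_nodes: " + ",".join(isolated) + "\n")
        fh.write("taxon_a\ttaxon_b\tweight\n")
        for u, v, data in sorted(g.edges(data=True)):
            a, b = sorted((u, v))
            fh.write(f"{a}\t{b}\t{data.get('weight', 1.0):.10g}\n")


def read_edge_list(path: str | Path) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# isolated_nodes:"):
            tail = first.split(":", 1)[1].strip()
            if tail:
                g.add_nodes_from(tail.split(","))
            fh.readline()  # header
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0]:
                w = float(parts[2]) if len(parts) > 2 else 1.0
                g.add_edge(parts[0], parts[1], weight=w)
    return g
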