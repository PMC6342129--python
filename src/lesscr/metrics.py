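"""Estimator scoring, convergence diagnostics, and density-surface comparison.

Simulation replicates are scored the standard way for SCR estimator
studies: relative bias ``RB = (1/(theta n)) sum_i (theta_hat_i - theta)``,
across-replicate coefficient of variation ``CV = SD(theta_hat)/mean * 100``,
and 95% credible-interval coverage.  Density surfaces are compared by the
mean relative error (MRE): both maps are restricted to non-buffer cells,
normalized to sum to one, and MRE is the mean absolute per-cell difference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .windows import SpatialDomain

__all__ = [
    "gelman_rubin",
    "relative_bias",
    "coefficient_of_variation",
    "ci_coverage",
    "DensityMap",
    "density_map_from_raster",
    "predicted_density_map",
    "mre",
    "summarize_scenario",
]


def gelman_rubin(chains: np.ndarray) -> float:
    """Brooks-Gelman potential scale-reduction factor (PSRF).

    Parameters
    ----------
    chains
        ``(m, n)`` array of ``m >= 2`` chains with ``n >= 2`` kept draws each.

    Notes
    -----
    With within-chain variance ``W``, between-chain variance ``B`` and
    ``Vhat = (n-1)/n W + B/n``, the PSRF is
    ``sqrt(((m+1)/m) * Vhat/W - (n-1)/(m n))``.  Values below 1 (a
    finite-sample artifact of the (n-1)/n correction, e.g. for identical
    chains) are reported as 1.0; the conventional convergence rule is
    PSRF <= 1.1.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need >= 2 chains (rows) to compute the PSRF")
    m, n = chains.shape
    if n < 2:
        raise ValueError("need >= 2 kept samples per chain")
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0 if b == 0 else float("inf")
    vhat = (n - 1) / n * w + b / n
    psrf2 = (m + 1) / m * vhat / w - (n - 1) / (m * n)
    return max(1.0, float(np.sqrt(max(psrf2, 0.0))))


def relative_bias(estimates: np.ndarray, truth: float) -> float:
    """Mean deviation of per-replicate point estimates from truth, over truth."""
    est = np.asarray(estimates, dtype=float)
    if est.size < 1:
        raise ValueError("need at least one estimate")
    if truth == 0:
        raise ValueError("relative bias undefined for truth = 0")
    return float((est - truth).mean() / truth)


def coefficient_of_variation(estimates: np.ndarray) -> float:
    """Across-replicate CV of point estimates, in percent."""
    est = np.asarray(estimates, dtype=float)
    if est.size < 2:
        raise ValueError("need >= 2 estimates for a CV")
    mean = est.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(est.std(ddof=1) / mean * 100.0)


def ci_coverage(intervals: np.ndarray, truth: float) -> float:
    """Fraction of replicates whose credible interval contains the truth."""
    iv = np.asarray(intervals, dtype=float)
    if iv.ndim != 2 or iv.shape[1] != 2:
        raise ValueError("intervals must be an (n, 2) array of (lo, hi)")
    if np.any(iv[:, 0] > iv[:, 1]):
        raise ValueError("malformed interval with lo > hi")
    inside = (iv[:, 0] <= truth) & (truth <= iv[:, 1])
    return float(inside.mean())


@dataclass(frozen=True)
class DensityMap:
    """A per-cell density raster with its buffer mask.

    ``values[iy, ix]`` is the density of habitat cell (ix, iy); buffer cells
    are flagged for exclusion from map comparisons.  ``normalized`` marks a
    map rescaled to sum to one over non-buffer cells.
    """

    values: np.ndarray
    buffer_mask: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        bm = np.asarray(self.buffer_mask, dtype=bool)
        if v.shape != bm.shape:
            raise ValueError("values and buffer_mask shapes differ")
        if np.any(v < 0):
            raise ValueError("density values must be >= 0")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "buffer_mask", bm)

    def normalize(self) -> "DensityMap":
        """Rescale so the non-buffer cells sum to one."""
        core = self.values[~self.buffer_mask]
        tot = core.sum()
        if tot <= 0:
            raise ValueError("cannot normalize an all-zero map")
        return DensityMap(self.values / tot, self.buffer_mask, normalized=True)


def density_map_from_raster(values: np.ndarray, domain: SpatialDomain) -> DensityMap:
    mask = (
        domain.buffer_mask
        if domain.buffer_mask is not None
        else np.zeros_like(np.asarray(values), dtype=bool)
    )
    return DensityMap(values, mask)


def predicted_density_map(
    results,
    domain: SpatialDomain,
    n_draws: int | None = None,
    seed: int = 0,
) -> DensityMap:
    """Posterior mean density surface from stored AC / inclusion draws.

    For each posterior draw, the half-normal space-use kernel
    ``exp(-d^2 / (2 sigma^2))`` of every included (z = 1) individual is
    evaluated at the habitat cell centers and summed; the map is the average
    over draws.  ``n_draws`` subsamples the kept draws without replacement
    (all draws by default).
    """
    s, z = results.s, results.z
    if s is None or z is None:
        raise ValueError("fit was run with store_sz=False; no s/z draws stored")
    sigma = results.sigma.reshape(-1)
    n_total = s.shape[0]
    rng = np.random.default_rng(seed)
    if n_draws is not None and n_draws < n_total:
        pick = np.sort(rng.choice(n_total, size=n_draws, replace=False))
    else:
        pick = np.arange(n_total)
    cx, cy = domain.cell_centers()
    gx, gy = np.meshgrid(cx, cy, indexing="xy")
    cells = np.column_stack([gx.ravel(), gy.ravel()])
    acc = np.zeros(cells.shape[0])
    for t in pick:
        live = z[t].astype(bool)
        if not live.any():
            continue
        pts = s[t, live]
        d2 = (
            (cells[:, None, 0] - pts[None, :, 0]) ** 2
            + (cells[:, None, 1] - pts[None, :, 1]) ** 2
        )
        acc += np.exp(-d2 / (2.0 * sigma[t] ** 2)).sum(axis=1)
    vals = (acc / len(pick)).reshape(domain.ny, domain.nx)
    return density_map_from_raster(vals, domain)


def mre(true_map: DensityMap, predicted_map: DensityMap, ratio: bool = False) -> float:
    """Mean relative error between two density maps, buffer excluded.

    Both maps are normalized to sum to one over non-buffer cells; the
    default MRE is the mean absolute per-cell difference of the normalized
    maps.  ``ratio=True`` instead averages ``|Dhat - D| / D`` over cells
    with ``D > 0`` (an alternative, non-default reading).
    """
    if true_map.values.shape != predicted_map.values.shape:
        raise ValueError("density maps are on different grids")
    if not np.array_equal(true_map.buffer_mask, predicted_map.buffer_mask):
        raise ValueError("density maps have different buffer masks")
    t = true_map.normalize().values[~true_map.buffer_mask]
    p = predicted_map.normalize().values[~predicted_map.buffer_mask]
    if ratio:
        ok = t > 0
        return float(np.mean(np.abs(p[ok] - t[ok]) / t[ok]))
    return float(np.mean(np.abs(p - t)))


def summarize_scenario(
    replicates: list[dict],
    truth: dict,
    labels: dict | None = None,
    rhat_threshold: float = 1.1,
) -> pd.DataFrame:
    """Scenario-level summary of replicate fits (one row per parameter).

    Each replicate dict carries, per parameter name, ``{"est": point
    estimate, "ci": (lo, hi), "rhat": PSRF}`` and optionally ``"mre"``.
    Replicates with any monitored PSRF above ``rhat_threshold`` are excluded
    (and counted in ``n_excluded``).
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    params = [p for p in truth if p != "mre"]
    kept, excluded = [], 0
    for rep in replicates:
        rhats = [rep[p].get("rhat", 1.0) for p in params if p in rep]
        if any(np.isfinite(r) and r > rhat_threshold for r in rhats):
            excluded += 1
        else:
            kept.append(rep)
    if not kept:
        raise ValueError("no replicate passed the convergence gate")
    rows = []
    mres = [r["mre"] for r in kept if "mre" in r]
    for p in params:
        est = np.array([r[p]["est"] for r in kept])
        ivs = np.array([r[p]["ci"] for r in kept])
        rows.append(
            dict(
                param=p,
                RB=relative_bias(est, truth[p]),
                CV=coefficient_of_variation(est) if len(est) > 1 else np.nan,
                coverage=ci_coverage(ivs, truth[p]),
                MRE=float(np.mean(mres)) if mres else np.nan,
                n_reps=len(kept),
                n_excluded=excluded,
            )
        )
    df = pd.DataFrame(rows)
    for k, v in (labels or {}).items():
        df[k] = v
    return df
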