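"""Posterior results container for fitted SCR models."""

from __future__ import annotations

import json
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .metrics import gelman_rubin

if TYPE_CHECKING:  # pragma: no cover
    from .model import SCRModel

__all__ = ["SCRResults", "PosteriorSamples"]

_SCALAR_PARAMS = ("sigma", "p0", "psi0", "N", "density")


class SCRResults:
    """Thinned posterior samples of a fitted SCR model.

    Holds, per chain, the kept draws of sigma, p0, psi0 and the derived
    abundance ``N = sum(z)`` (density is ``N / area(S)``), plus optional
    activity-center / inclusion snapshots for density mapping.  Point
    estimates are posterior means; intervals are equal-tailed 95% percentile
    intervals; convergence is judged by the Brooks-Gelman potential
    scale-reduction factor.
    """

    def __init__(self, model: "SCRModel", chains: list[dict], config: dict):
        self.model = model
        self._chains = chains
        self.config = config

    # ------------------------------------------------------------------ #
    @property
    def n_chains(self) -> int:
        return len(self._chains)

    @property
    def n_kept(self) -> int:
        return len(self._chains[0]["sigma"]) if self._chains else 0

    def _stack(self, param: str) -> np.ndarray:
        if param == "density":
            return np.stack([c["N"] for c in self._chains]) / self.model.domain.area
        return np.stack([c[param] for c in self._chains])

    @property
    def sigma(self) -> np.ndarray:
        return self._stack("sigma")

    @property
    def p0(self) -> np.ndarray:
        return self._stack("p0")

    @property
    def psi0(self) -> np.ndarray:
        return self._stack("psi0")

    @property
    def N(self) -> np.ndarray:  # noqa: N802 - field name of the model
        return self._stack("N")

    @property
    def density(self) -> np.ndarray:
        return self._stack("density")

    @property
    def s(self) -> np.ndarray | None:
        if self._chains and self._chains[0]["s"] is not None:
            return np.concatenate([c["s"] for c in self._chains], axis=0)
        return None

    @property
    def z(self) -> np.ndarray | None:
        if self._chains and self._chains[0]["z"] is not None:
            return np.concatenate([c["z"] for c in self._chains], axis=0)
        return None

    @property
    def acceptance(self) -> list[dict]:
        return [c["acceptance"] for c in self._chains]

    # ------------------------------------------------------------------ #
    def point_estimate(self, param: str) -> float:
        return float(self._stack(param).mean())

    def ci(self, param: str, level: float = 0.95) -> tuple[float, float]:
        lo = (1 - level) / 2 * 100
        draws = self._stack(param).ravel()
        return (float(np.percentile(draws, lo)), float(np.percentile(draws, 100 - lo)))

    def rhat(self, param: str) -> float:
        if self.n_chains < 2 or self.n_kept < 2:
            return float("nan")
        return gelman_rubin(self._stack(param))

    def converged(self, threshold: float = 1.1) -> bool:
        """True when every monitored scalar has PSRF <= threshold."""
        return all(
            self.rhat(p) <= threshold for p in ("sigma", "p0", "psi0", "N")
        )

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Posterior summary table (mean, sd, CI bounds, PSRF) per parameter."""
        rows = []
        for p in _SCALAR_PARAMS:
            if self.n_kept == 0:
                rows.append(dict(param=p, mean=np.nan, sd=np.nan,
                                 ci_lo=np.nan, ci_hi=np.nan, rhat=np.nan))
                continue
            draws = self._stack(p)
            lo, hi = self.ci(p, level)
            rows.append(
                dict(
                    param=p,
                    mean=float(draws.mean()),
                    sd=float(draws.std(ddof=1)),
                    ci_lo=lo,
                    ci_hi=hi,
                    rhat=self.rhat(p),
                )
            )
        return pd.DataFrame(rows).set_index("param")

    # ------------------------------------------------------------------ #
    def predicted_density_map(self, n_draws: int | None = None, seed: int = 0):
        """Posterior mean density surface; see :func:`lesscr.metrics.predicted_density_map`."""
        from .metrics import predicted_density_map

        return predicted_density_map(self, self.model.domain, n_draws=n_draws, seed=seed)

    def to_csv(self, outdir: str | Path) -> None:
        """One CSV per chain (iteration, sigma, p0, psi0, N, d) + metadata JSON."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        area = self.model.domain.area
        for c, ch in enumerate(self._chains):
            df = pd.DataFrame(
                dict(
                    iteration=np.arange(1, len(ch["sigma"]) + 1),
                    sigma=ch["sigma"],
                    p0=ch["p0"],
                    psi0=ch["psi0"],
                    N=ch["N"],
                    d=ch["N"] / area,
                )
            )
            df.to_csv(outdir / f"chain_{c}.csv", index=False)
        import hashlib

        cfg_hash = hashlib.sha256(
            json.dumps(self.config, sort_keys=True).encode()
        ).hexdigest()[:16]
        meta = dict(
            config=self.config,
            config_hash=cfg_hash,
            master_seed=self.config.get("seed"),
            chain_seeds=[ch["seed"] for ch in self._chains],
            acceptance=self.acceptance,
            area=area,
            n_detected=self.model.n_detected,
            M=self.model.m,
        )
        (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2))


#: Alias: the results object carries the posterior samples.
PosteriorSamples = SCRResults
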