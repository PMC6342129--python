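"""Bayesian SCR model with data augmentation and local state-space evaluation.

The model
---------
Detections of individual ``i`` at detector ``j`` are Bernoulli with the
half-normal detection function ``p_ij = p0 exp(-D_ij^2 / (2 sigma^2))``
where ``D_ij`` is the distance from the latent activity center ``s_i``.
Activity centers are uniform over suitable habitat of the state-space; the
observed individuals are augmented with all-zero pseudo-individuals whose
inclusion flags ``z_i ~ Bernoulli(psi_i)`` make abundance ``N = sum(z)``
estimable.  Each individual's inclusion probability is corrected for the
suitable-habitat fraction of its AC window,

    psi_i = 1 - (1 - psi0)^prop_habitat_i,      psi0 ~ Uniform(0, 1),

so that augmented ACs, which are confined to tiled windows of unequal
usable area, still imply a homogeneous point process over the domain.

Local evaluation (the LESS index) restricts each individual's AC to its AC
window and its likelihood to the detectors inside its detector window;
a model whose windows span the whole domain is exactly the classical
(no-LESS) SCR model and is produced by the same code path.

Fitting is by a bespoke Metropolis-within-Gibbs sampler: reflected
random-walk updates of each AC (non-habitat proposals rejected outright),
exact Bernoulli draws of the inclusion flags from their full conditionals,
and adaptive Metropolis updates of sigma (log scale), p0 and psi0 (logit
scale).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .simulate import CaptureHistory
from .windows import DetectorArray, LESSIndex, SpatialDomain, build_less_index

__all__ = [
    "PriorSpec",
    "MCMCState",
    "SCRModel",
    "psi_individual",
    "spanning_window_params",
]


def psi_individual(psi0, prop_habitat):
    """Per-individual inclusion probability ``1 - (1 - psi0)^prop_habitat``."""
    psi0 = np.asarray(psi0, dtype=float)
    prop = np.asarray(prop_habitat, dtype=float)
    if np.any(psi0 < 0) or np.any(psi0 > 1):
        raise ValueError("psi0 must lie in [0, 1]")
    if np.any(prop < 0) or np.any(prop > 1):
        raise ValueError("prop_habitat must lie in [0, 1]")
    out = -np.expm1(prop * np.log1p(-np.minimum(psi0, 1 - 1e-300)))
    out = np.where(psi0 >= 1, np.where(prop > 0, 1.0, 0.0), out)
    if out.ndim == 0:
        return float(out)
    return out


def spanning_window_params(domain: SpatialDomain) -> tuple[float, float]:
    """(ac_width, extension) making every window span the whole domain.

    With this geometry the local-evaluation model is exactly the classical
    SCR model: every detector window contains all detectors and every AC
    window contains all of S.
    """
    ex, ey = domain.extent
    diag = math.hypot(ex, ey)
    return 2.0 * diag, 0.0


@dataclass(frozen=True)
class PriorSpec:
    """Priors: p0 ~ U(0,1), psi0 ~ U(0,1), sigma ~ U(0, sigma_max).

    ``sigma_max = None`` defaults to the AC window width — the window
    construction already presumes sigma is known to that order.
    """

    sigma_max: float | None = None

    def resolved_sigma_max(self, less: LESSIndex) -> float:
        if self.sigma_max is not None:
            if self.sigma_max <= 0:
                raise ValueError("sigma_max must be > 0")
            return float(self.sigma_max)
        return float(max(w.width for w in less.ac_windows))


@dataclass
class MCMCState:
    """Mutable sampler state (one point in the augmented parameter space)."""

    sx: np.ndarray
    sy: np.ndarray
    z: np.ndarray  # int8, detected entries fixed at 1
    sigma: float
    p0: float
    psi0: float

    def copy(self) -> "MCMCState":
        return MCMCState(
            self.sx.copy(), self.sy.copy(), self.z.copy(),
            self.sigma, self.p0, self.psi0,
        )

    @property
    def psi(self) -> np.ndarray:
        raise AttributeError("psi is derived; use psi_individual(psi0, prop)")

    @property
    def n(self) -> int:
        return int(self.z.sum())


@dataclass
class _Arrays:
    """Flat kernel inputs derived once per model."""

    det_x: np.ndarray
    det_y: np.ndarray
    idx: np.ndarray
    nd: np.ndarray
    ypad: np.ndarray
    win: np.ndarray
    prop: np.ndarray
    hab: np.ndarray
    x0: float
    y0: float
    cell: float
    n_det: int


class SCRModel:
    """Spatial capture-recapture model bound to data and LESS geometry.

    Build with :meth:`from_captures` (local evaluation) or :meth:`no_less`
    (windows spanning the domain, i.e. the classical model); call
    :meth:`fit` to run the MCMC and obtain an :class:`~lesscr.results.SCRResults`.
    """

    def __init__(
        self,
        captures: CaptureHistory,
        detectors: DetectorArray,
        domain: SpatialDomain,
        less: LESSIndex,
        priors: PriorSpec | None = None,
    ):
        if captures.n_detected != less.n_detected:
            raise ValueError("capture rows must align with the LESS index")
        if captures.n_detected and captures.y.shape[1] != detectors.count:
            raise ValueError("capture matrix width must equal detector count")
        self.captures = captures
        self.detectors = detectors
        self.domain = domain
        self.less = less
        self.priors = priors or PriorSpec()
        self.sigma_max = self.priors.resolved_sigma_max(less)
        self._arr = self._build_arrays()

    # ------------------------------------------------------------------ #
    @property
    def m(self) -> int:
        """Total individuals, detected + augmented."""
        return self.less.n_individuals

    @property
    def n_detected(self) -> int:
        return self.less.n_detected

    def _build_arrays(self) -> _Arrays:
        less, dom = self.less, self.domain
        idx = np.ascontiguousarray(less.detector_index)
        nd = np.ascontiguousarray(less.n_detectors)
        m, k = idx.shape
        ypad = np.zeros((m, k), dtype=np.int8)
        y = self.captures.y
        for i in range(less.n_detected):
            ypad[i, : nd[i]] = y[i, idx[i, : nd[i]]]
        return _Arrays(
            det_x=np.ascontiguousarray(self.detectors.x),
            det_y=np.ascontiguousarray(self.detectors.y),
            idx=idx,
            nd=nd,
            ypad=ypad,
            win=np.ascontiguousarray(less.xy_bounds),
            prop=np.ascontiguousarray(less.prop_habitat),
            hab=np.ascontiguousarray(dom.habitat),
            x0=dom.x_min,
            y0=dom.y_min,
            cell=dom.cell_size,
            n_det=less.n_detected,
        )

    # ------------------------------------------------------------------ #
    @classmethod
    def from_captures(
        cls,
        captures: CaptureHistory,
        detectors: DetectorArray,
        domain: SpatialDomain,
        ac_width: float,
        extension: float,
        n_layers: int | None = None,
        expected_n: int | None = None,
        priors: PriorSpec | None = None,
    ) -> "SCRModel":
        """Build the LESS geometry from the data and wrap it in a model."""
        less = build_less_index(
            captures, detectors, domain, ac_width, extension,
            n_layers=n_layers, expected_n=expected_n,
        )
        return cls(captures, detectors, domain, less, priors=priors)

    @classmethod
    def no_less(
        cls,
        captures: CaptureHistory,
        detectors: DetectorArray,
        domain: SpatialDomain,
        n_layers: int | None = None,
        expected_n: int | None = None,
        priors: PriorSpec | None = None,
    ) -> "SCRModel":
        """Classical SCR: the same sampler with domain-spanning windows."""
        import warnings

        ac_width, extension = spanning_window_params(domain)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # oversize-tile warning is expected
            return cls.from_captures(
                captures, detectors, domain, ac_width, extension,
                n_layers=n_layers, expected_n=expected_n, priors=priors,
            )

    # ------------------------------------------------------------------ #
    # sampler surface (unit-testable single updates)
    def loglik_individual(self, i: int, state: MCMCState) -> float:
        """Log-likelihood of individual i's data over its detector window."""
        a = self._arr
        if i < a.n_det and state.z[i] == 0:
            raise ValueError("detected individuals must have z = 1")
        if state.z[i] == 0:
            return 0.0
        return float(
            K.loglik_one(
                state.sx[i], state.sy[i], i, a.idx, a.nd, a.ypad,
                a.det_x, a.det_y, state.p0, state.sigma,
            )
        )

    def total_loglik(self, state: MCMCState) -> float:
        curll = np.zeros(self.m)
        a = self._arr
        return float(
            K.all_loglik(
                state.sx, state.sy, state.z, curll, a.idx, a.nd, a.ypad,
                a.det_x, a.det_y, state.p0, state.sigma, a.n_det,
            )
        )

    def z_conditional(self, i: int, state: MCMCState) -> float:
        """P(z_i = 1 | rest) for augmented individual i (exact Gibbs weight)."""
        a = self._arr
        if i < a.n_det:
            return 1.0
        return float(
            K.z_conditional(
                state.sx[i], state.sy[i], i, a.idx, a.nd, a.det_x, a.det_y,
                state.p0, state.sigma, state.psi0, a.prop[i],
            )
        )

    def update_s(self, state: MCMCState, seed: int, sd: float | np.ndarray = 0.5) -> None:
        """One reflected random-walk sweep over all activity centers (in place)."""
        a = self._arr
        K.seed_rng(int(seed))
        curll = self._fresh_curll(state)
        sds = np.broadcast_to(np.asarray(sd, dtype=float), (self.m,)).copy()
        acc = np.zeros(self.m, dtype=np.int64)
        K.sweep_s(
            state.sx, state.sy, state.z, curll, a.win, a.hab, a.x0, a.y0, a.cell,
            a.idx, a.nd, a.ypad, a.det_x, a.det_y, state.p0, state.sigma,
            a.n_det, sds, acc,
        )

    def update_z(self, state: MCMCState, seed: int) -> None:
        """Exact Gibbs draw of all augmented inclusion flags (in place)."""
        a = self._arr
        K.seed_rng(int(seed))
        curll = self._fresh_curll(state)
        K.sweep_z(
            state.sx, state.sy, state.z, curll, a.prop, state.psi0,
            a.idx, a.nd, a.det_x, a.det_y, state.p0, state.sigma, a.n_det,
        )

    def update_detection_params(
        self, state: MCMCState, seed: int, sd_sigma: float = 0.1, sd_p0: float = 0.3
    ) -> None:
        """One Metropolis update each of sigma and p0 (in place)."""
        a = self._arr
        K.seed_rng(int(seed))
        curll = self._fresh_curll(state)
        tmp = np.empty(self.m)
        state.sigma, _ = K.update_sigma(
            state.sx, state.sy, state.z, curll, tmp, a.idx, a.nd, a.ypad,
            a.det_x, a.det_y, state.p0, state.sigma, self.sigma_max,
            sd_sigma, a.n_det,
        )
        state.p0, _ = K.update_p0(
            state.sx, state.sy, state.z, curll, tmp, a.idx, a.nd, a.ypad,
            a.det_x, a.det_y, state.p0, state.sigma, sd_p0, a.n_det,
        )

    def update_psi0(self, state: MCMCState, seed: int, sd: float = 0.3) -> None:
        """One Metropolis update of psi0 (in place)."""
        K.seed_rng(int(seed))
        state.psi0, _ = K.update_psi0(state.z, self._arr.prop, state.psi0, float(sd))

    def _fresh_curll(self, state: MCMCState) -> np.ndarray:
        a = self._arr
        curll = np.full(self.m, np.inf)
        for i in range(self.m):
            if i >= a.n_det and a.prop[i] <= 0:
                continue
            curll[i] = K.loglik_one(
                state.sx[i], state.sy[i], i, a.idx, a.nd, a.ypad,
                a.det_x, a.det_y, state.p0, state.sigma,
            )
        return curll

    # ------------------------------------------------------------------ #
    def crude_sigma(self) -> float:
        """Moment estimate: RMS per-axis spread of detections about centroids."""
        y = self.captures.y
        coords = self.detectors.coordinates
        ss, k = 0.0, 0
        for i in range(y.shape[0]):
            hit = np.flatnonzero(y[i])
            if hit.size < 2:
                continue
            pts = coords[hit]
            ss += ((pts - pts.mean(axis=0)) ** 2).sum()
            k += 2 * (hit.size - 1)
        if k == 0:
            return 0.2 * self.sigma_max
        return max(math.sqrt(ss / k), 1e-2 * self.sigma_max)

    def crude_p0(self, sigma: float) -> float:
        """Moment estimate from mean detections per detected individual."""
        y = self.captures.y
        if y.shape[0] == 0:
            return 0.1
        per_ind = y.sum() / y.shape[0]
        eff = 2.0 * math.pi * sigma**2  # effective detectors at unit density
        return float(np.clip(per_ind / max(eff, 1.0), 1e-3, 0.5))

    def initial_state(
        self, rng: np.random.Generator, overdisperse: bool = True
    ) -> MCMCState:
        """Starting point: detected ACs at their centroid (nudged into
        suitable habitat if needed), augmented ACs uniform in-window over
        habitat, z ~ Bernoulli(0.5) for augmented, crude overdispersed
        sigma / p0."""
        a = self._arr
        less, dom = self.less, self.domain
        sx = np.empty(self.m)
        sy = np.empty(self.m)
        z = np.ones(self.m, dtype=np.int8)
        for i in range(self.m):
            w = less.ac_windows[i]
            if i >= a.n_det and a.prop[i] <= 0:
                sx[i], sy[i] = (w.x_lo + w.x_hi) / 2, (w.y_lo + w.y_hi) / 2
                z[i] = 0
                continue
            if i < a.n_det:
                cx, cy = (w.x_lo + w.x_hi) / 2, (w.y_lo + w.y_hi) / 2
                if dom.suitable_at(cx, cy):
                    sx[i], sy[i] = cx, cy
                else:
                    sx[i], sy[i] = self._nearest_suitable(w, cx, cy)
            else:
                sx[i], sy[i] = self._uniform_in_window(w, rng)
                z[i] = rng.random() < 0.5
        sig0 = self.crude_sigma()
        p00 = self.crude_p0(sig0)
        if overdisperse:
            sig0 *= math.exp(rng.uniform(-0.5, 0.5))
            lg = math.log(p00 / (1 - p00)) + rng.uniform(-1.0, 1.0)
            p00 = 1.0 / (1.0 + math.exp(-lg))
            psi0 = rng.uniform(0.2, 0.8)
        else:
            psi0 = 0.5
        sig0 = float(np.clip(sig0, 1e-3, 0.9 * self.sigma_max))
        return MCMCState(sx=sx, sy=sy, z=z, sigma=sig0, p0=p00, psi0=psi0)

    def _nearest_suitable(self, w, cx: float, cy: float) -> tuple[float, float]:
        dom = self.domain
        gx, gy = dom.cell_centers()
        mx, my = np.meshgrid(gx, gy, indexing="xy")
        ok = dom.habitat & (
            (mx >= w.x_lo) & (mx < w.x_hi) & (my >= w.y_lo) & (my < w.y_hi)
        )
        if not ok.any():
            raise ValueError(
                "AC window contains no suitable habitat; cannot initialize"
            )
        d2 = (mx - cx) ** 2 + (my - cy) ** 2
        d2[~ok] = np.inf
        iy, ix = np.unravel_index(np.argmin(d2), d2.shape)
        return float(mx[iy, ix]), float(my[iy, ix])

    def _uniform_in_window(self, w, rng: np.random.Generator) -> tuple[float, float]:
        dom = self.domain
        for _ in range(1000):
            x = rng.uniform(w.x_lo, w.x_hi)
            y = rng.uniform(w.y_lo, w.y_hi)
            if dom.suitable_at(x, y):
                return x, y
        return self._nearest_suitable(w, (w.x_lo + w.x_hi) / 2, (w.y_lo + w.y_hi) / 2)

    # ------------------------------------------------------------------ #
    @staticmethod
    def chain_seed(master_seed: int, chain: int) -> int:
        """Chain c's kernel seed: first 32-bit word of SeedSequence([seed, c])."""
        ss = np.random.SeedSequence([int(master_seed), int(chain)])
        return int(ss.generate_state(1)[0] % (2**31 - 1)) + 1

    def fit(
        self,
        n_adapt: int = 1000,
        n_iter: int = 3000,
        n_chains: int = 3,
        thin: int = 3,
        seed: int | None = None,
        store_sz: bool = True,
    ):
        """Run the Metropolis-within-Gibbs sampler.

        Defaults mirror the validation protocol: a 1,000-iteration adaptive
        phase, then 3,000 iterations of three chains thinned by three.
        Chains start from independent overdispersed initial values; the
        kernel seed of chain ``c`` is derived from ``seed`` by
        :meth:`chain_seed`.  Returns an :class:`~lesscr.results.SCRResults`.
        """
        from .results import SCRResults

        if seed is None:
            seed = int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
        a = self._arr
        chains: list[dict] = []
        for c in range(n_chains):
            init_rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), int(c), 0xACC])
            )
            state = self.initial_state(init_rng, overdisperse=True)
            ll0 = self.total_loglik(state)
            if not np.isfinite(ll0):
                raise RuntimeError(
                    f"non-finite log-likelihood at initialization of chain {c} "
                    f"(sigma={state.sigma:.4g}, p0={state.p0:.4g}); "
                    "check detector/AC window geometry"
                )
            sds = np.full(self.m, state.sigma / 2.0)
            out = K.run_chain(
                self.chain_seed(seed, c),
                int(n_adapt), int(n_iter), int(thin),
                state.sx, state.sy, state.z,
                float(state.sigma), float(state.p0), float(state.psi0),
                a.win, a.prop, a.idx, a.nd, a.ypad, a.det_x, a.det_y,
                a.hab, a.x0, a.y0, a.cell,
                a.n_det, self.sigma_max,
                sds, 0.15, 0.3, 0.3,
                bool(store_sz),
            )
            (sig, p0, psi0, nvec, s_out, z_out,
             acc_s, acc_scalar, sds_f, sd_sig, sd_p0, sd_psi0) = out
            chains.append(
                dict(
                    sigma=sig, p0=p0, psi0=psi0, N=nvec,
                    s=s_out if store_sz else None,
                    z=z_out if store_sz else None,
                    acceptance=dict(
                        s_mean=float(acc_s.mean()) if len(acc_s) else 0.0,
                        sigma=float(acc_scalar[0]),
                        p0=float(acc_scalar[1]),
                        psi0=float(acc_scalar[2]),
                    ),
                    proposal_sd=dict(
                        sigma=float(sd_sig), p0=float(sd_p0), psi0=float(sd_psi0)
                    ),
                    seed=self.chain_seed(seed, c),
                )
            )
        return SCRResults(
            model=self,
            chains=chains,
            config=dict(
                n_adapt=n_adapt, n_iter=n_iter, n_chains=n_chains,
                thin=thin, seed=int(seed), store_sz=bool(store_sz),
            ),
        )
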