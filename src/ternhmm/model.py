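"""Two-state (general N-state) movement HMM with pooling and covariate variants.

The observed process is the bivariate (step length, turning angle) series of
a 1 Hz track; conditional on the latent behavioural state, steps are gamma
(mean/sd parametrisation) and angles are von Mises.  The latent process is a
first-order Markov chain whose transition probabilities may depend on the
distance to the breeding colony through a multinomial logit.  Seven model
variants are supported:

====== ============================ =============================
model  pooling                      covariate (distance to colony)
====== ============================ =============================
0      state + observed pooled      none
1      per-track transition matrix  none
2      per-track step parameters    none
3      both per-track               none
4      pooled                       on the state process
5      pooled                       on the step mean and sd
6      pooled                       on both processes
====== ============================ =============================

Usage follows the Model/Results convention::

    model = ForagingHMM(series_list, spec=0)
    res = model.fit(n_restarts=25, seed=1)
    res.summary(); res.aic; res.viterbi(); res.prob_foraging()

Angle parameters are always pooled across tracks; the first turning angle of
every track is undefined and contributes only its step density.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special

from ._kernels import forward_loglik, forward_backward, viterbi_path
from .distributions import transition_matrix
from .tracks import StepAngleSeries, FORAGING, NOT_FORAGING

__all__ = [
    "HMMSpec",
    "ForagingHMM",
    "ForagingHMMResults",
    "fit",
    "FitError",
    "ModelSpecError",
    "AmbiguousStateError",
]

#: model_id -> (pool_state, pool_observed, covariate_on_state, covariate_on_observed)
MODEL_TABLE = {
    0: (True, True, False, False),
    1: (False, True, False, False),
    2: (True, False, False, False),
    3: (False, False, False, False),
    4: (True, True, True, False),
    5: (True, True, False, True),
    6: (True, True, True, True),
}

MODEL_DESCRIPTIONS = {
    0: "Complete pool",
    1: "No pool on transition matrix",
    2: "No pool on step",
    3: "No pool on transition matrix and step",
    4: "Covariate on transition matrix",
    5: "Covariate on step",
    6: "Covariate on transition matrix and step",
}


class FitError(RuntimeError):
    """All restarts of the numerical MLE failed."""


class ModelSpecError(ValueError):
    """The model variant is incompatible with the supplied data."""


class AmbiguousStateError(ValueError):
    """States cannot be labelled (equal fitted mean steps)."""


@dataclass(frozen=True)
class HMMSpec:
    """Pooling / covariate flags of one model variant."""

    model_id: int
    pool_state: bool
    pool_observed: bool
    covariate_on_state: bool
    covariate_on_observed: bool

    @classmethod
    def from_model_id(cls, model_id: int) -> "HMMSpec":
        if model_id not in MODEL_TABLE:
            raise ModelSpecError(f"unknown model id {model_id}; expected 0-6")
        return cls(model_id, *MODEL_TABLE[model_id])

    @property
    def description(self) -> str:
        return MODEL_DESCRIPTIONS.get(self.model_id, "custom")


def _offdiag_to_matrix(vec: np.ndarray, n: int) -> np.ndarray:
    """Scatter a length N(N-1) vector into an (N, N) matrix with zero diagonal."""
    mat = np.zeros((n, n))
    mat[~np.eye(n, dtype=bool)] = vec
    return mat


class _ParamLayout:
    """Maps the flat working-parameter vector onto named natural blocks.

    Working scale: log for mu, sigma, kappa; multinomial logits (first state
    as reference) for delta; free coefficients for the transition and step
    covariate links; rho bounded to [-pi, pi] (the von Mises density is
    periodic, so the bound loses nothing).
    """

    def __init__(self, spec: HMMSpec, n_states: int, n_tracks: int):
        self.spec = spec
        self.n_states = n_states
        self.k_state = 1 if spec.pool_state else n_tracks
        self.k_obs = 1 if spec.pool_observed else n_tracks
        if spec.covariate_on_observed and self.k_obs != 1:
            raise ModelSpecError(
                "step covariates are only supported with pooled step parameters"
            )
        n = n_states
        noff = n * (n - 1)
        fields = [("delta_logit", (self.k_state, n - 1), (-15.0, 15.0)),
                  ("trans_beta0", (self.k_state, noff), (-20.0, 20.0))]
        if spec.covariate_on_state:
            fields.append(("trans_beta1", (self.k_state, noff), (-20.0, 20.0)))
        if spec.covariate_on_observed:
            fields += [("mu_beta0", (n,), (-15.0, 5.0)),
                       ("mu_beta1", (n,), (-10.0, 10.0)),
                       ("sigma_beta0", (n,), (-15.0, 5.0)),
                       ("sigma_beta1", (n,), (-10.0, 10.0))]
        else:
            fields += [("log_mu", (self.k_obs, n), (-15.0, 5.0)),
                       ("log_sigma", (self.k_obs, n), (-15.0, 5.0))]
        fields += [("rho", (n,), (-np.pi, np.pi)),
                   ("log_kappa", (n,), (-8.0, 9.0))]

        self.slices: dict[str, tuple[slice, tuple[int, ...]]] = {}
        self.bounds: list[tuple[float, float]] = []
        pos = 0
        for name, shape, bound in fields:
            size = int(np.prod(shape))
            self.slices[name] = (slice(pos, pos + size), shape)
            self.bounds += [bound] * size
            pos += size
        self.n_params = pos

    def unpack(self, x: np.ndarray) -> dict[str, np.ndarray]:
        return {name: x[sl].reshape(shape) for name, (sl, shape) in self.slices.items()}

    def pack(self, blocks: dict[str, np.ndarray]) -> np.ndarray:
        x = np.empty(self.n_params)
        for name, (sl, shape) in self.slices.items():
            x[sl] = np.asarray(blocks[name], dtype=float).reshape(-1)
        return x


class ForagingHMM:
    """Maximum-likelihood HMM for foraging / not-foraging state inference.

    Parameters
    ----------
    data : sequence of StepAngleSeries
        One observation series per track (or track segment).
    spec : HMMSpec or int
        Model variant (0-6) controlling pooling and covariate structure.
    n_states : int
        Number of latent states; the analysis suite uses 2 (foraging,
        not-foraging) but the recursions are written for general N.
    covariate_center, covariate_scale : float, optional
        Standardisation constants for the distance-to-colony covariate.
        Default: pooled mean and sd of the supplied data.  Pass explicit
        values to interpret coefficients on a known scale.
    standardize_covariate : bool
        If False the raw distance (km) enters the linear predictors.
    """

    def __init__(
        self,
        data: Sequence[StepAngleSeries],
        spec: HMMSpec | int = 0,
        n_states: int = 2,
        covariate_center: float | None = None,
        covariate_scale: float | None = None,
        standardize_covariate: bool = True,
    ):
        if isinstance(spec, int):
            spec = HMMSpec.from_model_id(spec)
        self.spec = spec
        self.n_states = int(n_states)
        self.data = list(data)
        if not self.data:
            raise ModelSpecError("no observation series supplied")
        if (not spec.pool_state or not spec.pool_observed) and len(self.data) < 2:
            raise ModelSpecError(
                f"model {spec.model_id} fits per-track parameters and requires "
                "at least two tracks"
            )
        self.layout = _ParamLayout(spec, self.n_states, len(self.data))

        all_c = np.concatenate([s.dist_colony for s in self.data])
        if standardize_covariate:
            self.covariate_center = (float(np.mean(all_c)) if covariate_center is None
                                     else float(covariate_center))
            scale = float(np.std(all_c)) if covariate_scale is None else float(covariate_scale)
            self.covariate_scale = scale if scale > 0 else 1.0
        else:
            self.covariate_center = 0.0
            self.covariate_scale = 1.0
        self.median_covariate = float(
            np.median((all_c - self.covariate_center) / self.covariate_scale)
        )

        # per-track precomputation: densities reuse log(r), cos/sin(angle)
        self._prep = []
        for s in self.data:
            valid = ~np.isnan(s.angle)
            self._prep.append({
                "r": s.step,
                "log_r": np.log(s.step),
                "cos_psi": np.where(valid, np.cos(s.angle), 0.0),
                "sin_psi": np.where(valid, np.sin(s.angle), 0.0),
                "angle_valid": valid,
                "c": (s.dist_colony - self.covariate_center) / self.covariate_scale,
            })

    # ------------------------------------------------------------------ #
    # likelihood machinery

    def _log_emissions(self, blocks: dict[str, np.ndarray], k: int) -> np.ndarray:
        """Log observation densities, shape (T, N), for track k."""
        p = self._prep[k]
        n = self.n_states
        T = len(p["r"])
        if self.spec.covariate_on_observed:
            c = p["c"][:, None]
            mu = np.exp(blocks["mu_beta0"] + blocks["mu_beta1"] * c)       # (T, N)
            sigma = np.exp(blocks["sigma_beta0"] + blocks["sigma_beta1"] * c)
            shape = (mu / sigma) ** 2
            scale = sigma**2 / mu
            logb = ((shape - 1.0) * p["log_r"][:, None] - p["r"][:, None] / scale
                    - shape * np.log(scale) - special.gammaln(shape))
        else:
            ko = min(k, self.layout.k_obs - 1)
            mu = np.exp(blocks["log_mu"][ko])
            sigma = np.exp(blocks["log_sigma"][ko])
            shape = (mu / sigma) ** 2
            scale = sigma**2 / mu
            logb = ((shape - 1.0) * p["log_r"][:, None] - p["r"][:, None] / scale
                    - (shape * np.log(scale) + special.gammaln(shape)))
        kappa = np.exp(blocks["log_kappa"])
        rho = blocks["rho"]
        log_i0 = np.log(special.i0e(kappa)) + kappa
        vm = (kappa * (p["cos_psi"][:, None] * np.cos(rho)
                       + p["sin_psi"][:, None] * np.sin(rho))
              - np.log(2.0 * np.pi) - log_i0)
        logb = logb + np.where(p["angle_valid"][:, None], vm, 0.0)
        return logb

    def _log_transition(self, blocks: dict[str, np.ndarray], k: int, T: int) -> np.ndarray:
        """Stack of log transition matrices, shape (T-1, N, N), for track k."""
        n = self.n_states
        ks = min(k, self.layout.k_state - 1)
        beta0 = _offdiag_to_matrix(blocks["trans_beta0"][ks], n)
        if self.spec.covariate_on_state:
            beta1 = _offdiag_to_matrix(blocks["trans_beta1"][ks], n)
            # transition t -> t+1 is evaluated at the covariate of the origin step
            c = self._prep[k]["c"][: T - 1]
            eta = beta0[None] + c[:, None, None] * beta1[None]
        else:
            eta = np.broadcast_to(beta0, (T - 1, n, n)).copy()
        idx = np.arange(n)
        eta[:, idx, idx] = 0.0
        return eta - special.logsumexp(eta, axis=2, keepdims=True)

    def _log_delta(self, blocks: dict[str, np.ndarray], k: int) -> np.ndarray:
        ks = min(k, self.layout.k_state - 1)
        logits = np.concatenate([[0.0], blocks["delta_logit"][ks]])
        return logits - special.logsumexp(logits)

    def loglik(self, params: np.ndarray | dict) -> float:
        """Log-likelihood of the data at a working vector or block dict."""
        blocks = params if isinstance(params, dict) else self.layout.unpack(np.asarray(params))
        total = 0.0
        for k, p in enumerate(self._prep):
            T = len(p["r"])
            logb = self._log_emissions(blocks, k)
            loggam = self._log_transition(blocks, k, T)
            logdelta = self._log_delta(blocks, k)
            ll = forward_loglik(np.ascontiguousarray(logdelta),
                                np.ascontiguousarray(loggam),
                                np.ascontiguousarray(logb))
            if not np.isfinite(ll):
                raise FloatingPointError(
                    f"non-finite likelihood on track {self.data[k].track_id!r}"
                )
            total += ll
        return float(total)

    def _negloglik(self, x: np.ndarray) -> float:
        try:
            return -self.loglik(x)
        except FloatingPointError:
            return 1e10

    # ------------------------------------------------------------------ #
    # starting values

    def _data_driven_start(self) -> dict[str, np.ndarray]:
        """Quantile-split starting values, following common HMM practice.

        Steps are split at their pooled median: the lower half seeds the
        short-step (foraging-like) state, the upper half the long-step state.
        States beyond 2 interpolate between the two groups.
        """
        n = self.n_states
        steps = np.concatenate([p["r"] for p in self._prep])
        qs = np.quantile(steps, np.linspace(0, 1, n + 1))
        mus, sds = [], []
        for j in range(n):
            grp = steps[(steps >= qs[j]) & (steps <= qs[j + 1])]
            m = float(np.mean(grp)) if len(grp) else float(np.mean(steps))
            s = float(np.std(grp)) if len(grp) > 1 else 0.5 * m
            mus.append(max(m, 1e-8))
            sds.append(max(s, 0.1 * m, 1e-9))
        kappas = np.linspace(0.5, 5.0, n)
        blocks = {
            "delta_logit": np.zeros((self.layout.k_state, n - 1)),
            "trans_beta0": np.full((self.layout.k_state, n * (n - 1)),
                                   special.logit(0.1)),
            "rho": np.zeros(n),
            "log_kappa": np.log(kappas),
        }
        if self.spec.covariate_on_state:
            blocks["trans_beta1"] = np.zeros((self.layout.k_state, n * (n - 1)))
        if self.spec.covariate_on_observed:
            blocks["mu_beta0"] = np.log(mus)
            blocks["mu_beta1"] = np.zeros(n)
            blocks["sigma_beta0"] = np.log(sds)
            blocks["sigma_beta1"] = np.zeros(n)
        else:
            blocks["log_mu"] = np.tile(np.log(mus), (self.layout.k_obs, 1))
            blocks["log_sigma"] = np.tile(np.log(sds), (self.layout.k_obs, 1))
        return blocks

    def _perturb(self, x0: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        scales = np.empty_like(x0)
        for name, (sl, _) in self.layout.slices.items():
            if name in ("log_mu", "log_sigma", "log_kappa", "mu_beta0", "sigma_beta0"):
                s = 0.4
            elif name in ("rho",):
                s = 0.5
            elif name in ("trans_beta0", "delta_logit"):
                s = 0.7
            else:  # covariate slopes
                s = 0.3
            scales[sl] = s
        x = x0 + rng.normal(0.0, scales)
        lo = np.array([b[0] for b in self.layout.bounds])
        hi = np.array([b[1] for b in self.layout.bounds])
        return np.clip(x, lo + 1e-6, hi - 1e-6)

    # ------------------------------------------------------------------ #
    # fitting

    def fit(
        self,
        n_restarts: int = 25,
        seed: int | None = None,
        tol: float = 1e-8,
        maxiter: int = 1000,
        start_params: np.ndarray | dict | None = None,
    ) -> "ForagingHMMResults":
        """Maximise the likelihood by multi-start quasi-Newton optimisation.

        The first start is the data-driven initial value; the remaining
        ``n_restarts - 1`` starts perturb it with seeded noise.  The best
        converged restart wins.  Deterministic given ``seed``.
        """
        if start_params is None:
            start_blocks = self._data_driven_start()
            x0 = self.layout.pack(start_blocks)
        elif isinstance(start_params, dict):
            x0 = self.layout.pack(start_params)
        else:
            x0 = np.asarray(start_params, dtype=float)

        rng = np.random.default_rng(seed)
        best = None
        best_restart = -1
        n_converged = 0
        for k in range(max(1, n_restarts)):
            xk = x0 if k == 0 else self._perturb(x0, rng)
            try:
                res = optimize.minimize(
                    self._negloglik,
                    xk,
                    method="L-BFGS-B",
                    bounds=self.layout.bounds,
                    options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-7},
                )
            except Exception:  # pragma: no cover - optimizer blow-up
                continue
            if not np.isfinite(res.fun) or res.fun >= 1e10:
                continue
            n_converged += int(res.success)
            if best is None or res.fun < best.fun - 1e-12:
                best = res
                best_restart = k
        if best is None:
            raise FitError(
                f"model {self.spec.model_id}: no restart produced a finite likelihood"
            )
        return ForagingHMMResults(
            model=self,
            working_params=np.asarray(best.x),
            llf=-float(best.fun),
            converged=n_converged > 0,
            n_restarts=max(1, n_restarts),
            n_converged=n_converged,
            restart_seed=seed,
            best_restart=best_restart,
            niter=int(getattr(best, "nit", -1)),
        )


class ForagingHMMResults:
    """Fit results: parameter estimates, likelihood, decoding and summaries."""

    def __init__(self, model, working_params, llf, converged, n_restarts,
                 n_converged, restart_seed, best_restart, niter):
        self.model = model
        self.spec = model.spec
        self.working_params = np.asarray(working_params, dtype=float)
        self.llf = float(llf)
        self.converged = bool(converged)
        self.n_restarts = n_restarts
        self.n_converged = n_converged
        self.restart_seed = restart_seed
        self.best_restart = best_restart
        self.niter = niter
        self._cov = None
        self._posteriors = None

    # -- parameters ----------------------------------------------------- #

    @property
    def n_params(self) -> int:
        return self.model.layout.n_params

    @property
    def aic(self) -> float:
        """Akaike information criterion 2k - 2 log L."""
        return 2.0 * self.n_params - 2.0 * self.llf

    @property
    def blocks(self) -> dict[str, np.ndarray]:
        return self.model.layout.unpack(self.working_params)

    @property
    def params(self) -> dict:
        """Natural-scale parameter estimates.

        Covariate coefficients are reported on the standardised scale used in
        fitting and, for the transition model, also on the raw km scale.
        """
        b = self.blocks
        n = self.model.n_states
        out: dict = {"model_id": self.spec.model_id}
        deltas = np.exp(np.vstack([
            np.concatenate([[0.0], row]) for row in b["delta_logit"]
        ]))
        out["delta"] = deltas / deltas.sum(axis=1, keepdims=True)
        out["trans_beta0"] = np.array(
            [_offdiag_to_matrix(row, n) for row in b["trans_beta0"]])
        if self.spec.covariate_on_state:
            out["trans_beta1"] = np.array(
                [_offdiag_to_matrix(row, n) for row in b["trans_beta1"]])
            scale = self.model.covariate_scale
            center = self.model.covariate_center
            out["trans_beta1_per_km"] = out["trans_beta1"] / scale
            out["trans_beta0_raw"] = out["trans_beta0"] - out["trans_beta1"] * center / scale
        if self.spec.covariate_on_observed:
            for key in ("mu_beta0", "mu_beta1", "sigma_beta0", "sigma_beta1"):
                out[key] = b[key].copy()
            out["mu"] = self.mean_step()
            out["sigma"] = np.exp(b["sigma_beta0"]
                                  + b["sigma_beta1"] * self.model.median_covariate)
        else:
            out["mu"] = np.exp(b["log_mu"])
            out["sigma"] = np.exp(b["log_sigma"])
        out["rho"] = b["rho"].copy()
        out["kappa"] = np.exp(b["log_kappa"])
        return out

    def cov_params(self) -> np.ndarray:
        """Covariance of the working parameters from the numerical Hessian."""
        if self._cov is None:
            from statsmodels.tools.numdiff import approx_hess

            hess = approx_hess(self.working_params, self.model._negloglik)
            self._cov = np.linalg.pinv(hess)
        return self._cov

    def bse(self) -> dict[str, np.ndarray]:
        """Standard errors of each working-parameter block."""
        se = np.sqrt(np.clip(np.diag(self.cov_params()), 0.0, None))
        return {name: se[sl].reshape(shape)
                for name, (sl, shape) in self.model.layout.slices.items()}

    # -- derived quantities --------------------------------------------- #

    def mean_step(self, c: float | None = None) -> np.ndarray:
        """State-wise mean step length (km), shape (k_obs, N).

        With covariate-driven step means, evaluated at standardised covariate
        ``c`` (default: the pooled median).
        """
        b = self.blocks
        if self.spec.covariate_on_observed:
            cc = self.model.median_covariate if c is None else c
            return np.exp(b["mu_beta0"] + b["mu_beta1"] * cc)[None, :]
        return np.exp(b["log_mu"])

    def transition_matrix(self, c: float = 0.0, track: int = 0) -> np.ndarray:
        """Gamma(c) for one track group at standardised covariate value ``c``."""
        b = self.blocks
        n = self.model.n_states
        ks = min(track, self.model.layout.k_state - 1)
        beta0 = _offdiag_to_matrix(b["trans_beta0"][ks], n)
        beta1 = (_offdiag_to_matrix(b["trans_beta1"][ks], n)
                 if self.spec.covariate_on_state else None)
        return transition_matrix(beta0, beta1, c)

    def state_labels(self) -> dict[int, str]:
        """Label the short-step state foraging, the long-step state not-foraging.

        With covariate-driven step means the comparison is made at the median
        standardised covariate.  Only defined for 2-state fits.
        """
        if self.model.n_states != 2:
            raise AmbiguousStateError("state labelling is defined for 2-state fits")
        means = self.mean_step().mean(axis=0)  # average over track groups
        if np.isclose(means[0], means[1]):
            raise AmbiguousStateError(
                f"fitted mean steps coincide ({means}); cannot label states"
            )
        f = int(np.argmin(means))
        return {f: FORAGING, 1 - f: NOT_FORAGING}

    # -- decoding -------------------------------------------------------- #

    def _track_inputs(self, k: int):
        blocks = self.blocks
        T = len(self.model._prep[k]["r"])
        return (np.ascontiguousarray(self.model._log_delta(blocks, k)),
                np.ascontiguousarray(self.model._log_transition(blocks, k, T)),
                np.ascontiguousarray(self.model._log_emissions(blocks, k)))

    def viterbi(self) -> list[np.ndarray]:
        """Global most-probable state sequence per track (0-based indices)."""
        return [viterbi_path(*self._track_inputs(k)) for k in range(len(self.model.data))]

    def local_probabilities(self, kind: str = "smoothed") -> list[np.ndarray]:
        """Per-time state posteriors, (T, N) per track; rows sum to one.

        ``kind="smoothed"`` (default) uses forward-backward P(S_t | x_{1:T});
        ``kind="filtered"`` uses forward-only P(S_t | x_{1:t}).
        """
        if kind == "smoothed":
            if self._posteriors is None:
                self._posteriors = [forward_backward(*self._track_inputs(k))[0]
                                    for k in range(len(self.model.data))]
            return self._posteriors
        if kind != "filtered":
            raise ValueError("kind must be 'smoothed' or 'filtered'")
        out = []
        for k in range(len(self.model.data)):
            logdelta, loggam, logb = self._track_inputs(k)
            T, n = logb.shape
            post = np.empty((T, n))
            alpha = logdelta + logb[0]
            post[0] = np.exp(alpha - special.logsumexp(alpha))
            for t in range(1, T):
                alpha = special.logsumexp(alpha[:, None] + loggam[t - 1], axis=0) + logb[t]
                post[t] = np.exp(alpha - special.logsumexp(alpha))
            out.append(post)
        return out

    def prob_foraging(self, kind: str = "smoothed") -> list[np.ndarray]:
        """Posterior probability of the foraging-labelled state, per track."""
        labels = self.state_labels()
        f = next(i for i, lab in labels.items() if lab == FORAGING)
        return [p[:, f] for p in self.local_probabilities(kind)]

    def decoded_foraging(self) -> list[np.ndarray]:
        """Viterbi decoding mapped to binary foraging (1) / not-foraging (0)."""
        labels = self.state_labels()
        f = next(i for i, lab in labels.items() if lab == FORAGING)
        return [(v == f).astype(int) for v in self.viterbi()]

    def decode(self) -> pd.DataFrame:
        """Per-step decoded output across all tracks."""
        labels = self.state_labels()
        vit = self.viterbi()
        probs = self.prob_foraging()
        frames = []
        for s, v, q in zip(self.model.data, vit, probs):
            frames.append(pd.DataFrame({
                "track_id": s.track_id,
                "t": np.arange(len(s)),
                "step_km": s.step,
                "angle_rad": s.angle,
                "dist_colony_km": s.dist_colony,
                "observed": s.behaviour if s.behaviour is not None else np.nan,
                "viterbi_state": v,
                "label": [labels[int(j)] for j in v],
                "prob_foraging": q,
            }))
        return pd.concat(frames, ignore_index=True)

    # -- reporting -------------------------------------------------------- #

    def summary(self) -> str:
        p = self.params
        lines = [
            f"ForagingHMM results — model {self.spec.model_id} ({self.spec.description})",
            f"  states: {self.model.n_states}   tracks: {len(self.model.data)}   "
            f"observations: {sum(len(s) for s in self.model.data)}",
            f"  log-likelihood: {self.llf:.3f}   n_params: {self.n_params}   "
            f"AIC: {self.aic:.3f}",
            f"  converged restarts: {self.n_converged}/{self.n_restarts} "
            f"(best: #{self.best_restart}, seed={self.restart_seed})",
            "  step length (gamma, km):",
        ]
        mu, sigma = np.atleast_2d(p["mu"]), np.atleast_2d(p["sigma"])
        for g in range(mu.shape[0]):
            grp = "" if mu.shape[0] == 1 else f" [track {g}]"
            lines.append("    " + "  ".join(
                f"state {j}: mu={mu[g, j]:.5f} sd={sigma[g, j]:.5f}"
                for j in range(mu.shape[1])) + grp)
        lines.append("  turning angle (von Mises):")
        lines.append("    " + "  ".join(
            f"state {j}: rho={p['rho'][j]:+.3f} kappa={p['kappa'][j]:.3f}"
            for j in range(len(p["rho"]))))
        gam = self.transition_matrix(self.model.median_covariate
                                     if self.spec.covariate_on_state else 0.0)
        lines.append("  transition matrix"
                     + (" (at median covariate):" if self.spec.covariate_on_state else ":"))
        for row in gam:
            lines.append("    [" + "  ".join(f"{v:.4f}" for v in row) + "]")
        try:
            labels = self.state_labels()
            lines.append("  state labels: "
                         + ", ".join(f"{i} -> {lab}" for i, lab in sorted(labels.items())))
        except AmbiguousStateError:
            lines.append("  state labels: ambiguous")
        return "\n".join(lines)

    # -- serialisation ---------------------------------------------------- #

    def to_json(self) -> dict:
        return {
            "spec": asdict(self.spec),
            "n_states": self.model.n_states,
            "working_params": self.working_params.tolist(),
            "loglik": self.llf,
            "n_params": self.n_params,
            "aic": self.aic,
            "converged": self.converged,
            "n_restarts": self.n_restarts,
            "restart_seed": self.restart_seed,
            "covariate_center": self.model.covariate_center,
            "covariate_scale": self.model.covariate_scale,
            "params": {k: np.asarray(v).tolist() for k, v in self.params.items()
                       if k != "model_id"},
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=2)

    @classmethod
    def from_json(cls, payload: dict, data: Sequence[StepAngleSeries]) -> "ForagingHMMResults":
        spec = HMMSpec(**payload["spec"])
        model = ForagingHMM(
            data, spec, n_states=payload["n_states"],
            covariate_center=payload["covariate_center"],
            covariate_scale=payload["covariate_scale"],
        )
        return cls(model=model,
                   working_params=np.asarray(payload["working_params"]),
                   llf=payload["loglik"], converged=payload["converged"],
                   n_restarts=payload["n_restarts"], n_converged=-1,
                   restart_seed=payload["restart_seed"], best_restart=-1, niter=-1)


def fit(spec, data, n_restarts: int = 25, seed: int | None = None,
        **kwargs) -> ForagingHMMResults:
    """Convenience wrapper: build a :class:`ForagingHMM` and fit it."""
    return ForagingHMM(data, spec, **{
        k: v for k, v in kwargs.items()
        if k in ("n_states", "covariate_center", "covariate_scale", "standardize_covariate")
    }).fit(n_restarts=n_restarts, seed=seed, **{
        k: v for k, v in kwargs.items() if k in ("tol", "maxiter", "start_params")
    })
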