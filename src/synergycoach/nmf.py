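"""Synergy extraction: Lee-Seung multiplicative-update NMF with restarts.

The envelope matrix ``E`` (p muscles x n time points) is factorized as
``E ~= W @ C`` with ``W >= 0`` (p x s muscle weights) and ``C >= 0`` (s x n
activation coefficients), minimizing the Frobenius residual ``||E - WC||_F``.
Multiplicative updates keep both factors nonnegative and never increase the
residual; because the problem is nonconvex, each factorization is restarted
from several random initializations and the lowest-residual run wins.

Reconstruction quality is summarized as variance accounted for (VAF), the
uncentered ratio-of-sums-of-squares convention standard in the synergy
literature::

    VAF = 100 * (1 - ||E - WC||_F^2 / ||E||_F^2)

and per muscle the same ratio restricted to one row.

Orientation note: unlike scikit-learn's (samples x features) convention,
``fit`` takes the field's muscles x time matrix directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

_EPS = 1e-12  # guards update denominators against exact zeros


@dataclass
class SynergyModel:
    """A fitted synergy decomposition of one envelope matrix."""

    W: np.ndarray                      # p x s, each column scaled to unit max
    C: np.ndarray                      # s x n, absorbs the inverse scale
    vaf_total: float                   # %
    vaf_muscle: np.ndarray             # % per muscle
    residual_norm: float               # ||E - WC||_F of the winning restart
    n_iter: int                        # iterations of the winning restart
    seed: int                          # restart seed of the winning run
    vaf_per_synergy: np.ndarray | None = None  # % shares (filled by selection)

    @property
    def n_synergies(self) -> int:
        return self.W.shape[1]


def update_W(E: np.ndarray, W: np.ndarray, C: np.ndarray) -> np.ndarray:
    """One multiplicative W step: W <- W * (E C^T) / (W C C^T)."""
    return W * (E @ C.T) / (W @ (C @ C.T) + _EPS)


def update_C(E: np.ndarray, W: np.ndarray, C: np.ndarray) -> np.ndarray:
    """One multiplicative C step: C <- C * (W^T E) / (W^T W C)."""
    return C * (W.T @ E) / ((W.T @ W) @ C + _EPS)


def compute_vaf(E: np.ndarray, W: np.ndarray,
                C: np.ndarray) -> tuple[float, np.ndarray]:
    """Total and per-muscle variance accounted for (uncentered), in %."""
    E = np.asarray(E, dtype=float)
    sst = np.sum(E ** 2, axis=1)
    if not np.any(sst > 0):
        raise ValueError("VAF undefined for an all-zero matrix")
    R = E - W @ C
    sse = np.sum(R ** 2, axis=1)
    vaf_total = 100.0 * (1.0 - sse.sum() / sst.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        vaf_muscle = 100.0 * (1.0 - sse / sst)
    vaf_muscle[sst == 0] = np.nan
    return float(vaf_total), vaf_muscle


def _mu_run(E: np.ndarray, s: int, rng: np.random.Generator, max_iter: int,
            tol: float, W_fixed: np.ndarray | None = None):
    """One multiplicative-update run from a random init; returns (W, C, res, it)."""
    p, n = E.shape
    scale = max(E.mean(), _EPS)
    if W_fixed is None:
        W = rng.uniform(_EPS, 1.0, size=(p, s)) * np.sqrt(scale)
    else:
        W = W_fixed
    C = rng.uniform(_EPS, 1.0, size=(s, n)) * np.sqrt(scale)
    prev = np.linalg.norm(E - W @ C)
    it = 0
    for it in range(1, max_iter + 1):
        if W_fixed is None:
            W = update_W(E, W, C)
        C = update_C(E, W, C)
        res = np.linalg.norm(E - W @ C)
        if prev > 0 and (prev - res) / prev < tol:
            prev = res
            break
        prev = res
    return W, C, prev, it


class SynergyNMF(BaseEstimator):
    """Muscle-synergy NMF estimator (Lee-Seung multiplicative updates).

    Parameters
    ----------
    n_components : number of synergies ``s`` (1 <= s <= number of muscles).
    n_restarts : random restarts; the lowest-residual run is kept.
    max_iter : iteration cap per restart.
    tol : relative residual-change convergence threshold.
    random_state : master seed; restart seeds are spawned from it.

    Fitted attributes
    -----------------
    W_ : (p, s) muscle weights, each column scaled to unit maximum.
    C_ : (s, n) activation coefficients (inverse scale absorbed, so ``W_ @ C_``
        equals the unnormalized product).
    vaf_total_, vaf_muscle_ : reconstruction VAF in % (overall / per muscle).
    residual_norm_, n_iter_, seed_ : diagnostics of the winning restart.
    """

    def __init__(self, n_components: int = 3, n_restarts: int = 20,
                 max_iter: int = 5000, tol: float = 1e-6,
                 random_state: int | None = None):
        self.n_components = n_components
        self.n_restarts = n_restarts
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    @staticmethod
    def _validate_E(E: np.ndarray) -> np.ndarray:
        E = np.asarray(E, dtype=float)
        if E.ndim != 2:
            raise ValueError("E must be a 2-D muscles x time matrix")
        if np.any(E < 0):
            raise ValueError("E must be nonnegative")
        return E

    def _restart_seeds(self) -> list[np.random.SeedSequence]:
        master = 0 if self.random_state is None else self.random_state
        return [np.random.SeedSequence([master, r])
                for r in range(self.n_restarts)]

    def fit(self, E: np.ndarray, y=None) -> "SynergyNMF":
        E = self._validate_E(E)
        s = self.n_components
        if not (1 <= s <= E.shape[0]):
            raise ValueError(f"n_components={s} outside 1..{E.shape[0]}")
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        best = None
        for r, ss in enumerate(self._restart_seeds()):
            rng = np.random.default_rng(ss)
            W, C, res, it = _mu_run(E, s, rng, self.max_iter, self.tol)
            if best is None or res < best[2]:
                best = (W, C, res, it, r)
        W, C, res, it, r = best
        # scale W columns to unit max, absorb the inverse into C
        scale = W.max(axis=0)
        scale[scale == 0] = 1.0
        self.W_ = W / scale
        self.C_ = C * scale[:, None]
        self.residual_norm_ = float(res)
        self.n_iter_ = it
        self.seed_ = r
        self.vaf_total_, self.vaf_muscle_ = compute_vaf(E, self.W_, self.C_)
        return self

    def transform(self, E: np.ndarray, max_iter: int | None = None,
                  tol: float | None = None) -> np.ndarray:
        """Fit activation coefficients for new data with ``W_`` held fixed."""
        E = self._validate_E(E)
        C, _ = fit_C_fixed_W(E, self.W_, max_iter or self.max_iter,
                             tol if tol is not None else self.tol,
                             self.random_state)
        return C

    def fit_transform(self, E: np.ndarray, y=None) -> np.ndarray:
        return self.fit(E).C_

    def to_model(self) -> SynergyModel:
        return SynergyModel(W=self.W_, C=self.C_, vaf_total=self.vaf_total_,
                            vaf_muscle=self.vaf_muscle_,
                            residual_norm=self.residual_norm_,
                            n_iter=self.n_iter_, seed=self.seed_)


def factorize(E: np.ndarray, s: int, n_restarts: int = 20,
              max_iter: int = 5000, tol: float = 1e-6,
              seed: int | None = None) -> SynergyModel:
    """Best-of-restarts NMF of an envelope matrix; see :class:`SynergyNMF`."""
    est = SynergyNMF(n_components=s, n_restarts=n_restarts, max_iter=max_iter,
                     tol=tol, random_state=seed)
    return est.fit(E).to_model()


def fit_C_fixed_W(E: np.ndarray, W_fixed: np.ndarray, max_iter: int = 2000,
                  tol: float = 1e-6,
                  seed: int | None = None) -> tuple[np.ndarray, float]:
    """Multiplicative C-only fit with fixed muscle weights.

    Used for fixed-vector cross-validation: a reference group's ``W`` is held
    constant while a subject's activation coefficients are refit from a random
    initialization until convergence.  Returns ``(C, vaf_total)``.
    """
    E = SynergyNMF._validate_E(E)
    W = np.asarray(W_fixed, dtype=float)
    if np.any(W < 0):
        raise ValueError("W_fixed must be nonnegative")
    if np.any(W.max(axis=0) == 0):
        raise ValueError("W_fixed has an all-zero column")
    rng = np.random.default_rng(np.random.SeedSequence(
        [0 if seed is None else seed, 0x5EED]))
    _, C, _, _ = _mu_run(E, W.shape[1], rng, max_iter, tol, W_fixed=W)
    vaf, _ = compute_vaf(E, W, C)
    return C, vaf
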