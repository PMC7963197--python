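"""Synergy-count selection and cross-model synergy matching.

The number of synergies is the smallest model order whose total VAF reaches
90% while every synergy contributes at least 5% of VAF.  The per-synergy
contribution is the incremental VAF between consecutive model orders
(``vaf_curve[s] - vaf_curve[s-1]``, with ``vaf_curve[0] = 0``), which is
monotone-compatible and sums exactly to the model's total VAF.

NMF returns synergies in arbitrary order, so models are aligned to a reference
by the permutation maximizing the summed Pearson correlation between muscle
weight vectors (optimal assignment), replacing manual sorting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .nmf import SynergyModel, factorize
from .preprocess import MUSCLES


@dataclass
class SelectionResult:
    chosen_s: int
    vaf_curve: np.ndarray              # vaf_total for s = 1..len(curve)
    per_synergy_share: np.ndarray      # incremental VAF % within the chosen model
    vaf_muscle_at_chosen: np.ndarray   # per-muscle VAF % of the chosen model
    flagged: bool                      # True if no s met both criteria
    models: dict[int, SynergyModel] = field(default_factory=dict)


def select_num_synergies(E: np.ndarray, s_max: int | None = None,
                         vaf_threshold: float = 90.0,
                         share_threshold: float = 5.0,
                         early_stop: bool = True,
                         **nmf_kwargs) -> SelectionResult:
    """Pick the synergy count by the 90%-VAF / 5%-per-synergy rule.

    Runs :func:`factorize` for increasing ``s``; stops at the first order
    meeting both criteria (every order below it has already failed, so it is
    the smallest).  If no order up to ``s_max`` qualifies, returns the order
    maximizing VAF among those whose synergies all clear the share rule
    (falling back to the best VAF overall) with ``flagged=True``.
    """
    E = np.asarray(E, dtype=float)
    p = E.shape[0]
    s_max = p if s_max is None else min(s_max, p)
    vaf_curve: list[float] = []
    models: dict[int, SynergyModel] = {}
    chosen = None
    for s in range(1, s_max + 1):
        model = factorize(E, s, **nmf_kwargs)
        models[s] = model
        vaf_curve.append(model.vaf_total)
        shares = np.diff([0.0] + vaf_curve)
        if vaf_curve[-1] >= vaf_threshold and np.all(shares >= share_threshold):
            chosen = s
            if early_stop:
                break
    curve = np.asarray(vaf_curve)
    flagged = chosen is None
    if flagged:
        all_shares = np.diff(np.concatenate(([0.0], curve)))
        ok = [s for s in range(1, curve.size + 1)
              if np.all(all_shares[:s] >= share_threshold)]
        chosen = max(ok, key=lambda s: curve[s - 1]) if ok else \
            int(np.argmax(curve)) + 1
    shares = np.diff(np.concatenate(([0.0], curve[:chosen])))
    model = models[chosen]
    model.vaf_per_synergy = shares
    return SelectionResult(chosen_s=chosen, vaf_curve=curve,
                           per_synergy_share=shares,
                           vaf_muscle_at_chosen=model.vaf_muscle,
                           flagged=flagged, models=models)


def vaf_muscle_screen(model: SynergyModel, threshold: float = 75.0,
                      labels: list[str] | None = None) -> list[str]:
    """Muscles whose per-muscle VAF falls below the threshold (report only)."""
    labels = labels or list(MUSCLES)[:model.vaf_muscle.size]
    return [labels[i] for i, v in enumerate(model.vaf_muscle) if v < threshold]


def _column_correlations(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pearson correlation of every column of A with every column of B."""
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    na = np.linalg.norm(Ac, axis=0)
    nb = np.linalg.norm(Bc, axis=0)
    na[na == 0] = np.inf
    nb[nb == 0] = np.inf
    return (Ac.T @ Bc) / np.outer(na, nb)


def match_synergies(models: list[SynergyModel],
                    reference: SynergyModel) -> list[np.ndarray]:
    """Align each model's synergy order to the reference's.

    Returns one permutation per model such that ``model.W[:, perm]`` has its
    columns in the reference's synergy order, chosen to maximize the summed
    Pearson correlation between matched muscle-weight vectors (optimal
    assignment; invariant to column rescaling).
    """
    s = reference.n_synergies
    perms = []
    for m in models:
        if m.n_synergies != s:
            raise ValueError("all models must share the reference's synergy count")
        corr = _column_correlations(reference.W, m.W)   # ref cols x model cols
        rows, cols = linear_sum_assignment(-corr)
        perm = np.empty(s, dtype=int)
        perm[rows] = cols
        perms.append(perm)
    return perms


def apply_permutation(model: SynergyModel, perm: np.ndarray) -> SynergyModel:
    """Reorder a model's synergies (W columns and C rows) by a permutation."""
    return SynergyModel(
        W=model.W[:, perm], C=model.C[perm], vaf_total=model.vaf_total,
        vaf_muscle=model.vaf_muscle, residual_norm=model.residual_norm,
        n_iter=model.n_iter, seed=model.seed,
        vaf_per_synergy=None if model.vaf_per_synergy is None
        else model.vaf_per_synergy[perm])
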