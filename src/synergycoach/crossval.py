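"""Fixed-vector cross-validation of synergy bases across groups.

To test whether one group's synergy basis explains the other group's muscle
activity, a reference weight matrix is built from the reference group's
(matched) models and held fixed while each subject's activation coefficients
are refit by the multiplicative C-update; the overall reconstruction VAF
quantifies the fit.  A lower VAF for the other group than for the reference
group's own members indicates group-specific synergy composition.
"""

from __future__ import annotations

import numpy as np

from .nmf import SynergyModel, fit_C_fixed_W


def build_reference_W(models: list[SynergyModel]) -> np.ndarray:
    """Average matched muscle-weight matrices into a reference basis.

    Models must already be matched to a common synergy ordering (see
    :func:`synergycoach.select.match_synergies`).  Each W is scaled to unit
    column maximum before averaging and the mean is rescaled to unit maximum.
    """
    if not models:
        raise ValueError("no models to average")
    shapes = {m.W.shape for m in models}
    if len(shapes) != 1:
        raise ValueError(f"unmatched models: differing W shapes {shapes}")
    Ws = []
    for m in models:
        scale = m.W.max(axis=0)
        if np.any(scale == 0):
            raise ValueError("model with an all-zero synergy column")
        Ws.append(m.W / scale)
    mean = np.mean(Ws, axis=0)
    return mean / mean.max(axis=0)


def cross_reconstruct(E_subject: np.ndarray, W_reference: np.ndarray,
                      max_iter: int = 2000, tol: float = 1e-6,
                      seed: int | None = None) -> tuple[float, np.ndarray]:
    """Reconstruct a subject's envelopes from a fixed reference basis.

    Returns ``(vaf_total, C)`` from the C-only multiplicative fit.
    """
    C, vaf = fit_C_fixed_W(E_subject, W_reference, max_iter=max_iter,
                           tol=tol, seed=seed)
    return vaf, C


def flag_low_vaf(vaf_by_subject: dict[str, float],
                 threshold: float = 80.0) -> list[str]:
    """Subjects whose cross-reconstruction VAF falls below the threshold."""
    return [s for s, v in sorted(vaf_by_subject.items()) if v < threshold]
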