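"""Run configuration: seeds, cohort sizes, generator/NMF/selection settings."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class RunConfig:
    """Everything an end-to-end synthetic-study run needs.

    ``n_synergies=None`` means the synergy count is selected per subject by
    the 90%-VAF / 5%-share rule; an integer fixes it.  ``generator`` holds
    keyword overrides for :func:`synergycoach.synth.make_default_ground_truth`
    (e.g. ``snr_db``, ``weight_jitter_sd``).
    """

    seed: int = 0
    n_une: int = 10            # untrained group size
    n_exp: int = 7             # weightlifter group size
    n_reps: int = 6            # analyzed repetitions per subject (8 recorded - 2 excluded)
    n_muscles: int = 16
    n_gt_synergies: int = 3    # ground-truth synergy count of the generator
    n_synergies: int | None = None
    s_max: int = 6             # highest model order tried during selection
    n_restarts: int = 20
    max_iter: int = 5000
    tol: float = 1e-6
    vaf_threshold: float = 90.0
    share_threshold: float = 5.0
    vaf_muscle_threshold: float = 75.0
    crossval_flag_threshold: float = 80.0
    alpha: float = 0.05
    generator: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("vaf_threshold", "share_threshold",
                     "vaf_muscle_threshold", "crossval_flag_threshold"):
            v = getattr(self, name)
            if not (0 < v <= 100):
                raise ValueError(f"{name} must be in (0, 100], got {v}")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
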