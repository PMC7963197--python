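"""End-to-end synthetic study: simulate -> extract -> match -> compare -> test.

Runs the whole analysis on a simulated two-group cohort with known ground
truth and returns a JSON-serializable report bundle: per-subject synergy
counts and VAFs, within-/between-group similarity indexes (r_max, lag,
weight-vector r), fixed-vector cross-validation VAFs in both directions, and
the gated statistical battery.  Fully deterministic under a fixed master seed.
"""

from __future__ import annotations

from dataclasses import asdict, is_dataclass

import numpy as np

from . import crossval as cv
from . import similarity as sim
from . import stats as st
from .config import RunConfig
from .nmf import SynergyModel, factorize
from .preprocess import CYCLE_POINTS, MUSCLES, assemble_matrix
from .select import (apply_permutation, match_synergies, select_num_synergies,
                     vaf_muscle_screen)
from .synth import make_default_ground_truth, simulate_cohort

GROUPS = ("UNE", "EXP")


def _jsonable(obj):
    """Recursively convert dataclasses / numpy objects to plain JSON types."""
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def _mean_activation(model: SynergyModel, n_reps: int) -> np.ndarray:
    """Per-subject representative activation: mean matched C across cycles."""
    s = model.n_synergies
    return model.C.reshape(s, n_reps, CYCLE_POINTS).mean(axis=1)


def extract_models(cycles_by_subject, cfg: RunConfig, seed_rng):
    """Per-subject synergy extraction (auto-selection or fixed order)."""
    nmf_kw = dict(n_restarts=cfg.n_restarts, max_iter=cfg.max_iter, tol=cfg.tol)
    models, chosen, selections = {}, {}, {}
    for sid, cycles in cycles_by_subject.items():
        E = assemble_matrix(cycles)
        s_seed = int(seed_rng.integers(0, 2 ** 31 - 1))
        if cfg.n_synergies is None:
            sel = select_num_synergies(E, s_max=cfg.s_max,
                                       vaf_threshold=cfg.vaf_threshold,
                                       share_threshold=cfg.share_threshold,
                                       seed=s_seed, **nmf_kw)
            chosen[sid] = sel.chosen_s
            selections[sid] = sel
        else:
            chosen[sid] = cfg.n_synergies
    # all subjects must share one model order for matching and comparison
    counts = np.bincount(list(chosen.values()))
    s_common = cfg.n_synergies or int(np.argmax(counts))
    for sid, cycles in cycles_by_subject.items():
        sel = selections.get(sid)
        if sel is not None and s_common in sel.models:
            models[sid] = sel.models[s_common]
        else:
            E = assemble_matrix(cycles)
            models[sid] = factorize(E, s_common,
                                    seed=int(seed_rng.integers(0, 2 ** 31 - 1)),
                                    **nmf_kw)
    return models, chosen, s_common


def align_models(models: dict[str, SynergyModel], groups: dict[str, str],
                 gt_W: np.ndarray | None = None) -> dict[str, SynergyModel]:
    """Match every model's synergy order to a common reference.

    The reference is the highest-VAF subject of the untrained group; when the
    generator's ground-truth weights are available (and the model order agrees)
    the reference itself is first reordered to the ground-truth synergy order,
    giving canonical synergy indices.
    """
    ref_id = max((s for s in models if groups[s] == GROUPS[0]),
                 key=lambda s: models[s].vaf_total)
    ref = models[ref_id]
    if gt_W is not None and gt_W.shape[1] == ref.n_synergies:
        gt_model = SynergyModel(W=np.asarray(gt_W, dtype=float),
                                C=np.zeros((gt_W.shape[1], 1)), vaf_total=100.0,
                                vaf_muscle=np.full(gt_W.shape[0], 100.0),
                                residual_norm=0.0, n_iter=0, seed=0)
        perm = match_synergies([ref], gt_model)[0]
        ref = apply_permutation(ref, perm)
    ids = list(models)
    perms = match_synergies([models[s] for s in ids], ref)
    return {s: apply_permutation(models[s], p) for s, p in zip(ids, perms)}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full synthetic study and return the report bundle."""
    gt = make_default_ground_truth(cfg.n_muscles, cfg.n_gt_synergies,
                                   seed=cfg.seed, **cfg.generator)
    cycles, groups = simulate_cohort(gt, cfg.n_une, cfg.n_exp, cfg.n_reps,
                                     seed=cfg.seed)
    seed_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))

    models, chosen_s, s_common = extract_models(cycles, cfg, seed_rng)
    models = align_models(models, groups, gt_W=gt.W0)
    une_ids = sorted(s for s in models if groups[s] == GROUPS[0])
    exp_ids = sorted(s for s in models if groups[s] == GROUPS[1])

    # representative per-subject signals
    act = {s: _mean_activation(m, cfg.n_reps) for s, m in models.items()}
    weights = {s: m.W for s, m in models.items()}
    mean_env = {s: np.mean([c.values for c in cycles[s]], axis=0)
                for s in models}

    syn_labels = [f"#{k + 1}" for k in range(s_common)]
    syn_idx = sim.pairwise_group_index(act, groups, weights_by_subject=weights,
                                       group_order=GROUPS,
                                       signal_labels=syn_labels)
    musc_idx = sim.pairwise_group_index(mean_env, groups, group_order=GROUPS,
                                        signal_labels=list(MUSCLES)[:cfg.n_muscles])

    # fixed-vector cross-validation, both directions
    refs = {"UNE": cv.build_reference_W([models[s] for s in une_ids]),
            "EXP": cv.build_reference_W([models[s] for s in exp_ids])}
    cv_vaf = {ref_g: {} for ref_g in refs}
    for ref_g, W_ref in refs.items():
        for sid in models:
            E = assemble_matrix(cycles[sid])
            vaf, _ = cv.cross_reconstruct(
                E, W_ref, seed=int(seed_rng.integers(0, 2 ** 31 - 1)))
            cv_vaf[ref_g][sid] = vaf
    flags = cv.flag_low_vaf(cv_vaf["UNE"], cfg.crossval_flag_threshold)

    # statistics battery
    tests = []
    for gi in syn_idx + musc_idx:
        lags = np.array([p.lag_pct for p in gi.pairs])
        if lags.size >= 3:
            tests.append(st.one_sample_vs_zero(
                lags, cfg.alpha, metric=f"lag {gi.group_pair} {gi.signal}"))
    vaf_une = np.array([models[s].vaf_total for s in une_ids])
    vaf_exp = np.array([models[s].vaf_total for s in exp_ids])
    if min(len(une_ids), len(exp_ids)) >= 3:
        tests.append(st.two_sample(vaf_une, vaf_exp, cfg.alpha,
                                   metric="vaf_total UNE vs EXP"))
        tests.append(st.two_sample(
            np.array([cv_vaf["UNE"][s] for s in une_ids]),
            np.array([cv_vaf["UNE"][s] for s in exp_ids]), cfg.alpha,
            metric="crossval vaf (UNE basis) UNE vs EXP"))

    report = {
        "config": asdict(cfg),
        "ground_truth": {"group_shifts": list(gt.group_shifts),
                         "n_synergies": gt.n_synergies},
        "groups": groups,
        "chosen_s": chosen_s,
        "s_common": s_common,
        "vaf_total": {s: models[s].vaf_total for s in models},
        "vaf_group_mean": {"UNE": float(vaf_une.mean()),
                           "EXP": float(vaf_exp.mean())},
        "vaf_group_sd": {"UNE": float(vaf_une.std(ddof=1)),
                         "EXP": float(vaf_exp.std(ddof=1))},
        "low_vaf_muscles": {s: vaf_muscle_screen(models[s],
                                                 cfg.vaf_muscle_threshold)
                            for s in models},
        "similarity_synergies": syn_idx,
        "similarity_muscles": musc_idx,
        "crossval": {
            "vaf": cv_vaf,
            "group_mean_une_basis": {
                "UNE": float(np.mean([cv_vaf["UNE"][s] for s in une_ids])),
                "EXP": float(np.mean([cv_vaf["UNE"][s] for s in exp_ids]))},
            "group_sd_une_basis": {
                "UNE": float(np.std([cv_vaf["UNE"][s] for s in une_ids], ddof=1)),
                "EXP": float(np.std([cv_vaf["UNE"][s] for s in exp_ids], ddof=1))},
            "flagged_below_threshold": flags,
        },
        "stats": tests,
    }
    return _jsonable(report)
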