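# synergycoach

Muscle-synergy analysis of the power clean: who coordinates which muscles,
when, and how that changes with training.

Surface EMG of a multi-joint lift can be compressed into a few *muscle
synergies*: nonnegative modules `E ≈ W C` where the columns of `W`
(muscles × s) hold each muscle's weighting in a synergy and the rows of `C`
(s × time) hold that synergy's activation over the movement cycle.
`synergycoach` implements the complete analysis used to compare untrained
lifters ("UNE") with experienced weightlifters ("EXP") on this exercise:

- **Preprocessing** — zero-phase Butterworth filtering (barbell 8 Hz low-pass;
  EMG 20–450 Hz band-pass, rectification, 12 Hz low-pass), cycle segmentation
  from the barbell's lowest/highest positions, amplitude normalization to a
  90%-of-5RM reference set, and phase normalization of every repetition to
  16 × 200 matrices (100 points per ascendant/descendant phase), excluding
  each set's first and last repetition.
- **Synergy extraction** — Lee–Seung multiplicative-update NMF minimizing
  `‖E − WC‖_F` with random restarts, exposed as a scikit-learn style
  estimator (`SynergyNMF`).
- **Model selection** — smallest s with total VAF ≥ 90% where every synergy
  contributes ≥ 5% of VAF (incremental definition), plus per-muscle VAF
  screening and automated optimal-assignment synergy matching across
  subjects.
- **Similarity & timing** — pairwise maximum cross-correlation (`r_max`) and
  its lag (% of cycle) for activation waveforms and single-muscle profiles,
  Pearson `r` for muscle-weight vectors, aggregated over all within-group and
  between-group pairs.
- **Fixed-vector cross-validation** — the untrained group's averaged `W` is
  held fixed while each subject's `C` is refit; reconstruction VAF tests
  whether one group's synergy basis explains the other group's EMG.
- **Statistics** — Shapiro–Wilk-gated t / Wilcoxon / Mann–Whitney tests with
  Cohen's d.

Because no recordings are distributed with the study this targets, the
package ships a first-class synthetic-EMG generator (`synergycoach.synth`)
with known ground truth: envelopes built from 3 synergies over 16 muscles,
per-subject weight/timing/waveform jitter, group-specific timing offsets
(−2.46, −4.60, +1.86 % of cycle) and weight-composition differences, additive
noise, and an optional raw-EMG mode (envelope-modulated 20–450 Hz carrier
plus a barbell trace) that exercises the preprocessing chain end to end.

## Worked example

```python
from synergycoach import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=1, n_restarts=20, s_max=5))

print(report["s_common"], report["vaf_group_mean"])
for g in report["similarity_synergies"]:
    if g["group_pair"] == "between":
        print(g["signal"], f"lag {g['mean_lag']:+.2f}%  r_max {g['mean_rmax']:.3f}")
print(report["crossval"]["group_mean_une_basis"])
```

prints (seed 1):

```
3 {'UNE': 92.37520430459679, 'EXP': 92.26974399263021}
#1 lag -2.45%  r_max 0.981
#2 lag -4.46%  r_max 0.975
#3 lag +2.56%  r_max 0.978
{'UNE': 88.59545179579952, 'EXP': 74.8105952496975}
```

Read: every simulated subject needs 3 synergies (total VAF ≈ 92%); the
between-group lags recover the imposed timing offsets of −2.46, −4.60 and
+1.86 % of the cycle with the correct signs; and the untrained group's synergy
basis reconstructs untrained subjects far better (≈ 89% VAF) than trained
ones (≈ 75%), the directional signature of training-specific coordination.

The same run is available from the shell:

```sh
synergycoach all --out results/
```

and the individual stages (`simulate`, `preprocess`, `extract`, `select`,
`compare`, `crossval`, `report`) operate on CSV/JSON/YAML files for use in
scripted workflows — see `synergycoach --help`.

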