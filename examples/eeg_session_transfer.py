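"""Cross-session transfer on toy motor-imagery-like EEG.

Simulates two recording sessions of band-limited oscillatory trials
(class-specific frequency and spatial pattern), band-pass filters
8–30 Hz, crops the 1.5–6.5 s epoch, reduces each trial to per-channel
log band-power, and classifies the second session from the first via
the sparse kernel-subspace method.
"""

from rkhsda import (
    EpochSpec,
    SolverConfig,
    ToyEEGScenario,
    combine,
    evaluate,
    fit,
    generate_toy_eeg_sessions,
    preprocess,
    raw_knn_accuracy,
)

sc = ToyEEGScenario(seed=0)
Xs_trials, ys, Xt_trials, yt = generate_toy_eeg_sessions(sc)
spec = EpochSpec()
print(f"{Xs_trials.shape[0]} trials/session, {sc.n_channels} channels at {sc.fs:.0f} Hz")
print(f"epoch window [{spec.t_start_s}, {spec.t_end_s}) s -> {spec.n_epoch_samples} samples/channel")

bundle = combine(preprocess(Xs_trials, spec), ys, preprocess(Xt_trials, spec))
print(f"feature dimension: {bundle.X.shape[1]} (log band-power per channel)")
print(f"raw-space KNN accuracy:        {raw_knn_accuracy(bundle, yt):.3f}")

fr = fit(bundle, method="slda_rkhsda_sparse", config=SolverConfig(d=2))
print(f"sparse subspace KNN accuracy:  {evaluate(fr, yt)['accuracy']:.3f}  (chance = {1/sc.n_classes:.2f})")
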