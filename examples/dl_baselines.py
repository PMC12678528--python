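"""Train the reduced-scale neural baselines and compare them with OLS.

The FFN committee (two tanh hidden layers, 5 members averaged) and the small
two-layer LSTM consume the same per-sample dataset as the linear pipelines.
On an exactly linear synthetic cohort the linear transform is the ceiling;
the baselines approach it from below at desk scale.
"""

import numpy as np

from ecgrecon import DLConfig, SynthConfig, generate_cohort, predict_dl, train_dl
from ecgrecon import fit_ols, predict

INPUTS = ("I", "II", "V3")
OUTPUTS = ("V1", "V2", "V4", "V5", "V6")

cohort = generate_cohort(SynthConfig(n_patients=4, seed=55))
train_items, test_items = cohort.items[:3], cohort.items[3:]
Xtr = [it.record.subset(INPUTS) for it in train_items]
Ytr = [it.record.subset(OUTPUTS) for it in train_items]
Xte = test_items[0].record.subset(INPUTS)
Yte = test_items[0].record.subset(OUTPUTS)

ols = fit_ols(np.vstack(Xtr), np.vstack(Ytr))
print(f"OLS   held-out RMSE: {np.sqrt(np.mean((predict(ols, Xte) - Yte) ** 2)):.4f} mV")

ffn = train_dl(Xtr, Ytr, DLConfig(variant="ffn", hidden=16, n_committee=3,
                                  epochs=40, seed=0))
rmse_ffn = np.sqrt(np.mean((predict_dl(ffn, Xte) - Yte) ** 2))
print(f"FFN   held-out RMSE: {rmse_ffn:.4f} mV "
      f"(committee of {len(ffn.members)}, final loss {ffn.loss_curves[0][-1]:.2e})")

lstm = train_dl(Xtr, Ytr, DLConfig(variant="lstm", hidden=8, window=250,
                                   epochs=3, seed=0))
rmse_lstm = np.sqrt(np.mean((predict_dl(lstm, Xte) - Yte) ** 2))
print(f"LSTM  held-out RMSE: {rmse_lstm:.4f} mV "
      f"(loss {lstm.loss_curves[0][0]:.3f} -> {lstm.loss_curves[0][-1]:.3f} "
      f"over {len(lstm.loss_curves[0])} epochs)")
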