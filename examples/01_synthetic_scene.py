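"""Build a synthetic study scene: true carbon fields, a biased model
ensemble, and noisy field plots.

The truth is unobservable in a real campaign; here we generate it, so
every later stage can be scored against it.
"""
import numpy as np

from forestcarbon import EnsembleConfig, TruthConfig, gen_model_ensemble, gen_plots, gen_truth

cfg = TruthConfig(seed=42, nrows=48, ncols=48, year_start=1982, year_end=2021)
cveg, csoil = gen_truth(cfg)
print(f"truth cVeg : mean {np.nanmean(cveg.data):6.1f} Mg C/ha, "
      f"{int(cveg.mask[0].sum())} of {cveg.geometry.nrows * cveg.geometry.ncols} pixels non-forest")
print(f"truth cSoil: mean {np.nanmean(csoil.data):6.1f} Mg C/ha")

stack = gen_model_ensemble(cveg, EnsembleConfig(seed=7))
for name, cube in stack:
    bias = np.nanmean(cube.data) - np.nanmean(cveg.data)
    print(f"  model {name}: mean bias {bias:+6.1f} Mg C/ha")

plots = gen_plots(cveg, csoil, 2001, n_plots=500, obs_noise_sd=5.0, seed=3)
rmse = float(np.sqrt(np.mean((plots.obs_cveg - plots.true_cveg) ** 2)))
print(f"500 plots sampled; observation RMSE {rmse:.2f} Mg C/ha "
      f"(configured noise 5.0 — plot measurements are noisy but unbiased)")
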