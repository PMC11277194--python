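"""Choosing SVR hyperparameters: CV grid search and the real-coded GA.

Both optimizers are run on the same task — pick (C, gamma) for an RBF
support-vector regressor predicting the outbreak level — and should
land in a similar region.  The GA maximizes the negated 5-fold CV
error over a continuous box instead of a fixed lattice.
"""

import numpy as np

from gepcast import GAConfig, ga_optimize, generate_synthetic, grid_search_cv
from gepcast.data import FEATURE_COLUMNS, apply_normalizer, fit_normalizer
from gepcast.ga import DEFAULT_C_GRID, DEFAULT_GAMMA_GRID
from sklearn.model_selection import KFold
from sklearn.svm import SVR

df = generate_synthetic(n_years=78, seed=0)
norm = fit_normalizer(df)
X = apply_normalizer(norm, df)[list(FEATURE_COLUMNS)].to_numpy(float)
y = df["level"].to_numpy(float)

gs = grid_search_cv(X, y, DEFAULT_C_GRID, DEFAULT_GAMMA_GRID, n_folds=5, seed=0)
print(f"grid search : C={gs.best_c:g}, gamma={gs.best_gamma:g}, "
      f"CV MSE={gs.best_score:.4f}  ({len(gs.table)} grid points)")

splits = list(KFold(n_splits=5, shuffle=True, random_state=0).split(X))


def neg_cv_mse(params):
    log2_c, log2_g = params
    errs = []
    for tr, te in splits:
        m = SVR(kernel="rbf", C=2.0**log2_c, gamma=2.0**log2_g, epsilon=0.1)
        m.fit(X[tr], y[tr])
        errs.append(float(np.mean((m.predict(X[te]) - y[te]) ** 2)))
    return -float(np.mean(errs))


res = ga_optimize(neg_cv_mse, bounds=[(-2.0, 8.0), (-10.0, 2.0)],
                  config=GAConfig(max_generations=25), rng=0)
print(f"GA search   : C={2 ** res.best[0]:.3g}, gamma={2 ** res.best[1]:.3g}, "
      f"CV MSE={-res.best_fitness:.4f}  ({len(res.trace)} generations)")
print()
print("Lower CV MSE is better; the two methods should broadly agree on")
print("the useful (C, gamma) region for this data.")
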