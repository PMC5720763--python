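"""Pre-run scoping: zero-inflation detection and minimum bag fractions.

Before a long model run it is worth knowing whether the response is
zero-inflated (which selects the hurdle path) and whether the dataset
is large enough for the requested bag fraction — the per-iteration
training subsample must keep a workable number of rows, and the
positive-only gaussian component sees far fewer rows than the binary
one.
"""

from deltaboost import synthetic
from deltaboost.core_data import bfcheck, check_zero_inflation

grid, truth = synthetic.gen_landscape(15, 15, seed=6)
samples = synthetic.gen_survey(grid, truth, 120, seed=6)
y = samples.y("cpue")

zi = check_zero_inflation(y, threshold=0.5)
print(f"{100 * (y == 0).mean():.1f}% zeros -> zero-inflated: {zi} "
      "(delta log-normal path selected)")

res = bfcheck(samples, "cpue", min_train_rows=21)
print(f"binary component: n = {res.n_binary}, "
      f"minimum bag fraction {res.bf_min_binary:.2f}")
if res.gaussian_feasible:
    print(f"gaussian component: n = {res.n_gaussian}, "
          f"minimum bag fraction {res.bf_min_gaussian:.2f}")
else:
    print(f"gaussian component: only {res.n_gaussian} positive rows — "
          "infeasible even with the full bag")
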