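"""Score how well a survey covers the environmental space of the
prediction grid.

Two surveys of the same landscape: one placed uniformly, one biased
toward deep cells.  The representativeness score at a cell is the
summed absolute difference between sampled and grid bin frequencies of
each explanatory variable — 0 means the samples mirror the grid there;
higher means predictions at that cell extrapolate from thin sampling.
"""

from deltaboost import synthetic
from deltaboost.rsb import rsb_scores

grid, truth = synthetic.gen_landscape(30, 30, seed=2)

uniform = synthetic.gen_survey(grid, truth, 200, seed=2)
biased = synthetic.gen_survey(grid, truth, 200, seed=2, bias_var="depth")

for name, survey in (("uniform", uniform), ("depth-biased", biased)):
    surf = rsb_scores(survey, grid, truth.expvars)
    print(f"{name:>12} survey: mean total score {surf.total.mean():.3f}, "
          f"worst cell {surf.total.max():.3f}")
print("higher scores on the biased survey flag the habitat its stations missed")
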