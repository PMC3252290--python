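"""Run a small screen end to end and rank compounds by NSI.

A 24-compound, two-line screen: images are rendered and analyzed
in memory, every cell is scored, per-line heatmaps are aggregated, and
the most negative aggregate NSI (best clearance in all lines) wins.
Takes ~20 s.
"""

from scipy.stats import spearmanr

from nsiscreen import assign_kinetics, build_library
from nsiscreen.pipeline import ScreenConfig, run_screen
from nsiscreen.render import FieldGeometry

lib = build_library(seed=42, n_compounds=24)
truth = assign_kinetics(lib, ("line1", "line2"), structure_link=0.7, seed=5)
cfg = ScreenConfig(cell_lines=("line1", "line2"), n_fields=2,
                   geometry=FieldGeometry(n_cells=15))
result = run_screen(lib, truth, cfg, seed=11)

print("top 5 compounds (most negative aggregate NSI = best):")
print(result.ranking.head(5).to_string(index=False))

est = result.compound_nsi()
true_lr = truth.true_log_ratios()
cids = sorted(est)
rho = spearmanr([est[c] for c in cids], [true_lr[c] for c in cids]).statistic
print(f"\nSpearman(estimated NSI, true log-ratio) over {len(cids)} "
      f"compounds: {rho:.2f}")
print("-> the pipeline recovers the generator's compound ordering")
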