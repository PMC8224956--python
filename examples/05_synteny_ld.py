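"""Synteny ordering and LD decay.

The draft assembly gives no marker order beyond each scaffold.  Anchors
to a chromosome-scale reference let us project markers onto one axis;
genuine linkage then shows as r-squared falling with projected distance.
"""

import numpy as np

import frostmap as fm

result = fm.run_pipeline(fm.RunConfig(seed=1))
ordered = result.ordered_markers
placed = ordered[ordered["placed"]]
print(f"marker panel: {len(ordered)} strongest association markers, "
      f"{len(placed)} placed by synteny anchors")
print(placed.sort_values("ref_pos").head(8)[
    ["scaffold", "pos", "ref_chrom", "ref_pos", "p"]].to_string(index=False))

decay = result.report["synteny_ld"]["decay"]
print(f"\nLD decay: Spearman(distance, r^2) = {decay['statistic']:.3f}, "
      f"permutation p = {decay['p_value']:.4g} over {decay['n_pairs']} pairs")
r2 = result.ld_r2
print(f"mean r^2 among panel markers: {np.nanmean(r2[np.triu_indices_from(r2, 1)]):.3f}")
# A clearly negative Spearman statistic with small p is the signature of
# LD decaying along the synteny-ordered axis, i.e. the anchors recovered a
# faithful marker order around the locus.
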