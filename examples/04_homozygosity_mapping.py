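"""Pooled-sequencing homozygosity mapping.

Founder-het variants tightly linked to the mutation should sit at AF ~1
in the homozygous-mutant pool, ~0.5 in the het pool and the founder, and
~0 in the wild-type pool.  The fraction of variants matching that
pattern, in 10 kb windows, peaks around the causal locus.
"""

import frostmap as fm

data = fm.simulate_colony(fm.ColonyConfig(seed=1))
lengths = dict(zip(data.scaffold_lengths["scaffold"],
                   data.scaffold_lengths["length"]))

kept, _ = fm.filter_founder_het(data.founder_wgs, fm.FilterConfig(), lengths)
keys = kept.variants[["scaffold", "pos", "ref", "alt"]]
pools = data.pool_counts.merge(keys, on=list(keys.columns), how="inner")

windows = fm.window_scan(pools, fm.ConcordanceRule(), 10_000, 5, lengths)
ranked, _ = fm.rank_candidates(windows, top_k=5)
print("top windows by concordant fraction:")
print(ranked[["scaffold", "start", "end", "n_informative", "n_concordant",
              "fraction"]].to_string(index=False))
qual = windows[windows["qualifying"]]
print(f"\ngenome-wide mean fraction: {qual['fraction'].mean():.3f} "
      f"over {len(qual)} qualifying windows")
print(f"true causal locus:         {data.truth.causal_scaffold}:"
      f"{data.truth.causal_scaffold_pos}")
# Windows on and around the causal scaffold carry fractions near 0.7-0.9
# against a ~0.02 background; the high-fraction plateau spans the whole
# linked region, so the peak localises the neighbourhood rather than one
# exact window.
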