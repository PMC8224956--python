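"""Simulate a mapping colony and look at its ground truth.

Builds the default scenario: one founder heterozygous for a semidominant
colour mutation, 12 outcross dams, carrier intercrosses and backcrosses,
RAD-seq-like genotypes for 188 animals and three pooled genomes
(25 homozygous mutant / 63 heterozygous / 71 wild type at 30x).
"""

import frostmap as fm

data = fm.simulate_colony(fm.ColonyConfig(seed=1))

print(f"colony size:        {len(data.pedigree)} individuals")
print(f"causal locus:       {data.truth.causal_scaffold}:"
      f"{data.truth.causal_scaffold_pos} "
      f"(chromosome {data.truth.causal_chrom})")
print(f"WGS variant sites:  {data.founder_wgs.n_variants}")
print(f"RAD marker sites:   {data.rad.n_variants} across "
      f"{len(data.rad.samples)} genotyped animals")
counts = data.truth.dosages.value_counts().sort_index()
print("causal dosage classes (whole colony):",
      {int(k): int(v) for k, v in counts.items()})
for pool, ids in data.truth.pool_ids.items():
    print(f"  pool {pool:3s}: {len(ids)} individuals")
# Dosage 0/1/2 maps to wild type / mutant / strong mutant phenotype; the
# pools are drawn from exactly those classes, mirroring the study design.
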