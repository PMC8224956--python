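"""Founder-heterozygosity variant filtering.

Only biallelic variants at which the founder is confidently heterozygous
(allele balance 0.4-0.6, DP >= 30, GQ >= 30, scaffold >= 5 kb) can track
the mutant haplotype through the pools.
"""

import frostmap as fm

data = fm.simulate_colony(fm.ColonyConfig(seed=1))
lengths = dict(zip(data.scaffold_lengths["scaffold"],
                   data.scaffold_lengths["length"]))

kept, report = fm.filter_founder_het(data.founder_wgs, fm.FilterConfig(), lengths)
print(f"variants in:  {data.founder_wgs.n_variants}")
print(f"variants out: {kept.n_variants}")
print("removal reasons (a record may fail several):")
reasons = report["reasons"].str.split(";").explode().value_counts()
for reason, n in reasons.items():
    print(f"  {reason:18s} {n}")
# Most removals are founder-homozygous sites (uninformative as haplotype
# markers) and sites failing the 30x depth requirement.
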