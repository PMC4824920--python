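"""Species-level Wolbachia occurrence from the packaged screening table.

Reproduces the headline screening statistics: 26 of 45 study species
infected (58%), 71% occurrence in the recently derived clades ONC3-ONC5,
and 52.9% across the 85 species known from this study plus prior reports.
"""
import cophylo as cp

table = cp.make_infection_fixture()

study = cp.compute_occurrence(table, in_study=True)
recent = cp.compute_occurrence(table, in_study=True, clades=("ONC3", "ONC4", "ONC5"))
combined = cp.compute_occurrence(table)

print(f"study sample:        {study.numerator}/{study.denominator} "
      f"= {study.percentage_integer}%")
print(f"clades ONC3-ONC5:    {recent.numerator}/{recent.denominator} "
      f"= {recent.percentage_integer}%")
print(f"study + prior data:  {combined.numerator}/{combined.denominator} "
      f"= {combined.percentage}%")

new = table[table["newly_examined"]]
print(f"\nnewly screened species: {len(new)} "
      f"({int((new['status'] == 'negative').sum())} Wolbachia-free, "
      f"{int(new['new_strain'].sum())} carrying new strains)")
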