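"""Simulate the dye-swap Pi-withdrawal time course.

Generates the default design — 7 sampling days around a phosphate
withdrawal/re-supply cycle, 2 treatments, 3 replicates, full dye swap —
and shows the planted truth for one responsive gene.
"""

from pidiag import SimDesign, generate_timecourse

design = SimDesign(n_genes=2000, seed=42)
matrix, meta, truth = generate_timecourse(design)

print(f"genes:               {design.n_genes}")
print(f"biological samples:  {meta['biological_id'].nunique()}")
print(f"arrays:              {meta['array_id'].nunique()}")
print(f"labelled channels:   {len(meta)}")

responsive = truth[truth["planted_fold"] > 1]
g = responsive.index[0]
print(f"\nplanted responsive genes: {len(responsive)}")
print(f"example gene {g}: pattern {truth.loc[g, 'pattern']!r}, "
      f"fold {truth.loc[g, 'planted_fold']:g}, "
      f"diagnostic={bool(truth.loc[g, 'is_diagnostic'])}")
print("\nThe pattern string gives the planted direction per sampling day")
print("(up/down arrows where the treated mean is shifted, '-' where not).")
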