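"""Marker prevalence, cgr-ratio skewness and association in a qPCR cohort.

Simulates a 158-individual cohort (log-normal E. lenta marker, Beta carrier
fraction for cgr2, 1e3 copies/g detection limit, repeat sampling) and
computes the cohort report.
"""

import numpy as np

from cgrmap.metagenome import (abundance_association, aggregate_individuals,
                               cgr_ratio, dagostino_skewness, prevalence)
from cgrmap.simulate import simulate_qpcr_cohort

table, truth = simulate_qpcr_cohort(n_individuals=158, seed=1)
limit = truth.extras["detection_limit"]

prev_eln, _ = prevalence(table, "elnmrk1_copies_per_g", limit)
prev_cgr, _ = prevalence(table, "cgr2_copies_per_g", limit)
per_ind = aggregate_individuals(table, ["elnmrk1_copies_per_g",
                                        "cgr2_copies_per_g"])
ratios = cgr_ratio(per_ind, detection_limit=limit)
skew = dagostino_skewness(ratios.to_numpy())
both = per_ind[(per_ind["elnmrk1_copies_per_g"] >= limit)
               & (per_ind["cgr2_copies_per_g"] >= limit)]
rho, p = abundance_association(np.log10(both["elnmrk1_copies_per_g"]),
                               np.log10(both["cgr2_copies_per_g"]))

print(f"prevalence: elnmrk1 {prev_eln:.1f}%  cgr2 {prev_cgr:.1f}%  (n=158)")
print(f"cgr-ratio skew g1={skew.g1:.3f}  p={skew.p:.2e}  n={skew.n}")
print(f"abundance association: Spearman rho={rho:.3f}  p={p:.2e}")
# The negative skew means many individuals harbor less cgr2 than their
# E. lenta abundance predicts — sub-populations of cgr2-negative strains;
# the strong rank correlation shows cgr2 carriage tracks the species.
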