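"""Clonal diversity from the published population census.

Recomputes the clonal diversity index R = (G-1)/(N-1) for every sampled
black locust population from its printed sample size N and unique
genotype count G, then tests whether clonality differs between the
invasive (European) and native (North American) range using the printed
pooled clone counts.
"""

import pandas as pd

from invadepop import clonal_R, load_population_census, range_clonality_test
from invadepop.clonality import ClonalReport

census = load_population_census()
census["R"] = [clonal_R(n, g) for n, g in zip(census["N"], census["G"])]

print("Most clonal populations (lowest R, i.e. most duplicated genotypes):")
print(census.nsmallest(5, "R")[["population", "range_label", "N", "G", "R"]]
      .to_string(index=False, float_format="%.3f"))

means = census.groupby("range_label")["R"].mean()
print(f"\nMean R  invasive (Europe): {means['invasive']:.2f}   "
      f"native (America): {means['native']:.2f}")
print("Lower mean R in Europe = more clonal (vegetative) spread there.")

# Range-level test from the pooled clone counts of the field survey:
# 68 clones among 280 European samples, 30 among 356 American samples.
reports = [
    ClonalReport("europe_pool", 280, 212, clonal_R(280, 212), [], [], 1),
    ClonalReport("america_pool", 356, 326, clonal_R(356, 326), [], [], 1),
]
meta = pd.DataFrame({
    "individual_id": ["e", "a"],
    "population": ["europe_pool", "america_pool"],
    "range_label": ["invasive", "native"],
    "longitude": [10.0, -80.0], "latitude": [48.0, 38.0],
    "source_type": ["natural", "natural"],
})
res = range_clonality_test(reports, meta)
print(f"\nRange effect on clonality: chi2 = {res.chi2:.2f}, df = {res.df}, "
      f"p = {res.p_value:.2e}")
print("A significant test means clone frequency differs between ranges.")
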