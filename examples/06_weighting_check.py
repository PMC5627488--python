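"""Post-stratification weighting check.

Simulates a population, draws respondents with a uniform response rate,
benchmarks the sample back to the population on area x sex x age cells, and
compares weighted vs unweighted area prevalence ratios.  A correlation near 1
means geographically structured non-response is not distorting the
unweighted spatial analysis.
"""

from walkmap.studies import weighting_study

out = weighting_study(seed=0)
print(f"Pearson r, unadjusted offsets: {out['unadjusted']:.3f}")
print(f"Pearson r, stage-1-adjusted offsets: {out['adjusted']:.3f}")
# Values above 0.95 mirror the 0.94-0.98 range reported for the emulated
# cohort, supporting unweighted disease mapping.
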