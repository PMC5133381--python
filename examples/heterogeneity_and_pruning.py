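"""Detect and remove an outlying instrument via Q contributions.

Builds ten concordant instruments plus one whose outcome association is
displaced by ten standard errors (e.g. a strongly pleiotropic variant),
then shows how its contribution to Cochran's Q singles it out and how
pruning at the chi-squared(1) 95th percentile (3.84) removes exactly it.
"""

from mrsense import DEFAULT_PRUNE_THRESHOLD, SummaryDataset, VariantAssociation, cochran_q, ivw, prune_outliers

variants = []
for i in range(11):
    bx, sy = 0.2, 0.05
    by = 0.5 * bx + (10 * sy if i == 5 else 0.0)
    variants.append(VariantAssociation(f"rs{i + 1}", bx, 0.01, by, sy))
data = SummaryDataset(variants=tuple(variants), oriented=True)

het = cochran_q(data)
print(f"Q = {het.Q:.2f} on {het.df} df (p = {het.p_value:.2g}); "
      f"I^2 = {100 * het.i_squared:.0f}%")
print(f"threshold for a single variant's contribution: {DEFAULT_PRUNE_THRESHOLD:.2f}\n")
for vid, q in het.contributions:
    flag = "  <-- outlier" if q > DEFAULT_PRUNE_THRESHOLD else ""
    print(f"  {vid:<6} q = {q:8.2f}{flag}")

pruned, removed = prune_outliers(data)
print(f"\nremoved: {removed}")
print(f"IVW before pruning: {ivw(data).beta:.3f}; after: {ivw(pruned).beta:.3f} "
      "(the concordant variants' common ratio)")
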