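"""Aggregate the published benchmark tables and verify their arithmetic.

Rebuilds the per-subject accuracy table for BCI Competition IV dataset 2b,
its Average row, the spread and the mean differences against competitor
methods, and checks that every published kappa equals 2*accuracy - 1
(Cohen's kappa at chance level 0.5).
"""

from mieeg import aggregate_table, kappa
from mieeg.evaluation import method_differences, summarize_methods
from mieeg.published import ACCURACY_2B, DATASET_III, KAPPA_2B

print("accuracy (%) per subject, BCI Competition IV dataset 2b")
print(aggregate_table(ACCURACY_2B, decimals=1).to_string())

s = summarize_methods(ACCURACY_2B)
print(f"\nIS-CBAM-CNN summary: mean {s.loc['IS-CBAM-CNN', 'mean']:.1f}%, "
      f"mean std {s.loc['IS-CBAM-CNN', 'mean_std']:.1f}%, "
      f"max-min spread {s.loc['IS-CBAM-CNN', 'spread']:.1f}%")

d = method_differences(ACCURACY_2B, "IS-CBAM-CNN")
print("mean improvement over: "
      + ", ".join(f"{m} {v:+.1f}%" for m, v in d.items()))

print("\nkappa consistency (kappa = 2*accuracy - 1 at chance 0.5):")
acc = ACCURACY_2B["IS-CBAM-CNN"]["mean"]
kap = KAPPA_2B["IS-CBAM-CNN"]["mean"]
for i, (a, k) in enumerate(zip(acc, kap), start=1):
    print(f"  subject {i}: accuracy {a:.1f}% -> kappa {kappa(a / 100):.3f} "
          f"(published {k:.3f})")
row = DATASET_III["IS-CBAM-CNN"]
print(f"  dataset III: accuracy {row['accuracy']:.1f}% -> "
      f"kappa {kappa(row['accuracy'] / 100):.3f} (published {row['kappa']:.3f})")
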