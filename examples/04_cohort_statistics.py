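"""Generate a synthetic cohort and run the full statistical battery.

Ten phantom subjects are drawn with hybrid classes coupled to volume
excess and disease duration, quantified end to end, and analysed the way
a clinical cohort would be: HP/DBF ratios across severity grades and
stages (Kruskal-Wallis + Dunn-Bonferroni), across chronicity
(Mann-Whitney), class-vs-severity correlation (Spearman), and ordered
trends (linear-by-linear).  Small n keeps this demo quick; expect wide
p-values.
"""

from lymphspect import PhantomSpec, generate_cohort, run_cohort

studies = generate_cohort(
    n=10, seed=5,
    base_spec=PhantomSpec(shape=(64, 64, 64), proximal_radius_mm=40.0,
                          distal_radius_mm=30.0),
)
report = run_cohort(studies)

print(report.table[["id", "class_true", "hybrid_class", "tls_combined",
                    "severity_grade", "hp_ratio", "dbf_ratio",
                    "chronic"]].to_string(index=False,
                                          float_format=lambda v: f"{v:.3f}"))
print()
print(report.staging.render_text())
print()
for name in ("hp_ratio_by_grade", "dbf_ratio_by_stage", "class_vs_grade",
             "trend_class_vs_chronicity"):
    if name in report.tests:
        t = report.tests[name]
        print(f"{name}: {t.method}, statistic={t.statistic:.3f}, p={t.p_value:.4g}")
print("\nclass_vs_grade is the headline: the hybrid class should track the")
print("volumetric severity grade strongly even at this small n.")
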