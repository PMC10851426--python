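"""Permutation test of group differences in metric AUC.

The full pipeline (residualize -> correlate -> threshold -> metric -> AUC
over the density sweep) is re-run on every relabeling of subjects, giving
an exact-size test of the group difference. The synthetic patients have
weaker within-module loading, so clustering and local efficiency AUCs
should come out significantly lower in the patient group.
"""

from scnkit import CohortSpec, generate_cohort, run_group_comparison

ds = generate_cohort(CohortSpec(loading_patient=0.5, loading_control=0.9,
                                n_regions=60, n_modules=6, seed=42))
results = run_group_comparison(
    ds, metrics=("C", "Lp", "Eglobal", "Elocal"), n_perm=200, seed=1
)

print(f"{'metric':8s} {'AUC patients':>12s} {'AUC controls':>12s} "
      f"{'diff':>8s} {'p':>7s}")
for r in results:
    print(f"{r.metric:8s} {r.auc_group1:12.4f} {r.auc_group2:12.4f} "
          f"{r.observed_diff:8.4f} {r.p:7.4f}")

print("\nNegative differences with small p for C and Elocal recover the "
      "planted effect (patients cluster less); Lp and Eglobal differences "
      "should be weaker or absent.")
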