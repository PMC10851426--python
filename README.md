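# scnkit

Structural covariance network (SCN) analysis of regional cortical
thickness, for neuroimaging researchers comparing the topology of
group-level morphometric networks — for example a patient cohort against
healthy controls.

## What it does

Cortical thickness covaries between anatomically and functionally related
regions. Given a subjects × regions thickness table, scnkit builds one
network per group and asks whether their topologies differ:

1. **Residualize** each region's thickness on nuisance covariates (age,
   sex, total intracranial volume) by ordinary least squares, within each
   group.
2. **Correlate**: Pearson *r* between every pair of the 148 regions of the
   bundled sulco-gyral cortical parcellation (74 per hemisphere) across
   subjects, giving a 148 × 148 matrix per group.
3. **Threshold** at every network density *d* ∈ [0.10, 0.40] (step 0.01),
   keeping the `round(d·N(N−1)/2)` strongest correlations — both groups
   get binary graphs with identical node and edge counts at each density.
4. **Measure** global topology — clustering coefficient *C*,
   characteristic path length *Lp*, global/local efficiency
   *E<sub>glob</sub>*, *E<sub>loc</sub>* — and nodal topology —
   betweenness (BC), degree (DC), nodal efficiency (NE). *C* and *Lp* are
   normalized by the means of 1,000 degree-preserving (Maslov–Sneppen)
   rewired null graphs: γ = C/C<sub>rand</sub>, λ = Lp/Lp<sub>rand</sub>,
   σ = γ/λ; σ > 1 indicates small-world organization.
5. **Summarize** each metric curve by its area under the curve (AUC) over
   the density sweep, and **test** group differences by permuting group
   labels and re-running the entire pipeline (1,000 permutations by
   default): p = (#{|null| ≥ |observed|} + 1)/(n_perm + 1). Nodal tests
   are FDR-corrected (Benjamini–Hochberg) across regions.

A synthetic-cohort generator with a latent-factor block model provides
ground truth for all of this: the within-module factor loading is a
monotone knob for local network topology, so planted group differences
(patients loading more weakly than controls) are recoverable end to end.

## Worked example

```python
from scnkit import CohortSpec, generate_cohort, run_group_comparison

ds = generate_cohort(CohortSpec(loading_patient=0.5, loading_control=0.9,
                                n_regions=60, n_modules=6, seed=42))
for r in run_group_comparison(ds, metrics=("C", "Lp", "Eglobal", "Elocal"),
                              n_perm=200, seed=1):
    print(f"{r.metric:8s} diff={r.observed_diff:+.4f}  p={r.p:.4f}")
```

prints

```
C        diff=-0.0241  p=0.0796
Lp       diff=+0.0813  p=0.0149
Eglobal  diff=+0.0187  p=0.0050
Elocal   diff=-0.0144  p=0.0597
```

The negative AUC differences for *C* and *E<sub>loc</sub>* recover the
planted effect — the synthetic patients' networks cluster less than the
controls' — while the positive *Lp*/*E<sub>glob</sub>* differences reflect
patient edges spilling out of modules and shortening between-module paths.
The `examples/` directory has one short script per capability (simulation,
network construction, metrics and small-world indices, group comparison,
clinical partial correlation / power); each prints its numbers with a line
on what they mean. A thin CLI wraps the same calls
(`scnkit simulate | describe | build-network | metrics | compare | run-all`).

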