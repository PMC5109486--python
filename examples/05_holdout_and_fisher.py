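"""Hold-out validation and the exact test on validation hit rates.

Splits the positive pairs 80/20 (and 60/40), rebuilds profiles from the
training pairs only, and measures how many held-out interactions appear in
the top-N ranked predictions.  Finally runs the two-sided Fisher exact
test on validation-style counts: 4 of 6 rationally selected assays active
versus 0 of 11 cross-test controls.
"""

from tipf import (
    ContingencyTable2x2,
    SyntheticSpec,
    fisher_exact_two_sided,
    generate,
    holdout_validate,
)

# Richer profiles (~28 targets each) so compounds survive the 15-target
# curation floor even after a 60/40 split.
spec = SyntheticSpec(
    n_families=4, compounds_per_family=10, targets_per_family=30,
    within_family_share=0.95, cross_family_noise=0.02, seed=31,
)
_, truth = generate(spec)

for fraction in (0.8, 0.6):
    result = holdout_validate(
        truth.emitted_positives, fraction, seed=17, rank_thresholds=[100, 300, 600]
    )
    print(
        f"train fraction {fraction}: {result.n_test_pairs} held-out pairs "
        f"({result.n_test_unscoreable} unscoreable under the training universe)"
    )
    for row in result.rows:
        print(
            f"  top {row.rank}: recovered {row.n_test_recovered} "
            f"(sensitivity {row.sensitivity_scoreable:.3f}, "
            f"specificity {row.specificity:.3f})"
        )

table = ContingencyTable2x2(4, 2, 0, 11)
p = fisher_exact_two_sided(table)
print(f"\nFisher exact test, 4/6 active vs 0/11 active: p = {p:.6f}")
# p < 0.05: the rationally selected candidates hit their targets far more
# often than the cross-tested controls — the signal is not chance.
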