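"""Statistical power of a binary-outcome MR study across odds ratios.

Reproduces why a 740-case / 372,016-control outcome has essentially no power
(5%, i.e. the test size) to detect per-SD odds ratios in the 0.999-1.002
range, and what sample composition would be needed instead.
"""

from mrpipe import PowerInput, binary_outcome_power

print("outcome: 372,756 total, 740 cases, instrument R^2 = 0.01, alpha = 0.05")
for or_per_sd in (0.999, 1.001, 1.002, 1.05, 1.2, 1.5):
    p = binary_outcome_power(
        PowerInput(n_total=372_756, case_fraction=740 / 372_756,
                   r2_instruments=0.01, or_per_sd=or_per_sd)
    )
    print(f"  OR per SD {or_per_sd:>6}: power {100 * p:5.1f}%")

print("\nbalanced design (50% cases), same N and R^2:")
for or_per_sd in (1.001, 1.05, 1.2):
    p = binary_outcome_power(
        PowerInput(n_total=372_756, case_fraction=0.5,
                   r2_instruments=0.01, or_per_sd=or_per_sd)
    )
    print(f"  OR per SD {or_per_sd:>6}: power {100 * p:5.1f}%")

print("\nWith 0.2% case prevalence the noncentrality collapses: ORs a fraction "
      "of a percent from 1 are undetectable, so power sits at the 5% test size.")
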