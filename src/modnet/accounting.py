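"""Sample accounting for complete-case cohorts, plus the published
composition of the London talking-therapies cohort this analysis design
targets (used as the default template for unbalanced synthetic scenarios and
for demographic-arithmetic checks).
"""

from __future__ import annotations

# Composition of the assessed primary-care psychological-treatment cohort
# (London NHS talking-therapies services, 2011-2020) that motivates the
# default unbalanced group-size scenario. Note: the published per-group sizes
# sum to 146,677, which is 360 short of the published overall n (147,037 =
# 483,683 - 316,282 - 20,364); both figures are kept as printed.
REFERENCE_COHORT = {
    "assessed_n": 483_683,
    "excluded_missing_items": 316_282,
    "excluded_missing_demographics": 20_364,
    "analyzed_n": 147_037,
    "group_sizes": {
        "White British": 65_138,
        "White Irish": 3_994,
        "White Other": 29_260,
        "Mixed": 10_054,
        "Indian": 6_602,
        "Pakistani": 3_449,
        "Bangladeshi": 3_191,
        "Asian Other or Chinese": 6_363,
        "Black African": 7_458,
        "Black Caribbean": 8_421,
        "Black Other": 2_747,
    },
    "n_female": 98_926,
    "n_male": 48_111,
}


def complete_case_accounting(
    assessed_n: int, excluded_missing_items: int, excluded_missing_demographics: int
) -> int:
    """Analyzed sample size after the two complete-case exclusion steps."""
    analyzed = assessed_n - excluded_missing_items - excluded_missing_demographics
    if analyzed <= 0:
        raise ValueError("exclusions exceed the assessed sample")
    return analyzed


def group_percentages(group_sizes: dict[str, int]) -> dict[str, float]:
    """Each group's share of the total, in percent (computed from counts)."""
    total = sum(group_sizes.values())
    return {g: 100.0 * n / total for g, n in group_sizes.items()}


def scaled_group_sizes(total: int, template: dict[str, int] | None = None) -> dict[str, int]:
    """Shrink a group-size template to a smaller total, preserving shares.

    Every group keeps at least 2 members. Used to run desk-scale synthetic
    scenarios with the same unbalanced shape as the reference cohort.
    """
    template = template or REFERENCE_COHORT["group_sizes"]
    ref_total = sum(template.values())
    sizes = {g: max(2, round(total * n / ref_total)) for g, n in template.items()}
    return sizes
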