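"""Score individual injuries in disability-adjusted life years (DALYs).

Each injury type carries four disability parameters; its DALY is
    st_weight * st_duration + lt_weight * fraction_long_term * remaining_life.
The fatal type scores the victim's full remaining life expectancy.
"""

from burdensim import (
    MEDIAN_REMAINING_LIFE_YEARS,
    RemainingLifeModel,
    daly_for_injury,
    default_catalogue,
    fatality_benchmark,
)

catalogue = default_catalogue()
life = RemainingLifeModel(mode="constant",
                          constant_years=MEDIAN_REMAINING_LIFE_YEARS)

print(f"{'injury type':<24} {'DALY (years)':>12}")
for name in ("Sprained or twisted", "Poisoning", "Concussion",
             "Spinal injury", "Fatal injury"):
    daly = daly_for_injury(catalogue[name], MEDIAN_REMAINING_LIFE_YEARS)
    print(f"{name:<24} {daly:>12.6f}")

print()
print(f"fatality benchmark: {fatality_benchmark(life, catalogue):.1f} DALYs")
print("(one death at the median remaining life expectancy; injuries with a")
print(" long-term component, like concussion, cost orders of magnitude more")
print(" than acute-only ones, like a sprain)")
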