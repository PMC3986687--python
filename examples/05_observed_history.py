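"""Historical accounting: observed DALYs per calendar quarter.

Before predicting the future, the observed burden in past records gives
the frame of reference: near misses and victimless incidents contribute
zero; a single fatality dwarfs whole quarters of minor injuries.
"""

from burdensim import (
    RemainingLifeModel,
    default_catalogue,
    observed_dalys,
)
from burdensim.synthetic import elevator_preset, generate

catalogue = default_catalogue()
life = RemainingLifeModel(mode="constant", constant_years=44.4)

dataset = generate(elevator_preset(seed=8), catalogue)
quarterly = observed_dalys(dataset, catalogue, life, period="quarter")

print("quarter      observed DALYs")
for period, total in quarterly.items():
    bar = "#" * min(int(total / 2), 40)
    print(f"{str(period):<12} {total:10.2f}  {bar}")
print(f"\ntotal over {dataset.span_years} years: {quarterly.sum():.1f} DALYs")
print("spikes mark quarters containing a fatality (44.4 DALYs each)")
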