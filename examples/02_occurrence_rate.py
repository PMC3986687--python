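"""Estimate the mean occurrence rate under three reporting conventions.

lambda = bias * (n_i + n_m / r) / T, with n_i incidents and n_m near
misses observed over T years.  r = 1 conservatively counts every near
miss toward the rate; r = 10 is a safety-pyramid sensitivity; dropping
near misses entirely gives the incidents-only floor.
"""

from burdensim import estimate_rate, rate_per_million

N_I, N_M, T = 2638, 1028, 4.6  # elevating devices, 4.6 observed years
POPULATION = 13.4e6

for label, n_m, r in (("r = 1 (conservative)", N_M, 1),
                      ("r = 10 (sensitivity)", N_M, 10),
                      ("no near misses", 0, 1)):
    est = estimate_rate(N_I, n_m, r=r, T=T)
    print(f"{label:<22} lambda = {est.lam:8.2f} /yr "
          f"= {rate_per_million(est, POPULATION):6.2f} per million persons/yr")

print()
print("the conservative rate is the simulator's default input; the spread")
print("across rows shows how much the near-miss convention moves it")
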