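"""Run the full lunar battery: counts, chi-square, Rayleigh, shift test.

First evaluates the circular tests on the published European onset-count
table (26,912 cycles), then simulates a cohort whose onsets are coupled to
the new moon (von Mises kappa = 2) and shows the series-shift Monte Carlo
test detecting the coupling at the correct phase.
"""

from infradian import (
    SimulationParams,
    chi_square_uniformity,
    count_onsets_by_phase,
    generate_cohort,
    monte_carlo_shift_test,
    rayleigh_grouped,
    rayleigh_per_woman,
)
from infradian.lunar import PHASE_NAMES
from infradian import reference

table = reference.EUROPEAN_TOTAL
chi = chi_square_uniformity(table)
ray = rayleigh_grouped(table)
print(f"published European table (n={table.total}):")
print(f"  chi-square p = {chi.p_value:.4f}; grouped Rayleigh p = {ray.p_value:.4f} "
      f"(mean direction {ray.mean_direction:.0f} deg, toward the waxing crescent)")

params = SimulationParams(
    mu=29.53, sigma=2.0, osc_amplitude=0, ar1=0, jump_prob=0,
    lunar_kappa=2.0, lunar_mu=0.0, n_cycles=24,
)
cohort = generate_cohort(200, params, seed=5)
counts = count_onsets_by_phase(cohort)
res = monte_carlo_shift_test(cohort, n_iter=2000, seed=6)
rw = rayleigh_per_woman(cohort)

print(f"\nsimulated new-moon-coupled cohort ({cohort.n_women} women, "
      f"{cohort.n_cycles} cycles):")
print(f"  per-woman Rayleigh p = {rw.p_value:.2e}")
print("  phase             count   shift-test rank")
for name, c, r, s in zip(PHASE_NAMES, counts.counts, res.ranks, res.significant):
    print(f"  {name:16s} {c:6d}   {r:.4f}{'  +' if s else ''}")
# A rank near 1 means the observed count exceeds almost every count obtained
# after re-placing each woman's series uniformly in the lunar cycle: the
# new-moon sector is flagged, its antiphase neighbours sit near 0.
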