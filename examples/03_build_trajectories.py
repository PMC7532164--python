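"""Concatenate directional pairs into linear disease trajectories.

At 50,000 patients the planted chain I10 -> I50 -> N18 (hypertension ->
heart failure -> chronic kidney disease) accrues enough followers to
survive the minimum-20-patient rule, so the output contains a length-3
trajectory alongside the five length-2 ones.
"""

import trajmine as tm

config = tm.SimulationConfig(n_patients=50_000)
registry = tm.simulate_registry(config, seed=5)
result = tm.mine_directional_pairs(registry, tm.ThresholdConfig(n_controls=100), seed=5)

trajectories = tm.build_trajectories(result.directional, registry, min_followers=20)
trajectories = [tm.trajectory_summary(registry, t) for t in trajectories]

print(f"{len(trajectories)} trajectories (min 20 followers):")
for t in trajectories:
    gaps = ", ".join(f"{g:.1f}" for g in t.inter_diagnosis_times)
    print(
        f"  {'->'.join(t.codes):20s} {t.n_followers:5d} followers, "
        f"mean age at inception {t.mean_age_at_inception:4.1f} y, "
        f"gaps [{gaps}] y, 5-y deaths {t.mortality_5y}"
    )
# A follower's first occurrences appear in trajectory order with any
# other diagnoses interleaved; the gap is the mean time between
# consecutive first occurrences, and the death count is within five
# years of the final diagnosis.
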