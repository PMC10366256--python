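"""How the half-apex angle and penalty exponent drive the load-case count.

A wider sector or a sharper penalty (larger p concentrates weight near the
edge vector) generally means fewer major loads — but the heuristic is not
provably monotone, so the grid is reported as data.
"""

from majorload import generate_daily_activity_dataset, parameter_sweep

dataset = generate_daily_activity_dataset(seed=1, samples_per_activity=60)
grid = parameter_sweep(dataset, half_apex_list=[5.0, 10.0, 15.0],
                       exponent_list=[0.0, 2.0, 6.0])
print(grid.pivot(index="half_apex_deg", columns="penalty_exponent",
                 values="major_load_count"))
print("\nEach cell is the number of static FE load cases needed to envelop "
      "the whole collection at that sector size and penalty sharpness.")
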