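"""Partition in-lung SPECT activity into central vs peripheral deposition.

Builds a lung activity volume with a proximal tracheobronchial cylinder
(trachea + principal bronchi) between two peripheral lobes, a 4 % central
share and Poisson noise, then normalizes the in-lung activity to 100 %
and tests the peripheral-dominance criterion (central < 5 %).
"""

from aerodepo import (
    ScenarioSpec, central_share_flag, partition_fractions,
    render_activity_volume,
)

vol, labels = render_activity_volume(ScenarioSpec(central_fraction=4.0),
                                     total_counts=1e5, seed=3)
res = partition_fractions(vol, labels)

print(f"central     {res.central_pct:5.2f} %  (configured truth 4 %)")
print(f"peripheral  {res.peripheral_pct:5.2f} %")
print(f"outside ROI {res.outside_pct:5.2f} %  (excluded from the 100 %)")
print(f"peripheral-dominant (<5 % central): "
      f"{central_share_flag(res.central_pct)}")
# Central + peripheral are normalized to 100 % of in-lung activity; a
# central share below 5 % reproduces the peripheral-dominant deposition
# pattern seen for all three aerosol size ranges.
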