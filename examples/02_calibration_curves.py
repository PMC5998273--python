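"""Fit and inspect per-zone calibration curves.

Each reaction zone performs a threshold titration: colour appears only
above the zone's threshold and saturates at the top of its range, so only
the rising linear segment is quantitative. This script fits a line to
standard-card signals for every measurement zone and prints the fitted
slope/intercept next to the generating chemistry.
"""

from saltcard import default_layout, quantify, simulate

layout = default_layout()
chems = simulate.default_chemistries(layout)

ladder = [0.5, 1.5, 3, 5, 7, 9, 11, 13, 15, 17, 19, 21, 23, 25, 27, 29,
          31, 33, 35, 37.5, 40, 43, 46, 49]
standards = [
    simulate.render_card(layout, chems, simulate.identity_scenario(c))[0]
    for c in ladder
]
curves = quantify.calibrate_from_images(standards, ladder, layout)

print("zone  range(ppm)   slope  true_gain  intercept  signal_range")
for z in layout.measurement_zones:
    c = curves[z.id]
    lo, hi = z.quant_range
    print(f"{z.id:>4}  {lo:4.0f}-{hi:<4.0f}  {c.slope:7.3f}  {chems[z.id].gain:9.3f}"
          f"  {c.intercept:9.2f}  {c.signal_range[0]:5.1f}-{c.signal_range[1]:5.1f}")

# exact inversion over the linear range
curve = curves[layout.measurement_zones[0].id]
for ppm in (2.0, 6.0, 10.0):
    signal = curve.intercept + curve.slope * ppm
    reading = quantify.invert_calibration(
        quantify.ZoneSignal(curve.zone_id, signal, 100, 0.0), curve
    )
    print(f"signal {signal:6.1f} -> {reading.concentration:.3f} ppm (expected {ppm})")
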