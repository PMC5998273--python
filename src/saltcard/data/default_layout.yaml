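# Default card geometry. All lengths in millimetres; origin at the top-left
# card corner, x rightward, y downward.
#
# Twelve wax-bounded reaction squares in a 4 x 3 grid, each with a central
# indicator circle (the ROI). Measurement zones form three replicate ladders
# covering 0-35 ppm iodine (triplicate coverage at every point), plus one
# high-range zone extending toward the 30-50 ppm production band. One square
# is a positive control (pre-loaded analyte: must always develop) and one a
# negative control (masked: must never develop).
#
# The six registration (fiducial) marks are deliberately asymmetric so the
# constellation has a unique match under similarity transforms.
card_size: [120.0, 90.0]
fiducials:
  - {id: 1, center: [6.0, 6.0], radius: 2.5}
  - {id: 2, center: [60.0, 6.0], radius: 2.5}
  - {id: 3, center: [114.0, 6.0], radius: 2.5}
  - {id: 4, center: [6.0, 84.0], radius: 2.5}
  - {id: 5, center: [114.0, 84.0], radius: 2.5}
  - {id: 6, center: [72.0, 59.0], radius: 2.5}
zones:
  - {id: 1, square: [8.0, 14.0, 18.0, 18.0], roi_center: [17.0, 23.0], roi_radius: 4.0, role: measurement, quant_range: [0.0, 12.0]}
  - {id: 2, square: [30.0, 14.0, 18.0, 18.0], roi_center: [39.0, 23.0], roi_radius: 4.0, role: measurement, quant_range: [10.0, 24.0]}
  - {id: 3, square: [52.0, 14.0, 18.0, 18.0], roi_center: [61.0, 23.0], roi_radius: 4.0, role: measurement, quant_range: [22.0, 36.0]}
  - {id: 4, square: [74.0, 14.0, 18.0, 18.0], roi_center: [83.0, 23.0], roi_radius: 4.0, role: positive_control, quant_range: [0.0, 50.0]}
  - {id: 5, square: [8.0, 38.0, 18.0, 18.0], roi_center: [17.0, 47.0], roi_radius: 4.0, role: measurement, quant_range: [0.0, 12.0]}
  - {id: 6, square: [30.0, 38.0, 18.0, 18.0], roi_center: [39.0, 47.0], roi_radius: 4.0, role: measurement, quant_range: [10.0, 24.0]}
  - {id: 7, square: [52.0, 38.0, 18.0, 18.0], roi_center: [61.0, 47.0], roi_radius: 4.0, role: measurement, quant_range: [22.0, 36.0]}
  - {id: 8, square: [74.0, 38.0, 18.0, 18.0], roi_center: [83.0, 47.0], roi_radius: 4.0, role: negative_control, quant_range: [0.0, 50.0]}
  - {id: 9, square: [8.0, 62.0, 18.0, 18.0], roi_center: [17.0, 71.0], roi_radius: 4.0, role: measurement, quant_range: [0.0, 12.0]}
  - {id: 10, square: [30.0, 62.0, 18.0, 18.0], roi_center: [39.0, 71.0], roi_radius: 4.0, role: measurement, quant_range: [10.0, 24.0]}
  - {id: 11, square: [52.0, 62.0, 18.0, 18.0], roi_center: [61.0, 71.0], roi_radius: 4.0, role: measurement, quant_range: [22.0, 36.0]}
  - {id: 12, square: [74.0, 62.0, 18.0, 18.0], roi_center: [83.0, 71.0], roi_radius: 4.0, role: measurement, quant_range: [28.0, 50.0]}
color_standards:
  - {id: 1, bounds: [96.0, 14.0, 8.0, 8.0], nominal_color: [0.92, 0.92, 0.92]}
  - {id: 2, bounds: [96.0, 26.0, 8.0, 8.0], nominal_color: [0.55, 0.55, 0.55]}
  - {id: 3, bounds: [96.0, 38.0, 8.0, 8.0], nominal_color: [0.25, 0.25, 0.25]}
  - {id: 4, bounds: [96.0, 72.0, 8.0, 8.0], nominal_color: [0.78, 0.62, 0.45]}
qr_region: [96.0, 50.0, 16.0, 16.0]
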