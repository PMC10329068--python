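{
  "name": "AAQ-17",
  "orientation": "higher_theta_more_limitation",
  "items": [
    {"id": "AAQ_01", "label": "Ascending stairs", "a": 2.743, "b": [0.126, 0.960, 1.954, 2.798]},
    {"id": "AAQ_02", "label": "Descending stairs", "a": 2.386, "b": [-0.191, 0.698, 1.802, 2.275, 3.096]},
    {"id": "AAQ_03", "label": "Walking outside on a flat surface", "a": 2.857, "b": [0.130, 1.168, 1.443, 2.193, 3.259]},
    {"id": "AAQ_04", "label": "Walking outside on uneven terrain", "a": 2.964, "b": [0.156, 1.079, 1.429, 2.444]},
    {"id": "AAQ_05", "label": "Walking inside: starting walking after at least 15 min sitting", "a": 2.467, "b": [-0.526, 0.879, 2.173, 3.363]},
    {"id": "AAQ_06", "label": "Ascending a bridge", "a": 3.453, "b": [0.087, 1.326, 2.123, 2.928]},
    {"id": "AAQ_07", "label": "Descending a bridge", "a": 3.132, "b": [0.005, 1.406, 2.221, 3.092]},
    {"id": "AAQ_08", "label": "Picking up an object from floor", "a": 2.260, "b": [0.092, 1.033, 1.710, 2.869]},
    {"id": "AAQ_09", "label": "Rising from the floor", "a": 1.983, "b": [-0.240, 0.987, 1.859]},
    {"id": "AAQ_10", "label": "Rising from a chair", "a": 2.693, "b": [-0.346, 1.230, 2.024, 3.526]},
    {"id": "AAQ_11", "label": "Sitting down on a chair", "a": 2.734, "b": [-0.105, 1.312, 1.823, 3.690]},
    {"id": "AAQ_12", "label": "Rising from a sofa", "a": 2.789, "b": [-0.886, 0.590, 1.553, 2.629]},
    {"id": "AAQ_13", "label": "Sitting down on a sofa", "a": 2.779, "b": [-0.400, 0.898, 1.606, 2.800]},
    {"id": "AAQ_14", "label": "Rising from a toilet", "a": 2.964, "b": [0.072, 0.929, 2.002, 3.195]},
    {"id": "AAQ_15", "label": "Sitting down on a toilet", "a": 2.727, "b": [0.186, 1.126, 2.234, 3.430]},
    {"id": "AAQ_16", "label": "Putting on shoes", "a": 1.403, "b": [-1.561, -0.259, 1.433, 3.055]},
    {"id": "AAQ_17", "label": "Taking off shoes", "a": 1.289, "b": [-0.461, 0.505, 3.144]}
  ]
}
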