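{
  "description": "Schematic right-scapula landmark template (synthetic). Units are millimetres in the canonical scapula frame: x lateral, y superior, z posterior; origin at the glenoid rim centroid. Hand-built stand-in geometry, not derived from any imaged specimen.",
  "frame": {"x": "lateral", "y": "superior", "z": "posterior"},
  "landmarks": [
    {"name": "glenoid_rim_superior",        "xyz": [0.0, 16.0, 0.0]},
    {"name": "glenoid_rim_posterosuperior", "xyz": [0.0, 11.3137085, 8.48528137]},
    {"name": "glenoid_rim_posterior",       "xyz": [0.0, 0.0, 12.0]},
    {"name": "glenoid_rim_posteroinferior", "xyz": [0.0, -11.3137085, 8.48528137]},
    {"name": "glenoid_rim_inferior",        "xyz": [0.0, -16.0, 0.0]},
    {"name": "glenoid_rim_anteroinferior",  "xyz": [0.0, -11.3137085, -8.48528137]},
    {"name": "glenoid_rim_anterior",        "xyz": [0.0, 0.0, -12.0]},
    {"name": "glenoid_rim_anterosuperior",  "xyz": [0.0, 11.3137085, -8.48528137]},
    {"name": "supraglenoid_tubercle",       "xyz": [-3.0, 17.0, 0.0]},
    {"name": "infraglenoid_tubercle",       "xyz": [-4.0, -18.0, 1.0]},
    {"name": "coracoid_base",               "xyz": [-12.0, 16.0, -6.0]},
    {"name": "coracoid_tip",                "xyz": [4.0, 10.0, -22.0]},
    {"name": "acromion_anterior",           "xyz": [15.0, 28.0, -14.0]},
    {"name": "acromion_lateral",            "xyz": [25.0, 30.0, 0.0]},
    {"name": "acromion_posterior",          "xyz": [5.0, 28.0, 14.0]},
    {"name": "acromion_angle",              "xyz": [-8.0, 26.0, 18.0]},
    {"name": "spine_lateral",               "xyz": [-22.0, 18.0, 12.0]},
    {"name": "spine_medial",                "xyz": [-88.0, 8.0, 6.0]},
    {"name": "fossa_medial",                "xyz": [-85.0, 12.0, 1.0]},
    {"name": "fossa_anterior",              "xyz": [-50.0, 13.0, -9.0]},
    {"name": "fossa_lateral",               "xyz": [-20.0, 13.0, 0.0]},
    {"name": "fossa_posterior",             "xyz": [-50.0, 13.0, 9.0]},
    {"name": "medial_border_superior",      "xyz": [-100.0, 10.0, 0.0]},
    {"name": "medial_border_mid",           "xyz": [-100.0, -25.0, 0.0]},
    {"name": "medial_border_inferior",      "xyz": [-100.0, -60.0, 0.0]},
    {"name": "inferior_angle",              "xyz": [-92.0, -72.0, 0.0]},
    {"name": "blade_center",                "xyz": [-55.0, -25.0, 0.0]},
    {"name": "scapular_notch",              "xyz": [-18.0, 14.0, -6.0]},
    {"name": "teres_major_origin",          "xyz": [-58.0, -55.0, 2.0]}
  ]
}
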