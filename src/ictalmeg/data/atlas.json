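{
  "version": 1,
  "frame": "head (mm): origin = preauricular midpoint, x right, y nasion, z up; synthetic box parcellation for a 96 mm sphere model",
  "regions": [
    {"label": "MFC", "lo_mm": [-20, 25, 5],    "hi_mm": [20, 96, 96]},
    {"label": "LFL", "lo_mm": [-96, 25, -5],   "hi_mm": [-25, 96, 96]},
    {"label": "LFL", "lo_mm": [25, 25, -5],    "hi_mm": [96, 96, 96]},
    {"label": "FC",  "lo_mm": [-96, 20, -15],  "hi_mm": [96, 96, 96]},
    {"label": "TH",  "lo_mm": [-22, -25, -15], "hi_mm": [22, 18, 25]},
    {"label": "PCC", "lo_mm": [-15, -50, 5],   "hi_mm": [15, -18, 40]},
    {"label": "Pc",  "lo_mm": [-20, -75, 35],  "hi_mm": [20, -35, 96]},
    {"label": "MOC", "lo_mm": [-25, -96, -15], "hi_mm": [25, -60, 40]},
    {"label": "TPJ", "lo_mm": [-96, -60, 5],   "hi_mm": [-35, -15, 50]},
    {"label": "TPJ", "lo_mm": [35, -60, 5],    "hi_mm": [96, -15, 50]},
    {"label": "TC",  "lo_mm": [-96, -35, -96], "hi_mm": [-32, 20, 10]},
    {"label": "TC",  "lo_mm": [32, -35, -96],  "hi_mm": [96, 20, 10]},
    {"label": "CE",  "lo_mm": [-96, -96, -96], "hi_mm": [96, -25, -25]},
    {"label": "POT", "lo_mm": [-96, -96, -25], "hi_mm": [96, -35, 35]},
    {"label": "PL",  "lo_mm": [-96, -60, 25],  "hi_mm": [96, 20, 96]},
    {"label": "DBA", "lo_mm": [-96, -96, -96], "hi_mm": [96, 96, 96]}
  ]
}
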