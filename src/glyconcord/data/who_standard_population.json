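{
  "description": "WHO world standard population, percent of total population per 5-year age band (Ahmad et al., GPE Discussion Paper 31, WHO 2001).",
  "bands": [
    {"lower": 0, "upper": 5, "percent": 8.86},
    {"lower": 5, "upper": 10, "percent": 8.69},
    {"lower": 10, "upper": 15, "percent": 8.60},
    {"lower": 15, "upper": 20, "percent": 8.47},
    {"lower": 20, "upper": 25, "percent": 8.22},
    {"lower": 25, "upper": 30, "percent": 7.93},
    {"lower": 30, "upper": 35, "percent": 7.61},
    {"lower": 35, "upper": 40, "percent": 7.15},
    {"lower": 40, "upper": 45, "percent": 6.59},
    {"lower": 45, "upper": 50, "percent": 6.04},
    {"lower": 50, "upper": 55, "percent": 5.37},
    {"lower": 55, "upper": 60, "percent": 4.55},
    {"lower": 60, "upper": 65, "percent": 3.72},
    {"lower": 65, "upper": 70, "percent": 2.96},
    {"lower": 70, "upper": 75, "percent": 2.21},
    {"lower": 75, "upper": 80, "percent": 1.52},
    {"lower": 80, "upper": 85, "percent": 0.91},
    {"lower": 85, "upper": 90, "percent": 0.44},
    {"lower": 90, "upper": 95, "percent": 0.15},
    {"lower": 95, "upper": 100, "percent": 0.04},
    {"lower": 100, "upper": 200, "percent": 0.005}
  ]
}
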