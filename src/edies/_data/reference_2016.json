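{
  "name": "reference-2016",
  "ps_by_score": {
    "0": 1.00000,
    "1": 0.99973,
    "2": 0.99935,
    "3": 0.99842,
    "4": 0.99511,
    "5": 0.98673,
    "6": 0.97252,
    "7": 0.95153,
    "8": 0.92339,
    "9": 0.88886,
    "10": 0.84543,
    "11": 0.79589,
    "12": 0.75019,
    "13": 0.69430,
    "14": 0.95177,
    "15": 0.59030,
    "16": 0.52206,
    "17": 0.49335,
    "18": 0.46640,
    "19": 0.44246,
    "20": 0.40063,
    "21": 0.37624
  },
  "top_ps_min_score": 22,
  "top_ps": 0.24753,
  "strata": [
    {"label": "0",   "scores": [0],  "count": 27248,  "printed_fraction": 0.0148},
    {"label": "1",   "scores": [1],  "count": 106039, "printed_fraction": 0.0577},
    {"label": "2",   "scores": [2],  "count": 198739, "printed_fraction": 0.1082},
    {"label": "3",   "scores": [3],  "count": 356919, "printed_fraction": 0.1943},
    {"label": "4",   "scores": [4],  "count": 393640, "printed_fraction": 0.2143},
    {"label": "5",   "scores": [5],  "count": 284345, "printed_fraction": 0.1548},
    {"label": "6",   "scores": [6],  "count": 177881, "printed_fraction": 0.0969},
    {"label": "7",   "scores": [7],  "count": 110766, "printed_fraction": 0.0603},
    {"label": "8",   "scores": [8],  "count": 68128,  "printed_fraction": 0.0371},
    {"label": "9",   "scores": [9],  "count": 41147,  "printed_fraction": 0.0224},
    {"label": "10",  "scores": [10], "count": 25930,  "printed_fraction": 0.0141},
    {"label": "11",  "scores": [11], "count": 16462,  "printed_fraction": 0.0090},
    {"label": "12",  "scores": [12], "count": 10616,  "printed_fraction": 0.0058},
    {"label": "13",  "scores": [13], "count": 6670,   "printed_fraction": 0.0036},
    {"label": "14",  "scores": [14], "count": 4319,   "printed_fraction": 0.0024},
    {"label": "15",  "scores": [15], "count": 2763,   "printed_fraction": 0.0015},
    {"label": "16",  "scores": [16], "count": 1768,   "printed_fraction": 0.0010},
    {"label": "17-18", "scores": [17, 18], "count": 1871, "printed_fraction": 0.0010},
    {"label": ">=19", "scores": [19, 20, 21, 22, 23, 24, 25, 26, 27, 28, 29, 30, 31, 32, 33, 34, 35, 36, 37, 38, 39], "count": 1326, "printed_fraction": 0.0007}
  ]
}
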