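{
  "name": "edies-v1",
  "items": [
    {
      "name": "sex",
      "field": "sex",
      "kind": "categorical",
      "scores": {"male": 1, "female": 0}
    },
    {
      "name": "event",
      "field": "cause",
      "kind": "categorical",
      "scores": {"disease": 2, "non_disease": 0}
    },
    {
      "name": "avpu",
      "field": "avpu",
      "kind": "categorical",
      "scores": {"A": 0, "V": 2, "P": 3, "U": 7}
    },
    {
      "name": "age",
      "field": "age",
      "kind": "binned",
      "lower": 15,
      "bins": [[39, 0], [70, 1], [78, 2], [85, 3], [93, 4]],
      "above": 5
    },
    {
      "name": "sbp",
      "field": "sbp",
      "kind": "binned",
      "lower": 0,
      "bins": [[21, 11], [26, 10], [33, 9], [39, 8], [46, 7], [52, 6], [60, 5], [67, 4], [78, 3], [90, 2], [106, 1], [202, 0]],
      "above": 1
    },
    {
      "name": "hr",
      "field": "hr",
      "kind": "binned",
      "lower": 0,
      "bins": [[42, 2], [54, 1], [87, 0], [120, 1], [140, 2]],
      "above": 3
    },
    {
      "name": "rr",
      "field": "rr",
      "kind": "binned",
      "lower": 0,
      "bins": [[5, 6], [7, 3], [13, 1], [20, 0], [33, 1]],
      "above": 2
    },
    {
      "name": "spo2",
      "field": "spo2",
      "kind": "binned",
      "lower": 0,
      "bins": [[82, 4], [86, 3], [91, 2], [96, 1]],
      "above": 0
    }
  ]
}
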