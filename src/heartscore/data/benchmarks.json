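{
  "provenance": "formative survey reference values (n=309, Johannesburg 2016)",
  "benchmarks": {
    "TV": {
      "mean": 31.7,
      "sd": 13.9
    },
    "PS": {
      "mean": 46.2,
      "sd": 10.3
    },
    "PAC": {
      "mean": 19.5,
      "sd": 9.5
    },
    "PR": {
      "mean": 10.5,
      "sd": 6.5
    },
    "HPR": {
      "mean": 27.3,
      "sd": 3.7
    }
  }
}
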