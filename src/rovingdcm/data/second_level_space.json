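{
  "description": "Default second-level model space for the ketamine effect: exclusively-extrinsic models over {A, B} and exclusively-intrinsic models over {tau, g, M, N} (singletons, pairs, and the full intrinsic set).",
  "models": [
    {"name": "A", "family": "extrinsic", "groups": ["A"]},
    {"name": "B", "family": "extrinsic", "groups": ["B"]},
    {"name": "A+B", "family": "extrinsic", "groups": ["A", "B"]},
    {"name": "tau", "family": "intrinsic", "groups": ["tau"]},
    {"name": "g", "family": "intrinsic", "groups": ["g"]},
    {"name": "M", "family": "intrinsic", "groups": ["M"]},
    {"name": "N", "family": "intrinsic", "groups": ["N"]},
    {"name": "tau+g", "family": "intrinsic", "groups": ["tau", "g"]},
    {"name": "tau+M", "family": "intrinsic", "groups": ["tau", "M"]},
    {"name": "tau+N", "family": "intrinsic", "groups": ["tau", "N"]},
    {"name": "g+M", "family": "intrinsic", "groups": ["g", "M"]},
    {"name": "g+N", "family": "intrinsic", "groups": ["g", "N"]},
    {"name": "M+N", "family": "intrinsic", "groups": ["M", "N"]},
    {"name": "tau+g+M+N", "family": "intrinsic", "groups": ["tau", "g", "M", "N"]}
  ]
}
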