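[
 {
  "name": "4-[(2,4-dichlorobenzenesulfonamido)methyl]cyclohexane carboxylic acid",
  "partition": [
   {"du": 1, "dv": 3, "count": 4},
   {"du": 2, "dv": 2, "count": 3},
   {"du": 2, "dv": 3, "count": 9},
   {"du": 3, "dv": 4, "count": 4},
   {"du": 1, "dv": 2, "count": 1},
   {"du": 3, "dv": 3, "count": 2},
   {"du": 1, "dv": 4, "count": 4}
  ],
  "properties": {"melting_point_C": 191, "formula_weight": 366.25}
 },
 {
  "name": "ethyl 4-[(2-naphthalenesulfonamido)methyl]cyclohexane carboxylate",
  "partition": [
   {"du": 2, "dv": 2, "count": 6},
   {"du": 2, "dv": 3, "count": 11},
   {"du": 3, "dv": 4, "count": 4},
   {"du": 1, "dv": 4, "count": 9},
   {"du": 1, "dv": 3, "count": 2},
   {"du": 3, "dv": 3, "count": 2},
   {"du": 2, "dv": 4, "count": 1},
   {"du": 4, "dv": 4, "count": 1}
  ],
  "properties": {"melting_point_C": 140, "formula_weight": 375.47}
 },
 {
  "name": "ethyl 4-[(2,4-dichlorobenzenesulfonamido)methyl]cyclohexane carboxylate",
  "partition": [
   {"du": 1, "dv": 3, "count": 4},
   {"du": 2, "dv": 3, "count": 9},
   {"du": 2, "dv": 2, "count": 3},
   {"du": 1, "dv": 4, "count": 9},
   {"du": 3, "dv": 4, "count": 4},
   {"du": 4, "dv": 4, "count": 1},
   {"du": 3, "dv": 3, "count": 2},
   {"du": 2, "dv": 4, "count": 1}
  ],
  "properties": {"melting_point_C": 133, "formula_weight": 394.3}
 },
 {
  "name": "4-[(naphthalene-2-sulfonamido)methyl]cyclohexane-1-carboxylic acid",
  "partition": [
   {"du": 1, "dv": 2, "count": 1},
   {"du": 1, "dv": 3, "count": 2},
   {"du": 1, "dv": 4, "count": 4},
   {"du": 2, "dv": 2, "count": 6},
   {"du": 2, "dv": 3, "count": 11},
   {"du": 3, "dv": 3, "count": 2},
   {"du": 3, "dv": 4, "count": 4}
  ],
  "properties": {"melting_point_C": 210, "formula_weight": 347.42}
 },
 {
  "name": "(2S)-3-methyl-2-(naphthalene-1-sulfonamido)-butanoic acid",
  "partition": [
   {"du": 1, "dv": 2, "count": 1},
   {"du": 1, "dv": 3, "count": 2},
   {"du": 1, "dv": 4, "count": 10},
   {"du": 2, "dv": 2, "count": 4},
   {"du": 2, "dv": 3, "count": 7},
   {"du": 3, "dv": 3, "count": 1},
   {"du": 3, "dv": 4, "count": 4},
   {"du": 4, "dv": 4, "count": 3}
  ],
  "properties": {"melting_point_C": 148, "formula_weight": 307.35}
 }
]
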