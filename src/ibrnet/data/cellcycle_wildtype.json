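{
 "n": 10,
 "genes": [
  "CycD",
  "Rb",
  "p27",
  "E2F",
  "CycE",
  "CycA",
  "Cdc20",
  "Cdh1",
  "UbcH10",
  "CycB"
 ],
 "functions": [
  {
   "target": "CycD",
   "regulators": [],
   "table": [
    0
   ]
  },
  {
   "target": "Rb",
   "regulators": [
    "CycD",
    "CycE",
    "CycA",
    "CycB",
    "p27"
   ],
   "table": [
    1,
    1,
    0,
    0,
    0,
    1,
    0,
    0,
    0,
    1,
    0,
    0,
    0,
    1,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0
   ]
  },
  {
   "target": "p27",
   "regulators": [
    "CycD",
    "CycE",
    "CycA",
    "CycB",
    "p27"
   ],
   "table": [
    1,
    1,
    0,
    0,
    0,
    1,
    0,
    0,
    0,
    1,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0
   ]
  },
  {
   "target": "E2F",
   "regulators": [
    "Rb",
    "CycA",
    "CycB",
    "p27"
   ],
   "table": [
    1,
    1,
    0,
    0,
    0,
    1,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0
   ]
  },
  {
   "target": "CycE",
   "regulators": [
    "E2F",
    "Rb"
   ],
   "table": [
    0,
    0,
    1,
    0
   ]
  },
  {
   "target": "CycA",
   "regulators": [
    "E2F",
    "Rb",
    "Cdc20",
    "Cdh1",
    "UbcH10",
    "CycA"
   ],
   "table": [
    0,
    1,
    0,
    1,
    0,
    1,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    1,
    1,
    1,
    1,
    1,
    1,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0
   ]
  },
  {
   "target": "Cdc20",
   "regulators": [
    "CycB"
   ],
   "table": [
    0,
    1
   ]
  },
  {
   "target": "Cdh1",
   "regulators": [
    "CycA",
    "CycB",
    "Cdc20",
    "p27"
   ],
   "table": [
    1,
    1,
    1,
    1,
    0,
    0,
    1,
    1,
    0,
    1,
    1,
    1,
    0,
    0,
    1,
    1
   ]
  },
  {
   "target": "UbcH10",
   "regulators": [
    "Cdh1",
    "UbcH10",
    "Cdc20",
    "CycA",
    "CycB"
   ],
   "table": [
    1,
    1,
    1,
    1,
    1,
    1,
    1,
    1,
    1,
    1,
    1,
    1,
    1,
    1,
    1,
    1,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    0,
    1,
    1,
    1,
    1,
    1,
    1,
    1
   ]
  },
  {
   "target": "CycB",
   "regulators": [
    "Cdc20",
    "Cdh1"
   ],
   "table": [
    1,
    0,
    0,
    0
   ]
  }
 ],
 "label": "wild-type"
}
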