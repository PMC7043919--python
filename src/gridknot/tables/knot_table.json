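{
 "version": 1,
 "knots": [
  {
   "name": "0_1",
   "alexander": {
    "coeffs": [
     1
    ],
    "minexp": 0
   },
   "jones": [
    {
     "coeffs": [
      1
     ],
     "minexp": 0
    }
   ]
  },
  {
   "name": "3_1",
   "alexander": {
    "coeffs": [
     1,
     -1,
     1
    ],
    "minexp": -1
   },
   "jones": [
    {
     "coeffs": [
      -1,
      1,
      0,
      1
     ],
     "minexp": -4
    }
   ]
  },
  {
   "name": "4_1",
   "alexander": {
    "coeffs": [
     -1,
     3,
     -1
    ],
    "minexp": -1
   },
   "jones": [
    {
     "coeffs": [
      1,
      -1,
      1,
      -1,
      1
     ],
     "minexp": -2
    }
   ]
  },
  {
   "name": "5_1",
   "alexander": {
    "coeffs": [
     1,
     -1,
     1,
     -1,
     1
    ],
    "minexp": -2
   },
   "jones": [
    {
     "coeffs": [
      -1,
      1,
      -1,
      1,
      0,
      1
     ],
     "minexp": -7
    }
   ]
  },
  {
   "name": "5_2",
   "alexander": {
    "coeffs": [
     2,
     -3,
     2
    ],
    "minexp": -1
   },
   "jones": [
    {
     "coeffs": [
      -1,
      1,
      -1,
      2,
      -1,
      1
     ],
     "minexp": -6
    }
   ]
  },
  {
   "name": "6_1",
   "alexander": {
    "coeffs": [
     -2,
     5,
     -2
    ],
    "minexp": -1
   },
   "jones": []
  },
  {
   "name": "6_2",
   "alexander": {
    "coeffs": [
     -1,
     3,
     -3,
     3,
     -1
    ],
    "minexp": -2
   },
   "jones": []
  },
  {
   "name": "6_3",
   "alexander": {
    "coeffs": [
     1,
     -3,
     5,
     -3,
     1
    ],
    "minexp": -2
   },
   "jones": []
  },
  {
   "name": "7_1",
   "alexander": {
    "coeffs": [
     1,
     -1,
     1,
     -1,
     1,
     -1,
     1
    ],
    "minexp": -3
   },
   "jones": [
    {
     "coeffs": [
      -1,
      1,
      -1,
      1,
      -1,
      1,
      0,
      1
     ],
     "minexp": -10
    }
   ]
  },
  {
   "name": "7_2",
   "alexander": {
    "coeffs": [
     3,
     -5,
     3
    ],
    "minexp": -1
   },
   "jones": []
  },
  {
   "name": "7_3",
   "alexander": {
    "coeffs": [
     2,
     -3,
     3,
     -3,
     2
    ],
    "minexp": -2
   },
   "jones": []
  },
  {
   "name": "7_4",
   "alexander": {
    "coeffs": [
     4,
     -7,
     4
    ],
    "minexp": -1
   },
   "jones": []
  },
  {
   "name": "7_5",
   "alexander": {
    "coeffs": [
     2,
     -4,
     5,
     -4,
     2
    ],
    "minexp": -2
   },
   "jones": []
  },
  {
   "name": "7_6",
   "alexander": {
    "coeffs": [
     -1,
     5,
     -7,
     5,
     -1
    ],
    "minexp": -2
   },
   "jones": []
  },
  {
   "name": "7_7",
   "alexander": {
    "coeffs": [
     1,
     -5,
     9,
     -5,
     1
    ],
    "minexp": -2
   },
   "jones": []
  },
  {
   "name": "8_1",
   "alexander": {
    "coeffs": [
     -3,
     7,
     -3
    ],
    "minexp": -1
   },
   "jones": []
  },
  {
   "name": "8_2",
   "alexander": {
    "coeffs": [
     -1,
     3,
     -3,
     3,
     -3,
     3,
     -1
    ],
    "minexp": -3
   },
   "jones": []
  },
  {
   "name": "8_3",
   "alexander": {
    "coeffs": [
     -4,
     9,
     -4
    ],
    "minexp": -1
   },
   "jones": []
  },
  {
   "name": "8_4",
   "alexander": {
    "coeffs": [
     -2,
     5,
     -5,
     5,
     -2
    ],
    "minexp": -2
   },
   "jones": []
  },
  {
   "name": "8_5",
   "alexander": {
    "coeffs": [
     -1,
     3,
     -4,
     5,
     -4,
     3,
     -1
    ],
    "minexp": -3
   },
   "jones": []
  },
  {
   "name": "8_6",
   "alexander": {
    "coeffs": [
     -2,
     6,
     -7,
     6,
     -2
    ],
    "minexp": -2
   },
   "jones": []
  },
  {
   "name": "8_7",
   "alexander": {
    "coeffs": [
     1,
     -3,
     5,
     -5,
     5,
     -3,
     1
    ],
    "minexp": -3
   },
   "jones": []
  },
  {
   "name": "8_8",
   "alexander": {
    "coeffs": [
     2,
     -6,
     9,
     -6,
     2
    ],
    "minexp": -2
   },
   "jones": []
  },
  {
   "name": "8_9",
   "alexander": {
    "coeffs": [
     -1,
     3,
     -5,
     7,
     -5,
     3,
     -1
    ],
    "minexp": -3
   },
   "jones": []
  },
  {
   "name": "8_10",
   "alexander": {
    "coeffs": [
     1,
     -3,
     6,
     -7,
     6,
     -3,
     1
    ],
    "minexp": -3
   },
   "jones": []
  },
  {
   "name": "8_11",
   "alexander": {
    "coeffs": [
     -2,
     7,
     -9,
     7,
     -2
    ],
    "minexp": -2
   },
   "jones": []
  },
  {
   "name": "8_12",
   "alexander": {
    "coeffs": [
     1,
     -7,
     13,
     -7,
     1
    ],
    "minexp": -2
   },
   "jones": []
  },
  {
   "name": "8_13",
   "alexander": {
    "coeffs": [
     2,
     -7,
     11,
     -7,
     2
    ],
    "minexp": -2
   },
   "jones": []
  },
  {
   "name": "8_14",
   "alexander": {
    "coeffs": [
     -2,
     8,
     -11,
     8,
     -2
    ],
    "minexp": -2
   },
   "jones": []
  },
  {
   "name": "8_15",
   "alexander": {
    "coeffs": [
     3,
     -8,
     11,
     -8,
     3
    ],
    "minexp": -2
   },
   "jones": []
  },
  {
   "name": "8_16",
   "alexander": {
    "coeffs": [
     1,
     -4,
     8,
     -9,
     8,
     -4,
     1
    ],
    "minexp": -3
   },
   "jones": []
  },
  {
   "name": "8_17",
   "alexander": {
    "coeffs": [
     -1,
     4,
     -8,
     11,
     -8,
     4,
     -1
    ],
    "minexp": -3
   },
   "jones": []
  },
  {
   "name": "8_18",
   "alexander": {
    "coeffs": [
     -1,
     5,
     -10,
     13,
     -10,
     5,
     -1
    ],
    "minexp": -3
   },
   "jones": []
  },
  {
   "name": "8_19",
   "alexander": {
    "coeffs": [
     1,
     -1,
     0,
     1,
     0,
     -1,
     1
    ],
    "minexp": -3
   },
   "jones": [
    {
     "coeffs": [
      -1,
      0,
      0,
      1,
      0,
      1
     ],
     "minexp": -8
    }
   ]
  },
  {
   "name": "8_20",
   "alexander": {
    "coeffs": [
     1,
     -2,
     3,
     -2,
     1
    ],
    "minexp": -2
   },
   "jones": []
  },
  {
   "name": "8_21",
   "alexander": {
    "coeffs": [
     -1,
     4,
     -5,
     4,
     -1
    ],
    "minexp": -2
   },
   "jones": []
  },
  {
   "name": "3_1#3_1",
   "alexander": {
    "coeffs": [
     1,
     -2,
     3,
     -2,
     1
    ],
    "minexp": -2
   },
   "jones": [
    {
     "coeffs": [
      1,
      -2,
      1,
      -2,
      2,
      0,
      1
     ],
     "minexp": -8
    },
    {
     "coeffs": [
      -1,
      1,
      -1,
      3,
      -1,
      1,
      -1
     ],
     "minexp": -3
    }
   ]
  }
 ]
}
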