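{
 "profile": "controlled",
 "seed": 3,
 "frames": [
  0,
  45,
  90,
  135,
  179
 ],
 "keypoints": {
  "0": [
   [
    500.0,
    345.0
   ],
   [
    488.0,
    335.0
   ],
   [
    512.0,
    335.0
   ],
   [
    478.0,
    339.0
   ],
   [
    522.0,
    339.0
   ],
   [
    455.0,
    400.0
   ],
   [
    545.0,
    400.0
   ],
   [
    449.0,
    475.0
   ],
   [
    551.0,
    475.0
   ],
   [
    443.0,
    540.0
   ],
   [
    557.0,
    540.0
   ],
   [
    468.0,
    560.0
   ],
   [
    532.0,
    560.0
   ],
   [
    468.0,
    655.0
   ],
   [
    532.0,
    655.0
   ],
   [
    468.0,
    745.0
   ],
   [
    532.0,
    745.0
   ]
  ],
  "45": [
   [
    428.623265,
    826.677149
   ],
   [
    416.623265,
    816.677149
   ],
   [
    440.623265,
    816.677149
   ],
   [
    406.623265,
    820.677149
   ],
   [
    450.623265,
    820.677149
   ],
   [
    407.736694,
    844.589571
   ],
   [
    497.736694,
    844.589571
   ],
   [
    393.727661,
    895.147188
   ],
   [
    511.745727,
    895.147188
   ],
   [
    403.449096,
    919.686739
   ],
   [
    502.024292,
    919.686739
   ],
   [
    549.176758,
    940.0
   ],
   [
    613.176758,
    940.0
   ],
   [
    515.954102,
    999.404297
   ],
   [
    646.399414,
    999.404297
   ],
   [
    485.697754,
    1045.50293
   ],
   [
    676.655762,
    1045.50293
   ]
  ],
  "90": [
   [
    677.075,
    940.0
   ],
   [
    665.075,
    930.0
   ],
   [
    689.075,
    930.0
   ],
   [
    655.075,
    934.0
   ],
   [
    699.075,
    934.0
   ],
   [
    645.0,
    940.0
   ],
   [
    735.0,
    940.0
   ],
   [
    625.5,
    973.8
   ],
   [
    754.5,
    973.8
   ],
   [
    646.0,
    970.6
   ],
   [
    734.0,
    970.6
   ],
   [
    818.0,
    940.0
   ],
   [
    882.0,
    940.0
   ],
   [
    762.0,
    975.0
   ],
   [
    938.0,
    975.0
   ],
   [
    711.0,
    991.0
   ],
   [
    989.0,
    991.0
   ]
  ],
  "135": [
   [
    677.075,
    940.0
   ],
   [
    665.075,
    930.0
   ],
   [
    689.075,
    930.0
   ],
   [
    655.075,
    934.0
   ],
   [
    699.075,
    934.0
   ],
   [
    645.0,
    940.0
   ],
   [
    735.0,
    940.0
   ],
   [
    625.5,
    973.8
   ],
   [
    754.5,
    973.8
   ],
   [
    646.0,
    970.6
   ],
   [
    734.0,
    970.6
   ],
   [
    818.0,
    940.0
   ],
   [
    882.0,
    940.0
   ],
   [
    762.0,
    975.0
   ],
   [
    938.0,
    975.0
   ],
   [
    711.0,
    991.0
   ],
   [
    989.0,
    991.0
   ]
  ],
  "179": [
   [
    677.075,
    940.0
   ],
   [
    665.075,
    930.0
   ],
   [
    689.075,
    930.0
   ],
   [
    655.075,
    934.0
   ],
   [
    699.075,
    934.0
   ],
   [
    645.0,
    940.0
   ],
   [
    735.0,
    940.0
   ],
   [
    625.5,
    973.8
   ],
   [
    754.5,
    973.8
   ],
   [
    646.0,
    970.6
   ],
   [
    734.0,
    970.6
   ],
   [
    818.0,
    940.0
   ],
   [
    882.0,
    940.0
   ],
   [
    762.0,
    975.0
   ],
   [
    938.0,
    975.0
   ],
   [
    711.0,
    991.0
   ],
   [
    989.0,
    991.0
   ]
  ]
 },
 "impact_frame_truth": 42,
 "descent_onset": 19,
 "descent_end": 42
}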