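{
 "interval_end": 10.0,
 "kernel_sigma": 40.0,
 "eta": 0.1,
 "inputs": [
  [
   1.0,
   4.0,
   7.0
  ],
  [
   2.0,
   5.0
  ],
  [
   0.0
  ]
 ],
 "hidden": [
  [
   0.0,
   3.0
  ],
  [
   2.0,
   5.0,
   8.0
  ],
  [],
  [
   6.0
  ]
 ],
 "actual": [
  [
   1.0,
   6.0
  ],
  [
   4.0
  ]
 ],
 "desired": [
  [
   0.0,
   5.0
  ],
  [
   3.0,
   9.0
  ]
 ],
 "w1": [
  [
   0.5,
   -0.3,
   0.8
  ],
  [
   -0.2,
   0.7,
   0.1
  ],
  [
   0.9,
   0.4,
   -0.6
  ],
  [
   0.3,
   -0.5,
   0.2
  ]
 ],
 "w2": [
  [
   0.6,
   -0.4,
   0.2,
   0.7
  ],
  [
   -0.1,
   0.5,
   -0.8,
   0.3
  ]
 ],
 "b1": [
  [
   -0.7,
   0.2,
   0.4
  ],
  [
   0.5,
   -0.9,
   0.3
  ],
  [
   0.1,
   0.6,
   -0.2
  ],
  [
   -0.4,
   0.8,
   0.5
  ]
 ],
 "b2": [
  [
   0.3,
   0.9,
   -0.5,
   0.1
  ],
  [
   -0.6,
   0.2,
   0.7,
   -0.3
  ]
 ],
 "ba1": [
  [
   0.4,
   -0.2,
   0.6,
   -0.9
  ],
  [
   0.8,
   0.1,
   -0.3,
   0.5
  ]
 ],
 "golden": {
  "stip_actual_hidden": [
   [
    3.9844428257316977,
    5.97295497717412,
    0,
    1.9922179382602434
   ],
   [
    1.9947000280157214,
    2.9934508089403025,
    0,
    0.9987507809245809
   ]
  ],
  "stip_desired_hidden": [
   [
    3.988160170557669,
    5.965550295237269,
    0,
    1.988500593434272
   ],
   [
    3.961009671282496,
    5.97016043624168,
    0,
    1.9943829027456899
   ]
  ],
  "stip_actual_inputs": [
   [
    5.976660763991942,
    3.989400056031443,
    1.988500593434272
   ],
   [
    2.9943829027456896,
    1.99843832974762,
    0.9950124791926823
   ]
  ],
  "stip_desired_inputs": [
   [
    5.97295497717412,
    3.9881601705576695,
    1.9922179382602434
   ],
   [
    5.9646182014318825,
    3.978254949158398,
    1.9721966266712627
   ]
  ],
  "delta_w2": [
   [
    0.0003717344825971303,
    -0.0007404681936851176,
    -0.0,
    -0.0003717344825971303
   ],
   [
    0.19663096432667748,
    0.29767096273013777,
    -0.0,
    0.0995632121821109
   ]
  ],
  "delta_w1_bp": [
   [
    -0.029924700195931228,
    -0.019872559322534185,
    -0.009548800785227527
   ],
   [
    0.14865999640702252,
    0.09904042638948983,
    0.04871051358089017
   ],
   [
    -0.2376929396312519,
    -0.15841012726233772,
    -0.07810038490176702
   ],
   [
    0.08884765388333828,
    0.059307706599159196,
    0.029575738562175404
   ]
  ],
  "delta_w1_fa": [
   [
    -0.17832529152570623,
    -0.11882619372885986,
    -0.058519528503935686
   ],
   [
    0.059071185160119916,
    0.039484742695575954,
    0.019878243983909027
   ],
   [
    0.20810176024892457,
    0.1386491576324431,
    0.06821702308220205
   ],
   [
    -0.089144116828764,
    -0.05940689743706107,
    -0.029278350976097697
   ]
  ],
  "delta_w1_ba": [
   [
    0.2374705924221826,
    0.15833573413391133,
    0.0783234255913253
   ],
   [
    0.029776468723218364,
    0.01982296390358325,
    0.00969749457826638
   ],
   [
    -0.08932940616965508,
    -0.05946889171074974,
    -0.02909248373479913
   ],
   [
    0.14884528574791359,
    0.0991024206631785,
    0.04852464633959161
   ]
  ],
  "rkhs_error": [
   [
    0.4981428125984435
   ]
  ]
 }
}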