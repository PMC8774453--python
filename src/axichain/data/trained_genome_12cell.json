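{
 "blocks": {
  "ug_anterior": [
   -0.13544681727468527,
   0.7201996141908914,
   -0.8259092382868897
  ],
  "ug_posterior": [
   1.317145395389829,
   -0.6146342625185159,
   -0.6854622067826311
  ],
  "us": [
   0.8431658030709045,
   -0.32717816047132037,
   -0.37395976619896387
  ],
  "us_bias": -1.0975855653507525,
  "up": [
   0.26465080183041295,
   -0.1348198142591324,
   -0.821641466525745,
   0.17483803245674312,
   -0.2524203690094861,
   0.2544643593004461,
   -1.0894622430751681,
   -0.004341277506182902,
   -0.33655144742559684
  ],
  "up_bias": -0.36449266442695016,
  "v": [
   0.2790224609783308,
   -0.8686628540820658,
   0.25566655911352676,
   0.6666742159432875,
   1.0244673243011602,
   0.03326271879690742,
   0.024603208903357827,
   -1.210383951652939,
   -1.7814025347965818
  ],
  "l": [
   [
    0.0,
    -0.10580173406962944,
    -0.0,
    -0.1597648547398724,
    0.0,
    0.0,
    0.0,
    -0.0,
    0.0
   ],
   [
    -0.20454808693617307,
    -0.0,
    -0.4149353542310071,
    0.0,
    0.2422193160694855,
    -0.0,
    0.0,
    0.0,
    0.0
   ],
   [
    0.0,
    -0.7802409487930371,
    0.0,
    0.0,
    0.0,
    -1.637777625004944,
    0.0,
    -0.0,
    -0.0
   ],
   [
    0.9061682601621837,
    0.0,
    0.0,
    -0.0,
    -0.9163012380190835,
    -0.0,
    0.651970431177336,
    0.0,
    0.0
   ],
   [
    -0.0,
    -0.676056714440173,
    0.0,
    0.3578534190161979,
    0.0,
    -0.4006510762525956,
    -0.0,
    1.3291797222575048,
    -0.0
   ],
   [
    0.0,
    -0.0,
    -0.6955329793114833,
    0.0,
    0.7381389681500052,
    0.0,
    0.0,
    -0.0,
    1.5882861813381004
   ],
   [
    -0.0,
    0.0,
    -0.0,
    1.3314032921574728,
    -0.0,
    -0.0,
    -0.0,
    0.08901089261140621,
    -0.0
   ],
   [
    -0.0,
    -0.0,
    -0.0,
    -0.0,
    -0.7492788621498784,
    0.0,
    -0.16859127705133425,
    0.0,
    0.8083400702803779
   ],
   [
    -0.0,
    0.0,
    0.0,
    0.0,
    -0.0,
    0.357974838062725,
    -0.0,
    1.5242397550383504,
    -0.0
   ]
  ],
  "l_bias": [
   -0.3720260854326806,
   -0.6910675812972384,
   -0.3858877146430227,
   0.21494667787249902,
   0.46841555196103196,
   -0.5213383925603009,
   -0.3801476186402284,
   -0.009001505297562601,
   0.4347651899155324
  ],
  "m_in": [
   -0.007470984306094124,
   0.6671549666503438,
   0.23639271502280665,
   0.4334705686100863,
   0.5121988135585634,
   -1.4812462487496914
  ],
  "m_lat": [
   [
    -0.0,
    -0.6610519150964204,
    -0.0,
    -0.8854569887007943,
    -0.0,
    -0.0
   ],
   [
    0.07187855367954317,
    0.0,
    0.7347127245883062,
    0.0,
    0.527261080939177,
    0.0
   ],
   [
    0.0,
    -0.04931714489203191,
    0.0,
    -0.0,
    -0.0,
    -0.6674012999399316
   ],
   [
    -0.9679306559022478,
    0.0,
    0.0,
    -0.0,
    0.4784141349569631,
    0.0
   ],
   [
    -0.0,
    1.2790873551088966,
    -0.0,
    -0.5100309441297861,
    0.0,
    -0.9009147298489696
   ],
   [
    0.0,
    -0.0,
    -0.3090943208355838,
    -0.0,
    0.5904843610412783,
    -0.0
   ]
  ],
  "m_bias": [
   1.1024397001867268,
   0.11932756906591317,
   -0.12180579994641844,
   -0.12443178286901939,
   -0.15910091501513463,
   -0.14365381399976213
  ],
  "m_out_anterior": [
   1.0440707388255739,
   -0.414339542317883
  ],
  "m_out_self": [
   2.1362621901761556,
   2.299602769724504
  ],
  "m_out_posterior": [
   -0.016432276773750528,
   0.7664712233939466
  ],
  "jmax": 1.6887005237102126
 },
 "provenance": {
  "seed": 1,
  "protocol": "lr5e-3 h4000 then lr2e-3 h8000 fine-tune",
  "stage2_iteration": 200,
  "scores": {
   "dev_a": 96.22,
   "dev_b": 99.3,
   "rescale": 67.22,
   "regen": 89.68,
   "ic": 69.47
  },
  "trained_by": "axichain BPTT"
 }
}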