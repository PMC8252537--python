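{
 "description": "SYNTHETIC reference relaxation-time table for the system phantom parameter arrays. Values follow a sqrt(2) geometric progression anchored to the published Ni-12 archival values (T1=44.53 ms, T2=31.86 ms at 3.0 T, 20.0 C); they mirror the structure of the NIST calibration tables but are not the calibrated values.",
 "field_T": 3.0,
 "temperature_C": 20.0,
 "uncertainty_pct": 1.5,
 "NiCl2": {
  "T1_ms": [
   2015.2,
   1424.96,
   1007.6,
   712.48,
   503.8,
   356.24,
   251.9,
   178.12,
   125.95,
   89.06,
   62.97,
   44.53,
   31.49,
   22.27
  ],
  "T2_ms": [
   1441.82,
   1019.52,
   720.91,
   509.76,
   360.45,
   254.88,
   180.23,
   127.44,
   90.11,
   63.72,
   45.06,
   31.86,
   22.53,
   15.93
  ],
  "concentration_mM": [
   0.2597,
   0.5809,
   1.0351,
   1.6774,
   2.5858,
   3.8705,
   5.6872,
   8.2566,
   11.8901,
   17.0287,
   24.2978,
   34.5731,
   49.1033,
   69.646
  ]
 },
 "MnCl2": {
  "T1_ms": [
   1260.0,
   890.95,
   630.0,
   445.48,
   315.0,
   222.73,
   157.5,
   111.37,
   78.75,
   55.69,
   39.38,
   27.85,
   19.69,
   13.91
  ],
  "T2_ms": [
   700.0,
   494.97,
   350.0,
   247.49,
   175.0,
   123.74,
   87.5,
   61.87,
   43.75,
   30.94,
   21.88,
   15.47,
   10.94,
   7.73
  ],
  "concentration_mM": [
   0.0124,
   0.0207,
   0.0325,
   0.0492,
   0.0727,
   0.1061,
   0.1532,
   0.2199,
   0.3142,
   0.4475,
   0.636,
   0.9027,
   1.2797,
   1.8143
  ]
 },
 "PD": {
  "PD_percent": [
   5,
   10,
   15,
   20,
   25,
   30,
   35,
   40,
   50,
   60,
   70,
   80,
   90,
   100
  ],
  "T1_ms": [
   400.0,
   400.0,
   400.0,
   400.0,
   400.0,
   400.0,
   400.0,
   400.0,
   400.0,
   400.0,
   400.0,
   400.0,
   400.0,
   400.0
  ],
  "T2_ms": [
   300.0,
   300.0,
   300.0,
   300.0,
   300.0,
   300.0,
   300.0,
   300.0,
   300.0,
   300.0,
   300.0,
   300.0,
   300.0,
   300.0
  ]
 },
 "fiducial": {
  "T1_ms": 407.0,
  "T2_ms": 347.0
 },
 "water": {
  "T1_ms": 3000.0,
  "T2_ms": 1800.0,
  "R1_s": 0.33,
  "R2_s": 0.55
 }
}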