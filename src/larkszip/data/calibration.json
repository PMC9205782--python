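{
 "tau_L": 76.71469572116142,
 "tau_Z": 300.49006232702845,
 "delta_max": -40.73877192896871,
 "weights": {
  "w_rep": 20.0,
  "w_att": 0.3,
  "w_solv": 2.0,
  "w_hb": 2.0
 },
 "controls": {
  "larks_positives": {
   "STGGYS": -39.1904,
   "SYSGYS": -130.2126,
   "GYNGFG": -26.0429,
   "GGYGGA": 63.6267,
   "GYGGAS": 18.0079,
   "SGMGGI": -10.6914,
   "GMGGIT": 10.7014
  },
  "larks_negatives": {
   "WWWWWW": 4154.569,
   "KWEWRF": 591.4612,
   "REKDKE": 115.9788,
   "WRWDWK": 960.8823,
   "KRKRKR": 158.3326,
   "WFYWFY": 792.8888,
   "YKEWRY": 362.9544,
   "EDEDED": 188.4493
  },
  "zipper_selected": {
   "KRT8_G62C": {
    "window": "GMGCIT",
    "e_zip_mut": -92.8897,
    "delta": -91.8774
   },
   "KRT8_G55A": {
    "window": "GGYAGA",
    "e_zip_mut": 54.7586,
    "delta": -50.9235
   },
   "KRT8_Y54H": {
    "window": "GHGGAS",
    "e_zip_mut": 273.1728,
    "delta": -1871.9614
   }
  }
 }
}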