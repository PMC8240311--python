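{
 "unweighted": {
  "precision": {
   "0.1": 0.11666666666666667,
   "0.2": 0.2833333333333333,
   "0.3": 0.5,
   "0.4": 0.7055555555555556,
   "0.5": 0.8722222222222222,
   "0.6": 0.9555555555555556,
   "0.7": 0.9722222222222222,
   "0.8": 0.9944444444444445,
   "0.9": 1.0,
   "1.0": 1.0,
   "1.1": 1.0,
   "1.2": 1.0,
   "1.3": 1.0,
   "1.4": 1.0,
   "1.5": 1.0,
   "1.6": 1.0,
   "1.7": 1.0,
   "1.8": 1.0,
   "1.9": 1.0,
   "2.0": 1.0
  },
  "coverage": {
   "0.1": 0.75,
   "0.2": 1.0,
   "0.3": 1.0,
   "0.4": 1.0,
   "0.5": 1.0,
   "0.6": 1.0,
   "0.7": 1.0,
   "0.8": 1.0,
   "0.9": 1.0,
   "1.0": 1.0,
   "1.1": 1.0,
   "1.2": 1.0,
   "1.3": 1.0,
   "1.4": 1.0,
   "1.5": 1.0,
   "1.6": 1.0,
   "1.7": 1.0,
   "1.8": 1.0,
   "1.9": 1.0,
   "2.0": 1.0
  },
  "acc_ss": 1.0,
  "err_phi": 3.9514783892390803,
  "err_psi": 4.005459771818511,
  "err_theta": 1.5196580993627924,
  "err_tau": 5.461499797633954,
  "err_ca_dist": 0.14178443436055058,
  "err_cb_dist": 0.20372659410126936,
  "weighted": false,
  "temperature": null
 },
 "weighted": {
  "precision": {
   "0.1": 0.11666666666666667,
   "0.2": 0.2833333333333333,
   "0.3": 0.5,
   "0.4": 0.7055555555555556,
   "0.5": 0.8722222222222222,
   "0.6": 0.9555555555555556,
   "0.7": 0.9722222222222222,
   "0.8": 0.9944444444444445,
   "0.9": 1.0,
   "1.0": 1.0,
   "1.1": 1.0,
   "1.2": 1.0,
   "1.3": 1.0,
   "1.4": 1.0,
   "1.5": 1.0,
   "1.6": 1.0,
   "1.7": 1.0,
   "1.8": 1.0,
   "1.9": 1.0,
   "2.0": 1.0
  },
  "coverage": {
   "0.1": 0.75,
   "0.2": 1.0,
   "0.3": 1.0,
   "0.4": 1.0,
   "0.5": 1.0,
   "0.6": 1.0,
   "0.7": 1.0,
   "0.8": 1.0,
   "0.9": 1.0,
   "1.0": 1.0,
   "1.1": 1.0,
   "1.2": 1.0,
   "1.3": 1.0,
   "1.4": 1.0,
   "1.5": 1.0,
   "1.6": 1.0,
   "1.7": 1.0,
   "1.8": 1.0,
   "1.9": 1.0,
   "2.0": 1.0
  },
  "acc_ss": 1.0,
  "err_phi": 3.797468138777558,
  "err_psi": 3.936801441505332,
  "err_theta": 1.457226972125,
  "err_tau": 4.988701695816228,
  "err_ca_dist": 0.11725299789481225,
  "err_cb_dist": 0.17663905157051404,
  "weighted": true,
  "temperature": 0.1
 },
 "n_fragments": 180,
 "mean_true_rmsd": 0.30823669311042434
}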