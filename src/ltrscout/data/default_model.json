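{
 "format": "ltrscout-merge-model",
 "version": 1,
 "weights": [
  -1.2143334143708322,
  -1.131204303891755,
  -3.7263254641307224,
  0.014384545740114649,
  0.2887424530199631,
  -0.0908416078748131,
  0.19037983191256172,
  0.27339154713105673,
  0.053064647990102985,
  -0.669308887167843
 ],
 "bias": -0.5899773739572509,
 "feature_means": [
  238.86764705882354,
  238.41176470588235,
  2173.6461937716263,
  7980.269896193771,
  1.8875432525951557,
  1.685404751510069,
  3.6894026709884558,
  3.6992456083777507,
  0.7627159142604867
 ],
 "feature_sds": [
  385.2343383688395,
  386.14203063130714,
  6222.469766643593,
  8247.34927080393,
  1.7782277594257223,
  1.5420004072893123,
  2.247660404442343,
  2.259744769110535,
  1.620162615140236
 ],
 "metadata": {
  "params": {
   "loss": "hinge",
   "alpha": 0.0012689610031679235,
   "penalty": "l2",
   "class_weight": "balanced"
  },
  "metrics": {
   "validation_f1": 0.7860262008733624,
   "test_recall": 0.9824561403508771,
   "test_precision": 0.7887323943661971,
   "test_f1": 0.875
  },
  "n_examples": 1156
 }
}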