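{
 "devices": [
  {
   "device_id": "SM-G930F",
   "model_name": "Galaxy S7",
   "aliases": [],
   "slope": 20.5379,
   "intercept": 1.3481,
   "r_squared": 0.9995,
   "source": "lab calibration, 1000 Hz pure tone, 50-80 dB(C)"
  },
  {
   "device_id": "SM-A310F",
   "model_name": "Galaxy A3",
   "aliases": [],
   "slope": 20.7228,
   "intercept": 1.2215,
   "r_squared": 0.9997,
   "source": "lab calibration, 1000 Hz pure tone, 50-80 dB(C)"
  },
  {
   "device_id": "XT1032",
   "model_name": "Moto G",
   "aliases": ["Moto G", "XT1028"],
   "slope": 21.216,
   "intercept": 14.258,
   "r_squared": 0.9994,
   "source": "lab calibration, 1000 Hz pure tone, 50-80 dB(C)"
  },
  {
   "device_id": "Moto G (5S) Plus",
   "model_name": "Moto G 5S Plus",
   "aliases": ["Moto G (5) Plus"],
   "slope": 21.341,
   "intercept": 10.166,
   "r_squared": 0.9998,
   "source": "lab calibration, 1000 Hz pure tone, 50-80 dB(C)"
  },
  {
   "device_id": "Pixel 2",
   "model_name": "Pixel 2",
   "aliases": [],
   "slope": 23.8364,
   "intercept": -2.7633,
   "r_squared": 0.9925,
   "source": "lab calibration, 1000 Hz pure tone, 50-80 dB(C)"
  },
  {
   "device_id": "LGL34C",
   "model_name": "LG Optimus Fuel",
   "aliases": [],
   "source": "crowdsensed user-agent mapping"
  },
  {
   "device_id": "SM-G800F",
   "model_name": "Galaxy S5 mini",
   "aliases": [],
   "source": "crowdsensed user-agent mapping"
  },
  {
   "device_id": "GT-I8190",
   "model_name": "Galaxy S3 mini",
   "aliases": [],
   "source": "crowdsensed user-agent mapping"
  },
  {
   "device_id": "SM-G900F",
   "model_name": "Galaxy S5",
   "aliases": [],
   "source": "crowdsensed user-agent mapping"
  },
  {
   "device_id": "GT-I9300",
   "model_name": "Galaxy S3",
   "aliases": [],
   "source": "crowdsensed user-agent mapping"
  },
  {
   "device_id": "SM-A300FU",
   "model_name": "Galaxy A3 (SM-A300FU)",
   "aliases": [],
   "source": "crowdsensed user-agent mapping; 2015 hardware, distinct from the calibrated SM-A310F"
  },
  {
   "device_id": "HTC One",
   "model_name": "HTC One",
   "aliases": [],
   "source": "crowdsensed user-agent mapping"
  },
  {
   "device_id": "GT-I9195",
   "model_name": "Galaxy S4 mini",
   "aliases": [],
   "source": "crowdsensed user-agent mapping"
  },
  {
   "device_id": "SM-A520F",
   "model_name": "Galaxy A5",
   "aliases": [],
   "source": "crowdsensed user-agent mapping"
  },
  {
   "device_id": "PRA-LX1",
   "model_name": "Huawei P8 Lite",
   "aliases": [],
   "source": "crowdsensed user-agent mapping"
  },
  {
   "device_id": "WAS-LX1A",
   "model_name": "Huawei P10 Lite",
   "aliases": [],
   "source": "crowdsensed user-agent mapping"
  },
  {
   "device_id": "SM-C115",
   "model_name": "Galaxy K Zoom",
   "aliases": [],
   "source": "crowdsensed user-agent mapping"
  },
  {
   "device_id": "SM-T810",
   "model_name": "Galaxy Tab S2",
   "aliases": [],
   "source": "crowdsensed user-agent mapping"
  },
  {
   "device_id": "SM-G960F",
   "model_name": "Galaxy S9",
   "aliases": [],
   "source": "crowdsensed user-agent mapping"
  },
  {
   "device_id": "LG-P970",
   "model_name": "LG P970",
   "aliases": [],
   "source": "crowdsensed user-agent mapping"
  },
  {
   "device_id": "LT26i",
   "model_name": "Sony Xperia S",
   "aliases": [],
   "source": "crowdsensed user-agent mapping"
  },
  {
   "device_id": "SGH-M919",
   "model_name": "SGH-M919",
   "aliases": [],
   "source": "crowdsensed user-agent mapping"
  }
 ]
}
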