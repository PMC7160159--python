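{
 "sha256": "c636a6e26900ce6132e83803ed8c608a3c6dd5ac2e03b0eb769212b3f1f4c34d",
 "models": [
  {
   "species": "croaker",
   "predictor": "OL",
   "response": "FTL",
   "form": "linear",
   "params": {
    "b0": -25.51784,
    "b1": 24.410412
   },
   "r2": 0.96,
   "aic": null,
   "n": null,
   "x_range": null
  },
  {
   "species": "croaker",
   "predictor": "SL",
   "response": "FTL",
   "form": "linear",
   "params": {
    "b0": -20.75988,
    "b1": 29.028549
   },
   "r2": 0.95,
   "aic": null,
   "n": null,
   "x_range": null
  },
  {
   "species": "croaker",
   "predictor": "CL",
   "response": "FTL",
   "form": "linear",
   "params": {
    "b0": 1.2494378,
    "b1": 61.30351
   },
   "r2": 0.88,
   "aic": null,
   "n": null,
   "x_range": null
  },
  {
   "species": "croaker",
   "predictor": "OL",
   "response": "FW",
   "form": "logistic",
   "params": {
    "A": 286.38443,
    "k": 0.6072569,
    "x0": 10.473646
   },
   "r2": 0.97,
   "aic": null,
   "n": null,
   "x_range": null
  },
  {
   "species": "croaker",
   "predictor": "SL",
   "response": "FW",
   "form": "logistic",
   "params": {
    "A": 262.50792,
    "k": 0.7774777,
    "x0": 8.3679234
   },
   "r2": 0.94,
   "aic": null,
   "n": null,
   "x_range": null
  },
  {
   "species": "croaker",
   "predictor": "CL",
   "response": "FW",
   "form": "logistic",
   "params": {
    "A": 261.82446,
    "k": 1.6664716,
    "x0": 3.5895675
   },
   "r2": 0.89,
   "aic": null,
   "n": null,
   "x_range": null
  },
  {
   "species": "spot",
   "predictor": "OL",
   "response": "FTL",
   "form": "logistic",
   "params": {
    "A": 380.79763,
    "k": 0.3929095,
    "x0": 6.705528
   },
   "r2": 0.98,
   "aic": null,
   "n": null,
   "x_range": null
  },
  {
   "species": "spot",
   "predictor": "SL",
   "response": "FTL",
   "form": "logistic",
   "params": {
    "A": 353.24343,
    "k": 0.4677786,
    "x0": 5.3485423
   },
   "r2": 0.98,
   "aic": null,
   "n": null,
   "x_range": null
  },
  {
   "species": "spot",
   "predictor": "CL",
   "response": "FTL",
   "form": "logistic",
   "params": {
    "A": 350.7459,
    "k": 1.1056006,
    "x0": 2.5360011
   },
   "r2": 0.95,
   "aic": null,
   "n": null,
   "x_range": null
  },
  {
   "species": "spot",
   "predictor": "OL",
   "response": "FW",
   "form": "gompertz",
   "params": {
    "A": 85841.563,
    "k": 0.085671,
    "x0": 29.16622
   },
   "r2": 0.97,
   "aic": null,
   "n": null,
   "x_range": null
  },
  {
   "species": "spot",
   "predictor": "SL",
   "response": "FW",
   "form": "gompertz",
   "params": {
    "A": 29777.77,
    "k": 0.1101145,
    "x0": 21.640302
   },
   "r2": 0.96,
   "aic": null,
   "n": null,
   "x_range": null
  },
  {
   "species": "spot",
   "predictor": "CL",
   "response": "FW",
   "form": "gompertz",
   "params": {
    "A": 483412.11,
    "k": 0.1733285,
    "x0": 15.095524
   },
   "r2": 0.92,
   "aic": null,
   "n": null,
   "x_range": null
  },
  {
   "species": "spotted_seatrout",
   "predictor": "OL",
   "response": "FTL",
   "form": "logistic",
   "params": {
    "A": 792.34349,
    "k": 0.1466631,
    "x0": 16.694034
   },
   "r2": 0.97,
   "aic": null,
   "n": null,
   "x_range": null
  },
  {
   "species": "spotted_seatrout",
   "predictor": "SL",
   "response": "FTL",
   "form": "logistic",
   "params": {
    "A": 793.22148,
    "k": 0.1702467,
    "x0": 14.004909
   },
   "r2": 0.97,
   "aic": null,
   "n": null,
   "x_range": null
  },
  {
   "species": "spotted_seatrout",
   "predictor": "CL",
   "response": "FTL",
   "form": "logistic",
   "params": {
    "A": 659.58373,
    "k": 0.5267355,
    "x0": 5.3660654
   },
   "r2": 0.94,
   "aic": null,
   "n": null,
   "x_range": null
  },
  {
   "species": "spotted_seatrout",
   "predictor": "OL",
   "response": "FW",
   "form": "logistic",
   "params": {
    "A": 2042.2502,
    "k": 0.3516577,
    "x0": 19.132198
   },
   "r2": 0.95,
   "aic": null,
   "n": null,
   "x_range": null
  },
  {
   "species": "spotted_seatrout",
   "predictor": "SL",
   "response": "FW",
   "form": "logistic",
   "params": {
    "A": 2029.3521,
    "k": 0.4105468,
    "x0": 16.059515
   },
   "r2": 0.95,
   "aic": null,
   "n": null,
   "x_range": null
  },
  {
   "species": "spotted_seatrout",
   "predictor": "CL",
   "response": "FW",
   "form": "logistic",
   "params": {
    "A": 1654.0488,
    "k": 1.1770936,
    "x0": 6.5814683
   },
   "r2": 0.9,
   "aic": null,
   "n": null,
   "x_range": null
  },
  {
   "species": "weakfish",
   "predictor": "OL",
   "response": "FTL",
   "form": "gompertz",
   "params": {
    "A": 2477.0097,
    "k": 0.0394058,
    "x0": 33.676056
   },
   "r2": 0.98,
   "aic": null,
   "n": null,
   "x_range": null
  },
  {
   "species": "weakfish",
   "predictor": "SL",
   "response": "FTL",
   "form": "gompertz",
   "params": {
    "A": 3409.5556,
    "k": 0.0379836,
    "x0": 36.322885
   },
   "r2": 0.97,
   "aic": null,
   "n": null,
   "x_range": null
  },
  {
   "species": "weakfish",
   "predictor": "CL",
   "response": "FTL",
   "form": "gompertz",
   "params": {
    "A": 2957.7632,
    "k": 0.0793614,
    "x0": 17.141034
   },
   "r2": 0.97,
   "aic": null,
   "n": null,
   "x_range": null
  },
  {
   "species": "weakfish",
   "predictor": "OL",
   "response": "FW",
   "form": "logistic",
   "params": {
    "A": 5861.9572,
    "k": 0.2409874,
    "x0": 27.556653
   },
   "r2": 0.93,
   "aic": null,
   "n": null,
   "x_range": null
  },
  {
   "species": "weakfish",
   "predictor": "SL",
   "response": "FW",
   "form": "logistic",
   "params": {
    "A": 5941.1188,
    "k": 0.2737339,
    "x0": 24.319011
   },
   "r2": 0.93,
   "aic": null,
   "n": null,
   "x_range": null
  },
  {
   "species": "weakfish",
   "predictor": "CL",
   "response": "FW",
   "form": "logistic",
   "params": {
    "A": 5377.982,
    "k": 0.5400035,
    "x0": 12.275319
   },
   "r2": 0.92,
   "aic": null,
   "n": null,
   "x_range": null
  }
 ]
}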