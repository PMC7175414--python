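{
 "description": "Validated run configuration (JSON-serializable).\n\nThe published JSON schema ships in-package as\n``oximetric/data/runconfig.schema.json`` and is generated from this model.",
 "properties": {
  "grid_nm": {
   "items": {
    "type": "number"
   },
   "title": "Grid Nm",
   "type": "array"
  },
  "left_set_nm": {
   "items": {
    "type": "number"
   },
   "title": "Left Set Nm",
   "type": "array"
  },
  "right_set_nm": {
   "items": {
    "type": "number"
   },
   "title": "Right Set Nm",
   "type": "array"
  },
  "fit_bounds": {
   "default": "unconstrained",
   "title": "Fit Bounds",
   "type": "string"
  },
  "noise_sigma": {
   "default": 0.1,
   "title": "Noise Sigma",
   "type": "number"
  },
  "fluence_geometry": {
   "default": "semi-infinite-point-source",
   "title": "Fluence Geometry",
   "type": "string"
  },
  "d_min_mm": {
   "default": 0.5,
   "title": "D Min Mm",
   "type": "number"
  },
  "seed": {
   "default": 0,
   "title": "Seed",
   "type": "integer"
  },
  "out_dir": {
   "default": ".",
   "title": "Out Dir",
   "type": "string"
  },
  "make_plots": {
   "default": true,
   "title": "Make Plots",
   "type": "boolean"
  },
  "so2_step_percent": {
   "default": 1.0,
   "title": "So2 Step Percent",
   "type": "number"
  },
  "ratio_threshold": {
   "anyOf": [
    {
     "type": "number"
    },
    {
     "type": "null"
    }
   ],
   "default": null,
   "title": "Ratio Threshold"
  }
 },
 "title": "RunConfig",
 "type": "object"
}
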