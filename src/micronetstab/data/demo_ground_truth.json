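{
  "note": "synthetic fixture generated by micronetstab.synthetic_data (seed 11)",
  "module_assignment": {
    "ASV01": 2,
    "ASV02": 0,
    "ASV03": 3,
    "ASV04": 3,
    "ASV05": 1,
    "ASV06": 0,
    "ASV07": 1,
    "ASV08": 0,
    "ASV09": 2,
    "ASV10": 3,
    "ASV11": 2,
    "ASV12": 1,
    "ASV13": 1,
    "ASV14": 3,
    "ASV15": 1,
    "ASV16": 2,
    "ASV17": 3,
    "ASV18": 0,
    "ASV19": 1,
    "ASV20": 1,
    "ASV21": 1,
    "ASV22": 1,
    "ASV23": 1,
    "ASV24": 2,
    "ASV25": 0,
    "ASV26": 2,
    "ASV27": 0,
    "ASV28": 2,
    "ASV29": 3,
    "ASV30": 0,
    "ASV31": 0,
    "ASV32": 3,
    "ASV33": 0,
    "ASV34": 3,
    "ASV35": 3,
    "ASV36": 0,
    "ASV37": 2,
    "ASV38": 1,
    "ASV39": 3,
    "ASV40": 1,
    "ASV41": 3,
    "ASV42": 1,
    "ASV43": 3,
    "ASV44": 2,
    "ASV45": 2,
    "ASV46": 0,
    "ASV47": 0,
    "ASV48": 1,
    "ASV49": 2,
    "ASV50": 2,
    "ASV51": 0,
    "ASV52": 3,
    "ASV53": 1,
    "ASV54": 0,
    "ASV55": 3,
    "ASV56": 2,
    "ASV57": 2,
    "ASV58": 3,
    "ASV59": 0,
    "ASV60": 2
  },
  "true_paths": {
    "treatment": {
      "treatment": 0.0,
      "soil": 0.6,
      "community": 0.5,
      "plant": 0.0
    },
    "soil": {
      "treatment": 0.0,
      "soil": 0.0,
      "community": 0.4,
      "plant": 0.3
    },
    "community": {
      "treatment": 0.0,
      "soil": 0.0,
      "community": 0.0,
      "plant": 0.5
    },
    "plant": {
      "treatment": 0.0,
      "soil": 0.0,
      "community": 0.0,
      "plant": 0.0
    }
  }
}
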