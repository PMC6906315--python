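{
  "montage": {
    "1": ["Fz", "F3", "F4", "FC1", "FC2", "FC5", "FC6", "Cz", "C3", "C4",
           "T7", "T8", "CP1", "CP2", "CP5", "CP6", "Pz", "P3", "P4", "P7",
           "P8", "POz", "PO3", "PO4", "PO7", "PO8", "O1", "O2"],
    "2": ["Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8", "FC1", "FC2", "FC5",
           "FC6", "Cz", "C3", "C4", "T7", "T8", "CP1", "CP2", "CP5", "CP6",
           "Pz", "P3", "P4", "P7", "P8", "Oz", "O1", "O2"]
  },
  "frontocentral": {
    "1": ["Fz", "F3", "F4", "FC1", "FC2", "FC5", "FC6", "Cz", "C3", "C4",
           "T7", "T8", "CP5", "CP6"],
    "2": ["Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8", "FC1", "FC2", "FC5",
           "FC6", "Cz", "C3", "C4"]
  },
  "occipitoparietal": {
    "1": ["CP5", "CP6", "Pz", "P3", "P4", "P7", "P8", "POz", "PO3", "PO4",
           "PO7", "PO8", "O1", "O2"],
    "2": ["T7", "T8", "CP1", "CP2", "CP5", "CP6", "Pz", "P3", "P4", "P7",
           "P8", "Oz", "O1", "O2"]
  }
}
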