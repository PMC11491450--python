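{
 "Fp1": "frontal",
 "AF7": "frontal",
 "AF3": "frontal",
 "F1": "frontal",
 "F3": "frontal",
 "F5": "frontal",
 "F7": "frontal",
 "FT7": "temporal",
 "FC5": "central",
 "FC3": "central",
 "FC1": "central",
 "C1": "central",
 "C3": "central",
 "C5": "central",
 "T7": "temporal",
 "TP7": "temporal",
 "CP5": "parietal",
 "CP3": "parietal",
 "CP1": "parietal",
 "P1": "parietal",
 "P3": "parietal",
 "P5": "parietal",
 "P7": "parietal",
 "P9": "parietal",
 "PO7": "occipital",
 "PO3": "occipital",
 "O1": "occipital",
 "Iz": "occipital",
 "Oz": "occipital",
 "POz": "occipital",
 "Pz": "parietal",
 "CPz": "parietal",
 "Fpz": "frontal",
 "Fp2": "frontal",
 "AF8": "frontal",
 "AF4": "frontal",
 "AFz": "frontal",
 "Fz": "frontal",
 "F2": "frontal",
 "F4": "frontal",
 "F6": "frontal",
 "F8": "frontal",
 "FT8": "temporal",
 "FC6": "central",
 "FC4": "central",
 "FC2": "central",
 "FCz": "central",
 "Cz": "central",
 "C2": "central",
 "C4": "central",
 "C6": "central",
 "T8": "temporal",
 "TP8": "temporal",
 "CP6": "parietal",
 "CP4": "parietal",
 "CP2": "parietal",
 "P2": "parietal",
 "P4": "parietal",
 "P6": "parietal",
 "P8": "parietal",
 "P10": "parietal",
 "PO8": "occipital",
 "PO4": "occipital",
 "O2": "occipital"
}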