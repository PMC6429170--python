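"""Fixed 32-channel 10-10 montage plus two periocular (EOG) channels.

The parietal/occipital group carries the familiarity response; the frontal
group picks up attenuated blink activity.
"""

EEG_CHANNELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6",
    "P7", "P3", "Pz", "P4", "P8",
    "PO3", "PO4", "O1", "Oz", "O2",
    "TP9", "TP10",
]

EOG_CHANNELS = ["EOG1", "EOG2"]

ALL_CHANNELS = EEG_CHANNELS + EOG_CHANNELS

# Relative weight of the familiarity component on the informative electrodes.
INFORMATIVE_WEIGHTS = {"P7": 1.0, "P8": 1.0, "Pz": 0.7, "O1": 0.4, "O2": 0.4}

# Channels that receive an attenuated copy of blink deflections.
FRONTAL_CHANNELS = ["Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8"]
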