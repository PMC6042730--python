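{
  "schema_version": "1",
  "persons": {
    "paternal_grandfather": {"had_ad": true, "onset_age": 82, "age": 87},
    "paternal_grandmother": {"had_ad": false, "age": 75},
    "maternal_grandfather": {"had_ad": false, "age": 79},
    "maternal_grandmother": {"had_ad": true, "onset_age": 67, "age": 77},
    "father": {"had_ad": true, "onset_age": 64, "age": 75},
    "mother": {"had_ad": true, "onset_age": 85, "age": 97},
    "subject": {"had_ad": false, "age": 45}
  },
  "factors": {
    "race": "White",
    "t2dm": "T2DM",
    "tbi": "No/Mild TBI",
    "education": "Secondary or greater",
    "exercise": "Regular",
    "diet": "Other"
  }
}
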