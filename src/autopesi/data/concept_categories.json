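{
  "cancer": {
    "roots": ["363346000"],
    "exclusions": []
  },
  "heart_failure": {
    "roots": ["84114007"],
    "exclusions": []
  },
  "chronic_lung_disease": {
    "roots": ["413839001"],
    "exclusions": []
  }
}
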