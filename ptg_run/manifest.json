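{
  "artifacts": [
    "config_echo.json",
    "manifest.json",
    "table.csv",
    "table.json",
    "timings.json",
    "trace.csv"
  ],
  "required": [
    "config_echo.json",
    "table.csv",
    "table.json",
    "trace.csv",
    "timings.json"
  ],
  "complete": true
}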