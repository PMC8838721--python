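# Default biochemical reference ranges (package defaults; supply your own
# laboratory's ranges for clinical use). Units: glucose mg/dL, lipids mg/dL,
# triglycerides mg/dL, ferritin ng/mL, transferrin mg/dL.
glucose: {low: 70, high: 100}
total_cholesterol: {low: 120, high: 200}
hdl_cholesterol: {low: 40, high: 90}
ldl_cholesterol: {low: 50, high: 130}
triglycerides: {low: 40, high: 150}
ferritin: {low: 15, high: 250}
transferrin: {low: 200, high: 360}
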