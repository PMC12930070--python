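# Model input parameters: baseline value, plausible range, PSA distribution.
# Keys mirror the published parameter-table row labels.
# Costs in 2025 USD; incidences/utilities unitless; times in model cycles.

"Risk for main adverse events in DFLOT group":
  "Diarrhea":          {value: 0.0630, min: 0.0473, max: 0.0788, dist: beta}
  "Anemia":            {value: 0.0510, min: 0.0383, max: 0.0638, dist: beta}
  "Neutropenia":       {value: 0.4090, min: 0.3068, max: 0.5113, dist: beta}
  "Thrombocytopenia":  {value: 0.0530, min: 0.0398, max: 0.0663, dist: beta}
"Risk for main adverse events in FLOT group":
  "Diarrhea":          {value: 0.0600, min: 0.0450, max: 0.0750, dist: beta}
  "Anemia":            {value: 0.0510, min: 0.0383, max: 0.0638, dist: beta}
  "Neutropenia":       {value: 0.4460, min: 0.3345, max: 0.5575, dist: beta}
  "Thrombocytopenia":  {value: 0.0600, min: 0.0450, max: 0.0750, dist: beta}
"Utility":
  "EFS":               {value: 0.797, min: 0.598, max: 0.996, dist: beta}
  "PD":                {value: 0.577, min: 0.433, max: 0.721, dist: beta}
  "Gastrectomy":       {value: 0.773, min: 0.580, max: 0.966, dist: beta}
"AEs disutility":
  "Diarrhea":          {value: 0.247, min: 0.164, max: 0.348, dist: beta}
  "Anemia":            {value: 0.200, min: 0.150, max: 0.250, dist: beta}
  "Neutropenia":       {value: 0.159, min: 0.106, max: 0.226, dist: beta}
  "Thrombocytopenia":  {value: 0.149, min: 0.101, max: 0.209, dist: beta}
"AEs cost per":
  "Diarrhea":          {value: 3928.00, min: 2946.00, max: 4910.00, dist: gamma}
  "Anemia":            {value: 528.00, min: 396.00, max: 660.00, dist: gamma}
  "Neutropenia":       {value: 18987.00, min: 14240.25, max: 23733.75, dist: gamma}
  "Thrombocytopenia":  {value: 96238.00, min: 72178.50, max: 120297.50, dist: gamma}
"Drug cost per cycle":
  "Durvalumab":        {value: 12787.50, min: 9590.63, max: 15984.38, dist: gamma}
  "Fluorouracil":      {value: 35.40, min: 26.55, max: 44.26, dist: gamma}
  "Leucovorin":        {value: 62.68, min: 47.01, max: 78.35, dist: gamma}
  "Oxaliplatin":       {value: 61.42, min: 46.06, max: 76.77, dist: gamma}
  "Docetaxel":         {value: 75.23, min: 56.42, max: 94.04, dist: gamma}
  "Ramucirumab":       {value: 20179.74, min: 15134.81, max: 25224.68, dist: gamma}
  "Paclitaxel":        {value: 50.50, min: 37.87, max: 63.12, dist: gamma}
"Administration cost per":
  "CT":                     {value: 171.10, min: 128.33, max: 213.88, dist: gamma}
  "Ppps, initial visit":    {value: 165.44, min: 124.08, max: 206.80, dist: gamma}
  "Ppps, subsequent visit": {value: 130.15, min: 97.61, max: 162.69, dist: gamma}
  "CBC":                    {value: 19.00, min: 14.25, max: 23.75, dist: gamma}
  "IV infusion 1h":         {value: 129.16, min: 96.87, max: 161.45, dist: gamma}
  "IV infusion over 1h":    {value: 156.79, min: 117.59, max: 195.99, dist: gamma}
  "Removal of stomach":     {value: 1910.80, min: 1433.10, max: 2388.49, dist: gamma}
  # published minimum (16955.57) exceeds the base value; repaired to +/-25% on load
  "Best supportive care":   {value: 16632.03, min: 16955.57, max: 28259.28, dist: gamma}
  "Hospice care":           {value: 4563.28, min: 3422.46, max: 5704.10, dist: gamma}
"Patient":
  "Body weight (kg)":  {value: 84.70, min: 63.53, max: 105.88, dist: normal}
  "BSA (m^2)":         {value: 1.99, min: 1.49, max: 2.48, dist: normal}
  "Gastrectomy utility duration(cycle)": {value: 13.0, min: 6.0, max: 20.0, dist: normal}
  "Discount rate, %":  {value: 3.00, min: 0.0, max: 5.00, dist: fixed}
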