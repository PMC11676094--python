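# Built-in 1H-NMR metabolite template library for the synthetic cohort
# generator.  Chemical shifts (ppm) follow standard reference values for
# aqueous biofluids at pH ~7.4; multiplet fine structure is collapsed to a
# few Lorentzian lines per metabolite, which is sufficient at 0.005-ppm
# binning resolution.  Heights are relative within a metabolite;
# `concentration` is an arbitrary base amplitude of order 1 (only relative
# between-group effects matter downstream).
#
# peaks: [center_ppm, relative_height, halfwidth_ppm]
metabolites:
  - name: lactate
    concentration: 1.2
    peaks:
      - [1.33, 1.00, 0.002]
      - [4.11, 0.33, 0.002]
  - name: alanine
    concentration: 0.8
    peaks:
      - [1.48, 1.00, 0.002]
  - name: alpha-glucose
    concentration: 1.0
    peaks:
      - [5.23, 0.40, 0.002]
      - [3.53, 0.60, 0.002]
      - [3.71, 0.50, 0.002]
  - name: beta-glucose
    concentration: 1.0
    peaks:
      - [4.64, 0.50, 0.002]
      - [3.89, 0.40, 0.002]
  - name: creatine
    concentration: 0.9
    peaks:
      - [3.03, 1.00, 0.002]
      - [3.93, 0.40, 0.002]
  - name: creatinine
    concentration: 0.7
    peaks:
      - [3.05, 1.00, 0.002]
      - [4.06, 0.50, 0.002]
  - name: taurine
    concentration: 0.9
    peaks:
      - [3.26, 0.80, 0.002]
      - [3.42, 0.80, 0.002]
  - name: nad+
    concentration: 0.4
    peaks:
      - [8.17, 0.30, 0.0025]
      - [8.42, 0.30, 0.0025]
      - [9.14, 0.25, 0.0025]
      - [9.33, 0.25, 0.0025]
  - name: allantoin
    concentration: 0.6
    peaks:
      - [5.39, 0.60, 0.002]
  - name: nicotinate
    concentration: 0.5
    peaks:
      - [7.52, 0.30, 0.0025]
      - [8.62, 0.40, 0.0025]
      - [8.94, 0.40, 0.0025]
  - name: nicotinamide-n-oxide
    concentration: 0.4
    peaks:
      - [7.82, 0.30, 0.0025]
      - [8.55, 0.30, 0.0025]
      - [8.78, 0.30, 0.0025]
  - name: succinate
    concentration: 0.8
    peaks:
      - [2.41, 1.00, 0.002]
  - name: acetone
    concentration: 0.6
    peaks:
      - [2.23, 1.00, 0.002]
  - name: valine
    concentration: 0.8
    peaks:
      - [0.99, 0.90, 0.002]
      - [1.04, 0.90, 0.002]
  - name: threonine
    concentration: 0.7
    peaks:
      - [1.32, 0.90, 0.002]
      - [4.25, 0.40, 0.002]
  - name: formate
    concentration: 0.3
    peaks:
      - [8.46, 0.50, 0.0025]
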