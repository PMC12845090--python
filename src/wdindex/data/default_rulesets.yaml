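rulesets:
- definition: WHO
  mandatory: glucose_dysregulation
  min_criteria: 2
  criteria:
  - name: glucose_dysregulation
    clauses:
    - variable: fbg
      op: ge
      threshold: 110.0
  - name: obesity
    clauses:
    - variable: bmi
      op: gt
      threshold: 30.0
    - variable: whr
      op: gt
      threshold:
        female: 0.85
        male: 0.9
  - name: dyslipidemia
    clauses:
    - variable: tg
      op: ge
      threshold: 150.0
    - variable: hdl
      op: lt
      threshold:
        female: 39.0
        male: 35.0
  - name: raised_bp_140_90
    clauses:
    - variable: sbp
      op: ge
      threshold: 140.0
    - variable: dbp
      op: ge
      threshold: 90.0
- definition: ATPIII
  mandatory: null
  min_criteria: 3
  criteria:
  - name: raised_wc
    clauses:
    - variable: wc
      op: gt
      threshold:
        female: 88.0
        male: 102.0
  - name: raised_tg
    clauses:
    - variable: tg
      op: ge
      threshold: 150.0
  - name: low_hdl
    clauses:
    - variable: hdl
      op: lt
      threshold:
        female: 50.0
        male: 40.0
  - name: raised_bp
    clauses:
    - variable: sbp
      op: ge
      threshold: 130.0
    - variable: dbp
      op: ge
      threshold: 85.0
  - name: raised_fbg
    clauses:
    - variable: fbg
      op: ge
      threshold: 100.0
- definition: IDF
  mandatory: central_obesity
  min_criteria: 2
  criteria:
  - name: central_obesity
    clauses:
    - variable: wc
      op: ge
      threshold:
        female: 80.0
        male: 94.0
  - name: raised_tg
    clauses:
    - variable: tg
      op: ge
      threshold: 150.0
  - name: low_hdl
    clauses:
    - variable: hdl
      op: lt
      threshold:
        female: 50.0
        male: 40.0
  - name: raised_bp
    clauses:
    - variable: sbp
      op: ge
      threshold: 130.0
    - variable: dbp
      op: ge
      threshold: 85.0
  - name: raised_fbg
    clauses:
    - variable: fbg
      op: ge
      threshold: 100.0
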