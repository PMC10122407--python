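# Illustrative run: cohort dimensioned like the Swedish child-twin sample
# (4,767 MZ + 5,580 same-sex DZ pairs), with a highly heritable clinical-autism
# exposure and three physical health conditions at their published prevalences
# and variance components.  Cross-trait rc/re values are illustrative: the
# genetic correlations follow the published estimates, the shared-environment
# correlations default to 0, and re for epilepsy is set so rPH is about 0.40.
seed: 1
cohort:
  spec:
    n_mz: 4767
    n_dz: 5580
    traits:
      - {name: clinical_autism, a2: 0.90, K: 0.016}
      - {name: epilepsy, a2: 0.61, K: 0.012}
      - {name: asthma, a2: 0.68, c2: 0.15, K: 0.134}
      - {name: constipation, a2: 0.51, K: 0.062}
    cross:
      - {a: clinical_autism, b: epilepsy, ra: 0.50, re: 0.15}
      - {a: clinical_autism, b: asthma, ra: 0.15}
      - {a: clinical_autism, b: constipation, ra: 0.31}
exposures: [clinical_autism]
outcomes: [epilepsy, asthma, constipation]
alpha: 0.05
bivariate_method: two_stage
out_dir: liabtwin_out
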