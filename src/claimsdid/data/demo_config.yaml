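# Bundled demo study: a small synthetic cohort with self-selection and a
# -$10 PUPM injected post-enlistment effect.  Omitted keys fall back to the
# package defaults (see claimsdid.config).
n_members: 6000
n_months: 30
enroll_window: [12, 22]
treatment_effect_pupm: -10.0
seed: 20230314
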