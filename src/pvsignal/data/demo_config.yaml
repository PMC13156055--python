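# Demonstration pipeline configuration: a synthetic spontaneous-report
# universe with eight atypical antipsychotics, four background drugs,
# five seizure preferred terms and seven background PTs.  Planted
# rate multipliers mirror the qualitative signal hierarchy seen in
# public reporting data (ziprasidone/quetiapine/clozapine strongest);
# the quetiapine–Status epilepticus pair is planted strongly enough to
# pass all four detection criteria at this sample size.
generator:
  n_reports: 20000
  seed: 20260926
  duplicate_rate: 0.05
  concomitant_rate: 0.25
  missing_age_rate: 0.25
  missing_sex_rate: 0.08
  missing_country_rate: 0.05
  drugs:
    - {name: clozapine, probability: 0.05, synonyms: [Clozaril, CLOZAPINE]}
    - {name: quetiapine, probability: 0.06, synonyms: [Seroquel, "  quetiapine "]}
    - {name: olanzapine, probability: 0.05, synonyms: [Zyprexa]}
    - {name: aripiprazole, probability: 0.05, synonyms: [Abilify]}
    - {name: ziprasidone, probability: 0.03, synonyms: [Geodon]}
    - {name: risperidone, probability: 0.05, synonyms: [Risperdal]}
    - {name: lurasidone, probability: 0.03, synonyms: [Latuda]}
    - {name: paliperidone, probability: 0.03, synonyms: [Invega]}
    - {name: sertraline, probability: 0.20, synonyms: [Zoloft]}
    - {name: metformin, probability: 0.20, synonyms: [Glucophage]}
    - {name: lisinopril, probability: 0.15, synonyms: [Prinivil, Zestril]}
    - {name: ibuprofen, probability: 0.10, synonyms: [Advil, Motrin]}
  events:
    - {pt: Seizure, probability: 0.012}
    - {pt: Generalised tonic-clonic seizure, probability: 0.004}
    - {pt: Epilepsy, probability: 0.003}
    - {pt: Status epilepticus, probability: 0.002}
    - {pt: Myoclonic epilepsy, probability: 0.001}
    - {pt: Nausea, probability: 0.08}
    - {pt: Headache, probability: 0.07}
    - {pt: Dizziness, probability: 0.06}
    - {pt: Insomnia, probability: 0.05}
    - {pt: Rash, probability: 0.04}
    - {pt: Fatigue, probability: 0.05}
    - {pt: Vomiting, probability: 0.04}
  signals:
    - {drug: clozapine, event_pt: Seizure, rate_multiplier: 2.4}
    - {drug: clozapine, event_pt: Generalised tonic-clonic seizure, rate_multiplier: 4.5}
    - {drug: quetiapine, event_pt: Seizure, rate_multiplier: 2.8}
    - {drug: quetiapine, event_pt: Generalised tonic-clonic seizure, rate_multiplier: 3.2}
    - {drug: quetiapine, event_pt: Status epilepticus, rate_multiplier: 8.0}
    - {drug: olanzapine, event_pt: Seizure, rate_multiplier: 2.3}
    - {drug: aripiprazole, event_pt: Seizure, rate_multiplier: 2.2}
    - {drug: ziprasidone, event_pt: Seizure, rate_multiplier: 3.4}
    - {drug: risperidone, event_pt: Seizure, rate_multiplier: 1.5}
screen_drugs: [clozapine, quetiapine, olanzapine, aripiprazole, ziprasidone, risperidone, lurasidone, paliperidone]
hlgt: Seizures (incl subtypes)
thresholds: {min_cases: 3}
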