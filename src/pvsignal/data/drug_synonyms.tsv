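raw	canonical
Clozaril	clozapine
FazaClo	clozapine
Seroquel	quetiapine
Seroquel XR	quetiapine
Zyprexa	olanzapine
Abilify	aripiprazole
Geodon	ziprasidone
Risperdal	risperidone
Latuda	lurasidone
Invega	paliperidone
Zoloft	sertraline
Glucophage	metformin
Prinivil	lisinopril
Zestril	lisinopril
Advil	ibuprofen
Motrin	ibuprofen
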