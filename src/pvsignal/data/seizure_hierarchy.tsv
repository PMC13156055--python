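pt	hlt	hlgt	soc
Seizure	Seizures NEC	Seizures (incl subtypes)	Nervous system disorders
Psychogenic seizure	Seizures NEC	Seizures (incl subtypes)	Nervous system disorders
Seizure like phenomena	Seizures NEC	Seizures (incl subtypes)	Nervous system disorders
Convulsive threshold lowered	Seizures NEC	Seizures (incl subtypes)	Nervous system disorders
Dreamy state	Seizures NEC	Seizures (incl subtypes)	Nervous system disorders
Alcoholic seizure	Seizures NEC	Seizures (incl subtypes)	Nervous system disorders
Hyponatraemic seizure	Seizures NEC	Seizures (incl subtypes)	Nervous system disorders
Hyponatremic seizure	Seizures NEC	Seizures (incl subtypes)	Nervous system disorders
Drug withdrawal convulsions	Seizures NEC	Seizures (incl subtypes)	Nervous system disorders
Generalised tonic-clonic seizure	Generalised tonic-clonic seizures	Seizures (incl subtypes)	Nervous system disorders
Tonic clonic movements	Generalised tonic-clonic seizures	Seizures (incl subtypes)	Nervous system disorders
Tonic convulsion	Generalised tonic-clonic seizures	Seizures (incl subtypes)	Nervous system disorders
Clonic convulsion	Generalised tonic-clonic seizures	Seizures (incl subtypes)	Nervous system disorders
Tonic posturing	Generalised tonic-clonic seizures	Seizures (incl subtypes)	Nervous system disorders
Atonic seizures	Generalised tonic-clonic seizures	Seizures (incl subtypes)	Nervous system disorders
Epilepsy	Epilepsies NEC	Seizures (incl subtypes)	Nervous system disorders
Temporal lobe epilepsy	Epilepsies NEC	Seizures (incl subtypes)	Nervous system disorders
Frontal lobe epilepsy	Epilepsies NEC	Seizures (incl subtypes)	Nervous system disorders
Idiopathic generalised epilepsy	Epilepsies NEC	Seizures (incl subtypes)	Nervous system disorders
Myoclonic epilepsy	Epilepsies NEC	Seizures (incl subtypes)	Nervous system disorders
Petit mal epilepsy	Generalised nonconvulsive epilepsy	Seizures (incl subtypes)	Nervous system disorders
Status epilepticus	Status epilepticus and convulsive states	Seizures (incl subtypes)	Nervous system disorders
Neonatal seizure	Neonatal seizures and disorders	Seizures (incl subtypes)	Nervous system disorders
Convulsion neonatal	Neonatal seizures and disorders	Seizures (incl subtypes)	Nervous system disorders
Complex partial seizures	Partial seizures	Seizures (incl subtypes)	Nervous system disorders
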