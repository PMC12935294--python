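pt
Myocarditis
Cardiac failure
Atrial fibrillation
Cardiac arrest
Pericardial effusion
Pericarditis
Tachycardia
Bradycardia
Cardiomyopathy
Palpitations
Myocardial infarction
Cardiac failure acute
Cardiac failure congestive
Ventricular tachycardia
Atrioventricular block
Cardiogenic shock
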