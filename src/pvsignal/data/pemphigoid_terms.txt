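Pemphigoid
Mucous membrane pemphigoid
Pemphigoid gestationis
Epidermolysis bullosa acquisita
Linear IgA disease
Benign familial pemphigus
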