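drug	pt	a	b	c	d
Tisagenlecleucel	Urinary hesitation	3	15237	544	15668261
Tisagenlecleucel	Kidney enlargement	3	15237	243	15668562
Axicabtagene ciloleucel	Urinary incontinence	35	19183	2116	15662711
Axicabtagene ciloleucel	Renal tubular necrosis	14	19204	3442	15661385
Brexucabtagene autoleucel	Urinary incontinence	8	2890	1450	11168998
Lisocabtagene maraleucel	Urinary incontinence	6	802	1004	7867633
Idecabtagene vicleucel	Acute kidney injury	26	1694	37016	8346665
Idecabtagene vicleucel	Urinary incontinence	4	1716	1060	8382621
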