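herb_id	name	role
BHSSC	Scleromitrion diffusum	JUN
CWJ	Eleutherococcus senticosus	JUN
FL	Poria	CHEN
BZ	Atractylodes macrocephala	CHEN
DS	Codonopsis radix	CHEN
GQZ	Lycium chinense	CHEN
TSZ	Cuscuta	CHEN
NZZ	Ligustri lucidi fructus	CHEN
HZ	Reynoutria japonica	ZUO_SHI
WWZ	Schisandra chinensis	ZUO_SHI
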