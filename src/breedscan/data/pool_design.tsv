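code	breeds	n	kind	size_class	ear_class	depth_x
BT	Border Terrier	5	SC	small	non-drop	4748
JR	Jack Russell Terrier	5	SC	small	non-drop	4910
GS	German Shepherd	5	SC	large	non-drop	5182
WEI	Weimaraner	5	SC	large	drop	4305
ESS	English Springer Spaniel	5	SC	large	drop	1990
Pool1	Wolf	12	WGS	large	non-drop	7.5
Pool2	Smaland Hound;Norwegian Elkhound;Swedish Elkhound;Finnish Lapphund	12	WGS	large	mix	6.9
Pool3	Cocker Spaniel;Springer Spaniel;Golden Retriever;Labrador Retriever	12	WGS	large	drop	6.1
Pool4	Drever	12	WGS	large	drop	8.0
Pool5	Belgian Tervuren	12	WGS	large	non-drop	8.1
Pool6	Bearded Collie;Hovawart;Riesenschnauzer;German Shepherd	12	WGS	large	mix	7.9
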