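breed	n	ear_type	body_mass_kg
Cavalier King Charles Spaniel	5	drop	6
Dachshund	12	drop	7
Beagle	10	drop	10
Cocker Spaniel	14	drop	13
English Cocker Spaniel	2	drop	14
Brittany Spaniel	12	drop	17
Nova Scotia Duck Tolling Retriever	23	drop	20
English Springer Spaniel	3	drop	23
Shar Pei	11	drop	24
Dalmatian	7	drop	25
Standard Poodle	12	drop	25
Weimaraner	26	drop	28
Flatcoated Retriever	2	drop	29
Large Munsterlander	1	drop	30
Labrador Retriever	14	drop	30
English Setter	12	drop	31
Gordon Setter	25	drop	31
Golden Retriever	14	drop	32
Bernese Mountain Dog	12	drop	45
Newfoundland	25	drop	64
Yorkshire Terrier	12	intermediate	3
Border Terrier	25	intermediate	6
Jack Russell Terrier	12	intermediate	7
Pug	2	intermediate	7
Border Collie	16	intermediate	17
Schnauzer	3	intermediate	17
English Bulldog	13	intermediate	24
Australian Shepherd	1	intermediate	25
English Bull Terrier	8	intermediate	25
Boxer	8	intermediate	29
Greyhound	11	intermediate	30
Doberman Pinscher	25	intermediate	35
Rottweiler	12	intermediate	45
Irish Wolfhound	11	intermediate	54
Chihuahua	2	prick	2
Schipperke	25	prick	7
Finnish Spitz	12	prick	11
Czechoslovakian Wolf Dog	3	prick	23
Elkhound	12	prick	23
Eurasier	12	prick	24
Siberian Husky	2	prick	24
Samoyed	2	prick	24
Greenland Sledge Dog	12	prick	31
Belgian Tervuren	12	prick	32
German Shepherd	12	prick	37
Sarloos	2	prick	37
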