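atc_code	name
A	Alimentary tract and metabolism
A01	Stomatological preparations
A02	Drugs for acid related disorders
A10	Drugs used in diabetes
B	Blood and blood forming organs
B01	Antithrombotic agents
C	Cardiovascular system
C03	Diuretics
C07	Beta blocking agents
D	Dermatologicals
D01	Antifungals for dermatological use
G	Genito urinary system and sex hormones
G03	Sex hormones and modulators of the genital system
H	Systemic hormonal preparations, excl. sex hormones and insulins
H02	Corticosteroids for systemic use
J	Antiinfectives for systemic use
J01	Antibacterials for systemic use
J05	Antivirals for systemic use
J05A	Direct acting antivirals
J05AB	Nucleosides and nucleotides excl. reverse transcriptase inhibitors
J05AB01	aciclovir
L	Antineoplastic and immunomodulating agents
L01	Antineoplastic agents
M	Musculo-skeletal system
M01	Antiinflammatory and antirheumatic products
N	Nervous system
N02	Analgesics
N02BE01	paracetamol
P	Antiparasitic products, insecticides and repellents
P01	Antiprotozoals
R	Respiratory system
R03	Drugs for obstructive airway diseases
S	Sensory organs
S01	Ophthalmologicals
V	Various
V03	All other therapeutic products
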