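disease	n
breast invasive carcinoma	68
pancreatic adenocarcinoma	67
kidney clear cell carcinoma	46
osteosarcoma	20
lung adenocarcinoma	19
stomach adenocarcinoma	14
colon adenocarcinoma	11
mesothelioma	10
testicular germ cell tumor	9
lung squamous cell carcinoma	8
ovarian serous cystadenocarcinoma	8
thyroid carcinoma	8
bladder urothelial carcinoma	7
dedifferentiated liposarcoma	5
skin cutaneous melanoma	5
glioblastoma multiforme	4
rectum adenocarcinoma	4
cholangiocarcinoma	3
kidney papillary cell carcinoma	3
sarcoma	3
glioma	2
hepatoblastoma	2
myoepithelial carcinoma of the liver	2
atypical teratoid/rhabdoid tumor	1
epithelioid hemangioendothelioma	1
head & neck squamous cell carcinoma	1
hepatocellular carcinoma	1
leiomyosarcoma	1
myoepithelial carcinoma	1
myofibromatosis	1
prostate adenocarcinoma	1
synovial sarcoma	1
uterine carcinosarcoma	1
uterine corpus endometrioid carcinoma	1
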