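name,formula,monoisotopic_mass,class,plausible_in_soil
DIMBOA,C9H9NO5,211.0481,benzoxazinoid,true
DIBOA,C8H7NO4,,benzoxazinoid,true
HBOA,C8H7NO3,,benzoxazinoid,true
HMBOA,C9H9NO4,,benzoxazinoid,true
BOA,C7H5NO2,,benzoxazinoid,true
APO,C12H8N2O2,,benzoxazinoid,true
quercetin,C15H10O7,,flavonoid,true
kaempferol,C15H10O6,,flavonoid,true
apigenin,C15H10O5,,flavonoid,true
naringenin,C15H12O5,,flavonoid,true
catechin,C15H14O6,,flavonoid,true
rutin,C27H30O16,,flavonoid,true
ferulic acid,C10H10O4,,phenylpropanoid,true
caffeic acid,C9H8O4,,phenylpropanoid,true
p-coumaric acid,C9H8O3,,phenylpropanoid,true
chlorogenic acid,C16H18O9,,phenylpropanoid,true
scopoletin,C10H8O4,,phenylpropanoid,true
esculetin,C9H6O4,,phenylpropanoid,true
palmitic acid,C16H32O2,,lipid,true
linoleic acid,C18H32O2,,lipid,true
oleic acid,C18H34O2,,lipid,true
stearic acid,C18H36O2,,lipid,true
alpha-linolenic acid,C18H30O2,,lipid,true
LysoPC 16:0,C24H50NO7P,,lipid,true
nicotine,C10H14N2,,alkaloid,true
trigonelline,C7H7NO2,,alkaloid,true
camalexin,C11H8N2S,,alkaloid,true
gramine,C11H14N2,,alkaloid,true
malic acid,C4H6O5,,organic acid,true
citric acid,C6H8O7,,organic acid,true
succinic acid,C4H6O4,,organic acid,true
salicylic acid,C7H6O3,,organic acid,true
tryptophan,C11H12N2O2,,amino acid,true
phenylalanine,C9H11NO2,,amino acid,true
glutamine,C5H10N2O3,,amino acid,true
sinigrin,C10H17NO9S2,,glucosinolate,true
ibuprofen,C13H18O2,,synthetic drug,false
paracetamol,C8H9NO2,,synthetic drug,false
diazepam,C16H13ClN2O,,synthetic drug,false
testosterone,C19H28O2,,mammalian hormone,false
estradiol,C18H24O2,,mammalian hormone,false
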