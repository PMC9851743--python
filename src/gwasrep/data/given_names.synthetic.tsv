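name	gender
james	men
john	men
robert	men
michael	men
david	men
william	men
thomas	men
daniel	men
matthew	men
andrew	men
joseph	men
christopher	men
anthony	men
mark	men
paul	men
steven	men
kenneth	men
george	men
erik	men
lars	men
anders	men
johan	men
henrik	men
olof	men
bjorn	men
hiroshi	men
takashi	men
kenji	men
yusuke	men
kazuhiko	men
wei	men
jun	men
hao	men
ming	men
lei	men
sung	men
minho	men
jihoon	men
hans	men
klaus	men
stefan	men
wolfgang	men
pierre	men
jean	men
luca	men
marco	men
carlos	men
jose	men
rajesh	men
arjun	men
ahmed	men
omar	men
kwame	men
tunde	men
mary	women
patricia	women
jennifer	women
linda	women
elizabeth	women
barbara	women
susan	women
jessica	women
sarah	women
karen	women
nancy	women
lisa	women
margaret	women
emily	women
anna	women
ingrid	women
astrid	women
karin	women
elin	women
freyja	women
sigrid	women
yuki	women
sakura	women
haruka	women
aiko	women
naoko	women
li	women
xiu	women
mei	women
fang	women
jing	women
eunji	women
soyeon	women
hana	women
greta	women
ursula	women
sabine	women
monika	women
marie	women
claire	women
giulia	women
chiara	women
maria	women
lucia	women
priya	women
ananya	women
fatima	women
leila	women
amara	women
adaeze	women
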