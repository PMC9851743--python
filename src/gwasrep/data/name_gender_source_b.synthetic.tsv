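name	country	label	accuracy	samples
james		men	95	12000
john		men	95	12000
robert		men	95	12000
michael		men	95	12000
david		men	95	12000
william		men	95	12000
thomas		men	95	12000
daniel		men	95	12000
matthew		men	95	12000
andrew		men	95	12000
joseph		men	95	12000
christopher		men	95	12000
anthony		men	95	12000
mark		men	95	12000
paul		men	95	12000
steven		men	95	12000
kenneth		men	95	12000
george		men	95	12000
erik		men	95	12000
lars		men	95	12000
anders		men	95	12000
johan		men	95	12000
henrik		men	95	12000
olof		men	95	12000
bjorn		men	95	12000
hiroshi		men	95	12000
takashi		men	95	12000
kenji		men	95	12000
yusuke		men	95	12000
kazuhiko		men	95	12000
wei		men	95	12000
jun		men	95	12000
hao		men	95	12000
ming		men	95	12000
lei		men	95	12000
sung		men	95	12000
minho		men	95	12000
jihoon		men	95	12000
hans		men	95	12000
klaus		men	95	12000
stefan		men	95	12000
wolfgang		men	95	12000
pierre		men	95	12000
jean		men	95	12000
luca		men	95	12000
marco		men	95	12000
carlos		men	95	12000
jose		men	95	12000
rajesh		men	95	12000
arjun		men	95	12000
ahmed		men	95	12000
omar		men	95	12000
kwame		men	95	12000
tunde		men	95	12000
mary		women	94	11000
patricia		women	94	11000
jennifer		women	94	11000
linda		women	94	11000
elizabeth		women	94	11000
barbara		women	94	11000
susan		women	94	11000
jessica		women	94	11000
sarah		women	94	11000
karen		women	94	11000
nancy		women	94	11000
lisa		women	94	11000
margaret		women	94	11000
emily		women	94	11000
anna		women	94	11000
ingrid		women	94	11000
astrid		women	94	11000
karin		women	94	11000
elin		women	94	11000
freyja		women	94	11000
sigrid		women	94	11000
yuki		women	94	11000
sakura		women	94	11000
haruka		women	94	11000
aiko		women	94	11000
naoko		women	94	11000
li		women	94	11000
xiu		women	94	11000
mei		women	94	11000
fang		women	94	11000
jing		women	94	11000
eunji		women	94	11000
soyeon		women	94	11000
hana		women	94	11000
greta		women	94	11000
ursula		women	94	11000
sabine		women	94	11000
monika		women	94	11000
marie		women	94	11000
claire		women	94	11000
giulia		women	94	11000
chiara		women	94	11000
maria		women	94	11000
lucia		women	94	11000
priya		women	94	11000
ananya		women	94	11000
fatima		women	94	11000
leila		women	94	11000
amara		women	94	11000
adaeze		women	94	11000
andrea	Italy	men	90	8000
andrea		women	70	9000
kim		women	55	2000
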