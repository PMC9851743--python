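name	country	label	accuracy	samples
james		men	0.97	5000
john		men	0.97	5000
robert		men	0.97	5000
michael		men	0.97	5000
david		men	0.97	5000
william		men	0.97	5000
thomas		men	0.97	5000
daniel		men	0.97	5000
matthew		men	0.97	5000
andrew		men	0.97	5000
joseph		men	0.97	5000
christopher		men	0.97	5000
anthony		men	0.97	5000
mark		men	0.97	5000
paul		men	0.97	5000
steven		men	0.97	5000
kenneth		men	0.97	5000
george		men	0.97	5000
erik		men	0.97	5000
lars		men	0.97	5000
anders		men	0.97	5000
johan		men	0.97	5000
henrik		men	0.97	5000
olof		men	0.97	5000
bjorn		men	0.97	5000
hiroshi		men	0.97	5000
takashi		men	0.97	5000
kenji		men	0.97	5000
yusuke		men	0.97	5000
kazuhiko		men	0.97	5000
wei		men	0.97	5000
jun		men	0.97	5000
hao		men	0.97	5000
ming		men	0.97	5000
lei		men	0.97	5000
sung		men	0.97	5000
minho		men	0.97	5000
jihoon		men	0.97	5000
hans		men	0.97	5000
klaus		men	0.97	5000
stefan		men	0.97	5000
wolfgang		men	0.97	5000
pierre		men	0.97	5000
jean		men	0.97	5000
luca		men	0.97	5000
marco		men	0.97	5000
carlos		men	0.97	5000
jose		men	0.97	5000
rajesh		men	0.97	5000
arjun		men	0.97	5000
ahmed		men	0.97	5000
omar		men	0.97	5000
kwame		men	0.97	5000
tunde		men	0.97	5000
mary		women	0.96	4500
patricia		women	0.96	4500
jennifer		women	0.96	4500
linda		women	0.96	4500
elizabeth		women	0.96	4500
barbara		women	0.96	4500
susan		women	0.96	4500
jessica		women	0.96	4500
sarah		women	0.96	4500
karen		women	0.96	4500
nancy		women	0.96	4500
lisa		women	0.96	4500
margaret		women	0.96	4500
emily		women	0.96	4500
anna		women	0.96	4500
ingrid		women	0.96	4500
astrid		women	0.96	4500
karin		women	0.96	4500
elin		women	0.96	4500
freyja		women	0.96	4500
sigrid		women	0.96	4500
yuki		women	0.96	4500
sakura		women	0.96	4500
haruka		women	0.96	4500
aiko		women	0.96	4500
naoko		women	0.96	4500
li		women	0.96	4500
xiu		women	0.96	4500
mei		women	0.96	4500
fang		women	0.96	4500
jing		women	0.96	4500
eunji		women	0.96	4500
soyeon		women	0.96	4500
hana		women	0.96	4500
greta		women	0.96	4500
ursula		women	0.96	4500
sabine		women	0.96	4500
monika		women	0.96	4500
marie		women	0.96	4500
claire		women	0.96	4500
giulia		women	0.96	4500
chiara		women	0.96	4500
maria		women	0.96	4500
lucia		women	0.96	4500
priya		women	0.96	4500
ananya		women	0.96	4500
fatima		women	0.96	4500
leila		women	0.96	4500
amara		women	0.96	4500
adaeze		women	0.96	4500
andrea	Italy	men	0.88	3000
andrea		women	0.80	6000
kim		unknown	0	0
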