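alias	canonical	type
United States	United States	country
USA	United States	iso
US	United States	country
U.S.	United States	country
U.S.A.	United States	country
United States of America	United States	country
America	United States	country
United Kingdom	United Kingdom	country
GBR	United Kingdom	iso
UK	United Kingdom	country
U.K.	United Kingdom	country
Great Britain	United Kingdom	country
Britain	United Kingdom	country
China	China	country
CHN	China	iso
People's Republic of China	China	country
P.R. China	China	country
PR China	China	country
Japan	Japan	country
JPN	Japan	iso
Germany	Germany	country
DEU	Germany	iso
Deutschland	Germany	country
Sweden	Sweden	country
SWE	Sweden	iso
Sverige	Sweden	country
Iceland	Iceland	country
ISL	Iceland	iso
Norway	Norway	country
NOR	Norway	iso
Norge	Norway	country
Australia	Australia	country
AUS	Australia	iso
South Korea	South Korea	country
KOR	South Korea	iso
Republic of Korea	South Korea	country
Korea, Republic of	South Korea	country
Korea	South Korea	country
Netherlands	Netherlands	country
NLD	Netherlands	iso
The Netherlands	Netherlands	country
Holland	Netherlands	country
France	France	country
FRA	France	iso
Italy	Italy	country
ITA	Italy	iso
Italia	Italy	country
Spain	Spain	country
ESP	Spain	iso
Espana	Spain	country
Finland	Finland	country
FIN	Finland	iso
Suomi	Finland	country
Denmark	Denmark	country
DNK	Denmark	iso
Danmark	Denmark	country
Canada	Canada	country
CAN	Canada	iso
Switzerland	Switzerland	country
CHE	Switzerland	iso
Schweiz	Switzerland	country
Suisse	Switzerland	country
Austria	Austria	country
AUT	Austria	iso
Osterreich	Austria	country
Belgium	Belgium	country
BEL	Belgium	iso
Belgique	Belgium	country
Belgie	Belgium	country
Ireland	Ireland	country
IRL	Ireland	iso
Singapore	Singapore	country
SGP	Singapore	iso
Israel	Israel	country
ISR	Israel	iso
Estonia	Estonia	country
EST	Estonia	iso
Eesti	Estonia	country
Greece	Greece	country
GRC	Greece	iso
Hellas	Greece	country
Portugal	Portugal	country
PRT	Portugal	iso
Poland	Poland	country
POL	Poland	iso
Polska	Poland	country
Czechia	Czechia	country
CZE	Czechia	iso
Czech Republic	Czechia	country
New Zealand	New Zealand	country
NZL	New Zealand	iso
Saudi Arabia	Saudi Arabia	country
SAU	Saudi Arabia	iso
Brazil	Brazil	country
BRA	Brazil	iso
Brasil	Brazil	country
Mexico	Mexico	country
MEX	Mexico	iso
South Africa	South Africa	country
ZAF	South Africa	iso
Thailand	Thailand	country
THA	Thailand	iso
Malaysia	Malaysia	country
MYS	Malaysia	iso
Turkey	Turkey	country
TUR	Turkey	iso
Turkiye	Turkey	country
Colombia	Colombia	country
COL	Colombia	iso
Argentina	Argentina	country
ARG	Argentina	iso
Russia	Russia	country
RUS	Russia	iso
Russian Federation	Russia	country
India	India	country
IND	India	iso
Nigeria	Nigeria	country
NGA	Nigeria	iso
Kenya	Kenya	country
KEN	Kenya	iso
Pakistan	Pakistan	country
PAK	Pakistan	iso
Bangladesh	Bangladesh	country
BGD	Bangladesh	iso
Philippines	Philippines	country
PHL	Philippines	iso
The Philippines	Philippines	country
Egypt	Egypt	country
EGY	Egypt	iso
Vietnam	Vietnam	country
VNM	Vietnam	iso
Viet Nam	Vietnam	country
Ghana	Ghana	country
GHA	Ghana	iso
Indonesia	Indonesia	country
IDN	Indonesia	iso
Ethiopia	Ethiopia	country
ETH	Ethiopia	iso
Uganda	Uganda	country
UGA	Uganda	iso
Malawi	Malawi	country
MWI	Malawi	iso
Gambia	Gambia	country
GMB	Gambia	iso
The Gambia	Gambia	country
Massachusetts	United States	region
MA	United States	region
California	United States	region
CA	United States	region
New York	United States	region
NY	United States	region
Maryland	United States	region
MD	United States	region
Washington	United States	region
WA	United States	region
Texas	United States	region
TX	United States	region
Pennsylvania	United States	region
PA	United States	region
Illinois	United States	region
IL	United States	region
Michigan	United States	region
MI	United States	region
North Carolina	United States	region
NC	United States	region
Connecticut	United States	region
CT	United States	region
Minnesota	United States	region
MN	United States	region
Tennessee	United States	region
TN	United States	region
Florida	United States	region
FL	United States	region
Wisconsin	United States	region
WI	United States	region
Utah	United States	region
UT	United States	region
Arizona	United States	region
AZ	United States	region
New Jersey	United States	region
NJ	United States	region
Missouri	United States	region
MO	United States	region
Ohio	United States	region
OH	United States	region
Georgia	United States	region
Virginia	United States	region
VA	United States	region
Colorado	United States	region
Oregon	United States	region
North Dakota	United States	region
ND	United States	region
England	United Kingdom	region
Scotland	United Kingdom	region
Wales	United Kingdom	region
Northern Ireland	United Kingdom	region
New South Wales	Australia	region
NSW	Australia	region
Victoria	Australia	region
Queensland	Australia	region
QLD	Australia	region
Ontario	Canada	region
Quebec	Canada	region
British Columbia	Canada	region
BC	Canada	region
Alberta	Canada	region
Bavaria	Germany	region
Bayern	Germany	region
Baden-Wurttemberg	Germany	region
Noord-Holland	Netherlands	region
Zuid-Holland	Netherlands	region
Guangdong	China	region
Zhejiang	China	region
Jiangsu	China	region
Sichuan	China	region
Hunan	China	region
Hokkaido	Japan	region
Kanagawa	Japan	region
Aichi	Japan	region
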