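country	income_group
United States	HIC
United Kingdom	HIC
Japan	HIC
Germany	HIC
Sweden	HIC
Iceland	HIC
Norway	HIC
Australia	HIC
South Korea	HIC
Netherlands	HIC
France	HIC
Italy	HIC
Spain	HIC
Finland	HIC
Denmark	HIC
Canada	HIC
Switzerland	HIC
Austria	HIC
Belgium	HIC
Ireland	HIC
Singapore	HIC
Israel	HIC
Estonia	HIC
Greece	HIC
Portugal	HIC
Poland	HIC
Czechia	HIC
New Zealand	HIC
Saudi Arabia	HIC
China	UMIC
Brazil	UMIC
Mexico	UMIC
South Africa	UMIC
Thailand	UMIC
Malaysia	UMIC
Turkey	UMIC
Colombia	UMIC
Argentina	UMIC
Russia	UMIC
India	LMIC
Nigeria	LMIC
Kenya	LMIC
Pakistan	LMIC
Bangladesh	LMIC
Philippines	LMIC
Egypt	LMIC
Vietnam	LMIC
Ghana	LMIC
Indonesia	LMIC
Ethiopia	LIC
Uganda	LIC
Malawi	LIC
Gambia	LIC
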