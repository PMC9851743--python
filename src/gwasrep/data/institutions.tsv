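alias	canonical	country	city
Harvard Medical School	Harvard Medical School	United States	Boston
Harvard T.H. Chan School of Public Health	Harvard T.H. Chan School of Public Health	United States	Boston
Harvard School of Public Health	Harvard T.H. Chan School of Public Health	United States	Boston
Broad Institute	Broad Institute	United States	Cambridge
Broad Institute of MIT and Harvard	Broad Institute	United States	Cambridge
The Broad Institute	Broad Institute	United States	Cambridge
Massachusetts General Hospital	Massachusetts General Hospital	United States	Boston
Mass General Hospital	Massachusetts General Hospital	United States	Boston
Mayo Clinic	Mayo Clinic	United States	Rochester
National Cancer Institute	National Cancer Institute	United States	Bethesda
NCI	National Cancer Institute	United States	Bethesda
Stanford University	Stanford University	United States	Stanford
Stanford University School of Medicine	Stanford University	United States	Stanford
Johns Hopkins University	Johns Hopkins University	United States	Baltimore
Johns Hopkins School of Medicine	Johns Hopkins University	United States	Baltimore
University of Michigan	University of Michigan	United States	Ann Arbor
Vanderbilt University	Vanderbilt University	United States	Nashville
Vanderbilt University Medical Center	Vanderbilt University	United States	Nashville
Karolinska Institutet	Karolinska Institutet	Sweden	Stockholm
Karolinska Institutet Stockholm	Karolinska Institutet	Sweden	Stockholm
Lund University	Lund University	Sweden	Malmo
Lunds universitet	Lund University	Sweden	Malmo
Lund University Diabetes Centre	Lund University	Sweden	Malmo
Uppsala University	Uppsala University	Sweden	Uppsala
Uppsala universitet	Uppsala University	Sweden	Uppsala
deCODE genetics	deCODE genetics	Iceland	Reykjavik
deCODE Inc	deCODE genetics	Iceland	Reykjavik
deCODE	deCODE genetics	Iceland	Reykjavik
University of Iceland	University of Iceland	Iceland	Reykjavik
King's College London	King's College London	United Kingdom	London
Kings College London	King's College London	United Kingdom	London
KCL	King's College London	United Kingdom	London
University of Manchester	University of Manchester	United Kingdom	Manchester
The University of Manchester	University of Manchester	United Kingdom	Manchester
Wellcome Trust Sanger Institute	Wellcome Trust Sanger Institute	United Kingdom	Hinxton
Wellcome Sanger Institute	Wellcome Trust Sanger Institute	United Kingdom	Hinxton
Sanger Institute	Wellcome Trust Sanger Institute	United Kingdom	Hinxton
University of Oxford	University of Oxford	United Kingdom	Oxford
Wellcome Trust Centre for Human Genetics	Wellcome Trust Centre for Human Genetics	United Kingdom	Oxford
Wellcome Centre for Human Genetics	Wellcome Trust Centre for Human Genetics	United Kingdom	Oxford
University of Cambridge	University of Cambridge	United Kingdom	Cambridge
University College London	University College London	United Kingdom	London
UCL	University College London	United Kingdom	London
University of Tokyo	University of Tokyo	Japan	Tokyo
The University of Tokyo	University of Tokyo	Japan	Tokyo
Tokyo University	University of Tokyo	Japan	Tokyo
RIKEN	RIKEN	Japan	Yokohama
RIKEN Center for Integrative Medical Sciences	RIKEN	Japan	Yokohama
Osaka University	Osaka University	Japan	Osaka
Peking University	Peking University	China	Beijing
Fudan University	Fudan University	China	Shanghai
Shanghai Jiao Tong University	Shanghai Jiao Tong University	China	Shanghai
Seoul National University	Seoul National University	South Korea	Seoul
Seoul National University College of Medicine	Seoul National University	South Korea	Seoul
University of Melbourne	University of Melbourne	Australia	Melbourne
The University of Melbourne	University of Melbourne	Australia	Melbourne
QIMR Berghofer Medical Research Institute	QIMR Berghofer Medical Research Institute	Australia	Brisbane
QIMR Berghofer	QIMR Berghofer Medical Research Institute	Australia	Brisbane
Erasmus University Medical Center	Erasmus University Medical Center	Netherlands	Rotterdam
Erasmus MC	Erasmus University Medical Center	Netherlands	Rotterdam
Erasmus Medical Center	Erasmus University Medical Center	Netherlands	Rotterdam
University of Groningen	University of Groningen	Netherlands	Groningen
Charite Universitatsmedizin Berlin	Charite Universitatsmedizin Berlin	Germany	Berlin
Charite	Charite Universitatsmedizin Berlin	Germany	Berlin
Helmholtz Zentrum Munchen	Helmholtz Zentrum Munchen	Germany	Munich
Helmholtz Munich	Helmholtz Zentrum Munchen	Germany	Munich
INSERM	INSERM	France	Paris
Institut national de la sante et de la recherche medicale	INSERM	France	Paris
University of Helsinki	University of Helsinki	Finland	Helsinki
Helsingin yliopisto	University of Helsinki	Finland	Helsinki
University of Copenhagen	University of Copenhagen	Denmark	Copenhagen
Kobenhavns Universitet	University of Copenhagen	Denmark	Copenhagen
University of Oslo	University of Oslo	Norway	Oslo
Universitetet i Oslo	University of Oslo	Norway	Oslo
University of Toronto	University of Toronto	Canada	Toronto
National University of Singapore	National University of Singapore	Singapore	Singapore
NUS	National University of Singapore	Singapore	Singapore
University of the Witwatersrand	University of the Witwatersrand	South Africa	Johannesburg
Wits University	University of the Witwatersrand	South Africa	Johannesburg
University of Sao Paulo	University of Sao Paulo	Brazil	Sao Paulo
Universidade de Sao Paulo	University of Sao Paulo	Brazil	Sao Paulo
USP	University of Sao Paulo	Brazil	Sao Paulo
All India Institute of Medical Sciences	All India Institute of Medical Sciences	India	New Delhi
AIIMS	All India Institute of Medical Sciences	India	New Delhi
Makerere University	Makerere University	Uganda	Kampala
University of Ibadan	University of Ibadan	Nigeria	Ibadan
Aga Khan University	Aga Khan University	Pakistan	Karachi
Cairo University	Cairo University	Egypt	Giza
Chulalongkorn University	Chulalongkorn University	Thailand	Bangkok
Istanbul University	Istanbul University	Turkey	Istanbul
National Autonomous University of Mexico	National Autonomous University of Mexico	Mexico	Mexico City
UNAM	National Autonomous University of Mexico	Mexico	Mexico City
University of Nairobi	University of Nairobi	Kenya	Nairobi
University of Milan	University of Milan	Italy	Milan
University of Bologna	University of Bologna	Italy	Bologna
University of Barcelona	University of Barcelona	Spain	Barcelona
Pompeu Fabra University	Pompeu Fabra University	Spain	Barcelona
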