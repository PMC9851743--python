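efo_code	disease_area
EFO:01010011	cardiovascular diseases
EFO:01010012	cardiovascular diseases
EFO:01010013	cardiovascular diseases
EFO:01010021	neoplasms
EFO:01010022	neoplasms
EFO:01010023	neoplasms
EFO:01010031	chronic respiratory diseases
EFO:01010032	chronic respiratory diseases
EFO:01010033	chronic respiratory diseases
EFO:01010041	diabetes and CKD
EFO:01010042	diabetes and CKD
EFO:01010043	diabetes and CKD
EFO:01010051	neurological disorders
EFO:01010052	neurological disorders
EFO:01010053	neurological disorders
EFO:01010061	mental disorders
EFO:01010062	mental disorders
EFO:01010063	mental disorders
EFO:01010071	digestive diseases
EFO:01010072	digestive diseases
EFO:01010073	digestive diseases
EFO:01010081	musculoskeletal disorders
EFO:01010082	musculoskeletal disorders
EFO:01010083	musculoskeletal disorders
EFO:01010091	substance use
EFO:01010092	substance use
EFO:01010093	substance use
EFO:01010101	skin diseases
EFO:01010102	skin diseases
EFO:01010103	skin diseases
EFO:0101099	diabetes and CKD
EFO:0101099	cardiovascular diseases
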