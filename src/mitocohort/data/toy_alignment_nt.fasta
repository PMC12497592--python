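>human_synthetic reference row (synthetic toy alignment, 8 species, 90 nt)
ATGGCATTACCGGATCAGTACGGCTTAACCGTAGCATGACCGTTAGGCATCGATTACGGA-TCCGATTAGCCGTAACGGATTCAGCATGA
>species_2
ATGGCATTACCGGATCAGTACGGCTTAACCGTAGCATGACCGTTAGGCATCGATTACGGAATCCGATTAGCCGTAACGGATTCAGCATGA
>species_3
ATGGCATTACCAGATCAGTACGGCTTAACCGTAGCATGACCGTTAGGCATCGATTACGGA-TCCGATTAGCCGTAACGGATTCAGCATGA
>species_4
ATGGCATTACCGGATCAGTACGGCTTAACCGTAGCATGACCGTTAGGCATCGATTACGGA-TCCGATTAGCCGTAACGGATTCAGCATGA
>species_5
ATGGCGTTACCGGATCAGTACGGCTTAACCGTAGCATGACCGTTAGGCATCGATTACGGA-TCCGATTAGCCGTAACGGATTCAGCATGA
>species_6
ATGGCATTACCGGATCAGTACGGCTTAACCATAGCATGACCGTTAGGCATCGATTACGGA-TCCGATTAGCCGTAACGGATTCAGCATGA
>species_7
ATGGCATTACCGGATCAGTACGGCTTAACCGTAGCATGACCGTTAGGCATCGATT-CGGA-TCCGATTAGCCGTAACGGATTCAGCATGA
>species_8
ATGGCATTACCGGATCAGTACGGCTTAACCGTAGCATGACCGTTAGGCATCGATTACGGA-TCCGATTAGCCGTAACGGATTCAGCATGA
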