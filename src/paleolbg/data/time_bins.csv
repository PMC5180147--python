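scheme,label,max_ma,min_ma
five_bin,Tr,252.17,201.30
five_bin,Jur,201.30,145.00
five_bin,rCret,145.00,83.60
five_bin,Camp,83.60,72.10
five_bin,Maas,72.10,66.00
three_bin,Jurassic,201.30,145.00
three_bin,Early Cretaceous,145.00,100.50
three_bin,Late Cretaceous,100.50,66.00
era,Triassic,252.17,201.30
era,Jurassic,201.30,145.00
era,Cretaceous,145.00,66.00
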