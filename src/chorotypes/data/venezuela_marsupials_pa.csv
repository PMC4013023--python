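species,A2,B1,B2,B3,B4,B5,C1,C2,D1,D2,D3,D4,D5,D6,D7
Caenolestes fuliginosus,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0
Caluromys lanatus,0,1,0,0,0,1,0,0,1,1,0,0,0,0,0
Caluromys philander,0,0,0,0,1,1,0,1,0,0,0,0,0,0,1
Caluromys trinitatis,0,0,1,1,0,0,1,0,0,1,0,1,1,1,0
Chironectes minimus,0,0,0,1,1,0,0,0,1,1,0,1,1,0,1
Didelphis imperfecta,0,0,0,0,0,1,0,1,0,0,0,0,0,0,1
Didelphis marsupialis,0,1,1,1,1,1,1,1,1,1,1,1,1,0,1
Didelphis pernigra,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0
Gracilinanus dryas,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0
Gracilinanus marica,0,0,0,0,0,0,0,0,1,1,1,1,1,0,0
Lutreolina crassicaudata,0,0,1,1,0,0,0,1,0,0,0,0,0,0,1
Marmosa demerarae,0,0,0,1,1,1,0,1,0,1,1,1,1,0,1
Marmosa lepida,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0
Marmosa murina,0,1,0,1,1,1,0,1,1,1,0,1,1,0,1
Marmosa robinsoni,0,1,1,1,0,0,1,0,1,1,1,1,1,1,0
Marmosa tyleriana,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
Marmosa waterhousei,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0
Marmosa xerophila,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0
Marmosops cracens,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0
Marmosops fuscatus,0,0,0,0,0,0,1,0,1,1,1,1,1,0,0
Marmosops impavidus,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0
Marmosops neblina,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
Marmosops pakaraimae,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
Marmosops pinheiroi,0,0,0,0,1,0,0,0,0,0,0,0,0,0,1
Metachirus nudicaudatus,0,1,1,1,1,1,0,1,1,1,0,0,0,0,1
Monodelphis adusta,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0
Monodelphis brevicaudata,0,0,0,0,1,1,0,1,0,0,0,0,0,0,1
Monodelphis palliolata,0,1,0,1,0,0,1,0,1,1,1,1,1,0,0
Monodelphis reigi,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
Monodelphis species A,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0
Philander andersoni,0,0,0,0,1,1,0,0,0,0,0,0,0,0,0
Philander deltae,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0
Philander mondolfii,0,1,1,0,0,0,0,1,1,1,0,0,0,0,1
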