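word,length,frequency_per_million
VOPU,4,8.0
SEBE,4,8.9
TALU,4,8.2
CISE,4,3.5
REVI,4,5.5
NIMU,4,8.1
POGU,4,2.9
SATO,4,1.4
LACI,4,5.2
SUSO,4,5.6
FIKE,4,82.6
CAVO,4,124.1
RELA,4,262.6
PAME,4,273.7
DIVU,4,220.7
BOLA,4,199.1
RINU,4,159.5
PICA,4,165.3
NEFA,4,259.6
KENU,4,209.8
LOLOM,5,2.4
PILEF,5,4.6
SAKUV,5,7.0
FAGIT,5,7.0
MASUL,5,9.1
VUMED,5,2.7
RUFIB,5,9.0
DUNIM,5,4.4
VIDEP,5,8.9
BILOM,5,3.9
LOBAR,5,86.7
KUCIV,5,224.7
RICIL,5,155.7
TANEP,5,158.2
TIMOS,5,113.2
TIVEB,5,245.7
RUPAS,5,259.4
KUBUN,5,254.5
VICOF,5,123.7
FUKAD,5,156.1
GUTIVEC,7,9.6
FELEVAM,7,5.7
TURONIS,7,8.9
KEKOTAB,7,4.9
DIMURES,7,7.1
SERANUV,7,4.0
NEREDAL,7,9.2
DUSICON,7,5.3
DILOKEC,7,5.2
VENINAD,7,1.6
PIBOPUT,7,104.9
RUTOSOT,7,195.1
SUGADAL,7,135.6
BOFUDUM,7,88.6
GICACOC,7,148.3
BIVUMOS,7,224.8
FOFARIK,7,256.4
BIVUSAB,7,154.5
SEDAGOC,7,149.0
SOTISEC,7,248.7
RULANIKO,8,6.5
SALOBOTU,8,8.2
KECOGULU,8,2.5
GALOPEDI,8,9.5
TEDETIVO,8,1.9
NESADOPU,8,4.4
GEPIGEPE,8,4.0
SINAGORI,8,3.7
DADOTAMA,8,2.2
NARURESE,8,8.5
LOSABIDU,8,162.6
GOLAPOBO,8,261.7
SOGERAFI,8,246.6
SAFERIDO,8,277.2
MATABOLO,8,238.6
KUNUSUCO,8,166.9
GODATONO,8,238.7
DIDEGILA,8,265.8
LICEVIBO,8,163.9
BUFUKESA,8,247.3
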