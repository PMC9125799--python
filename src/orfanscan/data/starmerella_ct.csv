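virus;Cz1;Cz2;Cz3;Cz4;Cz6;Cz7;Cz12;Cz16;Cz21;Cz25;Cz26;CzGP
SbOMV1_RNA1;;;;;;;24,67;25,37;;23,37;;
SbOMV1_RNA2;;;;;;;23,95;24,41;;23,49;;
SbTV1;28,15;;31,23;;31,17;;26,98;;;25,43;;28,56
SbMV1;34,43;;;;;;23,08;;;;;
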