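>synthAQP1_ref synthetic water-selective reference frame
PEESKGRGAMAIIVLVLMMVAAFAFLMALAHKDDTKPHGTGDQPQKHSFFMMMFLFIMAV
FVAFMIALIFRGHEQNPARTRRSKKRQHDRKTKQMMVMIFIAAFAVVMMAIMAAILKESD
THEQSDSSAVVFLFFFIIMVFIVAFLMIIFHDQGGEEHDQTQAMAAALMALFFFFFVAFH
LMLATPRTCKSNPARTTTSQAEQRTTDQKPTGRGAAFFIMLLAVMALIAVVVVVIFTEQD
YERGWQEKRPSQEERSRPKHHEG
>synthGLP_ref synthetic glycerol-facilitator reference frame
PHESGDRGAMAIILMMLMFVMAFFFLMIFVHKDDTQPHGEGDQTQKHSFFMMVFLWIFAV
VMMLMIALIMRQHEQNPAQTRRGKKRPHDQKTKQIVIMLFIAAIMFVMMALMVIILPGRD
YHEQSTSSAMLLIVFFIIVMFIVAFLMAMFRDQEGETGRSTQLMALALMALALFMAMAFG
IALATPRQFPSNPARTTTDQKRQRTTDQKPEGRKALFLMLLLAAMMLIAVVIAVILSGTD
PEQGLREHRESTESSQERQHHEG
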