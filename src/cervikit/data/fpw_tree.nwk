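(Laurasiatheria,((Tupaia,(MouseLemur,((Marmoset,SquirrelMonkey),((Rhesus,Baboon),(Gorilla,(Chimp,Human)))))),(Rabbit,((GroundSquirrel,Woodchuck),(GuineaPig,(Mouse,Rat))))));
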