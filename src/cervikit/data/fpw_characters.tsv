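Laurasiatheria	0
Tupaia	1
MouseLemur	?
Marmoset	0
SquirrelMonkey	1
Rhesus	1
Baboon	1
Gorilla	1
Chimp	1
Human	1
Rabbit	0
GroundSquirrel	0
Woodchuck	0
GuineaPig	1
Mouse	0
Rat	0
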