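activates	3
activate	3
activated	3
activation	3
activator	3
enhances	3
enhance	3
enhanced	3
induces	3
induce	3
induced	3
stimulates	3
stimulate	3
stimulated	3
upregulates	3
up-regulates	3
upregulated	3
increases	3
increased	3
potentiates	3
potentiated	3
promotes	3
augments	3
inhibits	4
inhibit	4
inhibited	4
inhibitor	4
inhibition	4
blocks	4
blocked	4
blockade	4
suppresses	4
suppressed	4
downregulates	4
down-regulates	4
downregulated	4
decreases	4
decreased	4
reduces	4
reduced	4
attenuates	4
attenuated	4
impairs	4
abolishes	4
antagonised	4
agonist	5
agonists	5
agonism	5
agonistic	5
antagonist	6
antagonists	6
antagonism	6
antagonizes	6
antagonized	6
blocker	6
blockers	6
substrate	9
substrates	9
metabolized	9
metabolizes	9
metabolism	9
hydrolyzes	9
hydrolyzed	9
catalyzes	9
catalyzed	9
converts	9
converted	9
produces	9
produced	9
synthesized	9
synthesizes	9
caused	9
generates	9
generated	9
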