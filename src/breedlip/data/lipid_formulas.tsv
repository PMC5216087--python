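formula	name
C39H78NO8P	PC(31:0)
C41H82NO8P	PC(33:0)
C43H86NO8P	PC(35:0)
C18H34	long-chain hydrocarbon (one alkene)
C18H36	long-chain hydrocarbon (one alkene)
C17H34	long-chain hydrocarbon (one alkene)
C17H34O2	heptadecanoic acid / C17 sphinganine
C14H28	long-chain hydrocarbon
C15H30O	pentadecanal / 9-pentadecen-1-ol
C29H48O2	hydroxy-dihydro-ethanovitamin D3
C44H78NO7P	PC(O-32:6)
C46H82NO7P	PC(O-38:6)
C32H61NO5S	N-(trans-tetradecanoyl)-deoxysphing-4-enine-1-sulphonate
C39H82N2O6P	SM(d18:0/16:0)
C42H80NO7P	PC(O-34:3)
C42H82NO7P	PC(O-34:2)
C42H83NO9P	unknown phospholipid
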