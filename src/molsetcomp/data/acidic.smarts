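# Acidic group patterns, one SMARTS + label per line.
# Covers the classic ionisable acids: carboxylic, sulfonic/sulfinic, phosphonic/phosphoric.
[CX3](=O)[OX2H1,OX1-]	carboxylic_acid
[SX4](=O)(=O)[OX2H1,OX1-]	sulfonic_acid
[SX3](=O)[OX2H1,OX1-]	sulfinic_acid
[PX4](=O)[OX2H1,OX1-]	phosphonic_or_phosphoric_acid
c1ccccc1[OX2H1]	phenol
[NX3](=O)=O	aci_nitro
[CX3](=O)[SX2H1]	thiocarboxylic_acid
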