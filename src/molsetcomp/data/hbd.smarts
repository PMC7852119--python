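# Hydrogen-bond donor patterns (Lipinski-style: N-H or O-H).
[#7;!H0]	nh_donor
[#8;!H0]	oh_donor
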