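# Hydrogen-bond acceptor patterns (Lipinski-style: any N or O).
[#7]	nitrogen_acceptor
[#8]	oxygen_acceptor
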