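{"signature":[2,1,1,1],"reduced":[["u1",0],["u2",0],["m",1],["m",2],["m",3]],"provenance":"numeric-interpolation (dominant map)","max_degree":2,"polys":[],"checksum":"ea35f6a60e437733a14046aa12dd2b36ee4d4c00af9c6108a7d8f2c723f65ef1"}
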