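{"signature":[2,2,1,1],"reduced":[["m",0],["u1",1],["u2",1],["m",2],["m",3],["m",4],["m",5],["m",6],["m",7]],"provenance":"numeric-interpolation+swap","max_degree":2,"polys":[[[1,1,[0]],[1,1,[3]],[-1,1,[4]],[-1,1,[0,1]],[-2,1,[0,2]]]],"checksum":"30acd8176b4d312b5b8fc33b2fe357b19a3d9bbc68c07f70b1c0526b22f6278d"}
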