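{"signature":[1,2,1,1],"reduced":[["m",0],["u1",1],["u2",1],["m",2],["m",3]],"provenance":"numeric-interpolation+swap","max_degree":2,"polys":[[[1,1,[0]],[1,1,[3]],[-1,1,[4]],[-1,1,[0,1]],[-2,1,[0,2]]]],"checksum":"197ec4aa3b785a07b51514f2a4213494e2cf2c50b445be0ce8a3362bfed147b6"}
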