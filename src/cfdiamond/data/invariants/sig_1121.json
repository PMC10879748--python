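{"signature":[1,1,2,1],"reduced":[["m",0],["m",1],["u1",2],["u2",2],["m",3]],"provenance":"numeric-interpolation","max_degree":2,"polys":[[[1,1,[0]],[1,1,[1]],[-1,1,[4]],[-2,1,[0,2]],[-1,1,[0,3]]]],"checksum":"a3f4accbc8b0be1a1f05d3a25faaa0e52baae3bc5d360947e3ecd987e8524352"}
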